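"""Skew-normal null model, BH correction, and the gene-absence test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

import popscan as p
from popscan.absence import default_candidate_rule
from popscan.errors import FitError, GateError, ParameterError


def _detected_summary(depth=5.0):
    return p.PopulationSummary(ani=99.5, breadth=0.99, mean_depth=depth)


class TestFitSkewNormal:
    def test_recovers_normal(self):
        rng = np.random.default_rng(1)
        x = rng.normal(10, 2, size=5000)
        fit = p.fit_skew_normal(x)
        assert fit.mean == pytest.approx(10, abs=0.2)
        assert abs(fit.skewness) < 0.1

    def test_recovers_skew_normal(self):
        rng = np.random.default_rng(2)
        x = stats.skewnorm.rvs(4, loc=5, scale=3, size=5000, random_state=rng)
        fit = p.fit_skew_normal(x)
        true_mean = stats.skewnorm.mean(4, loc=5, scale=3)
        true_sd = stats.skewnorm.std(4, loc=5, scale=3)
        assert fit.mean == pytest.approx(true_mean, rel=0.05)
        assert fit.sd == pytest.approx(true_sd, rel=0.05)
        assert fit.skewness > 0

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        x = rng.normal(5, 1, size=500)
        f1, f2 = p.fit_skew_normal(x), p.fit_skew_normal(x)
        assert (f1.xi, f1.omega, f1.alpha) == (f2.xi, f2.omega, f2.alpha)

    def test_constant_input_fails(self):
        with pytest.raises(FitError):
            p.fit_skew_normal(np.full(100, 3.0))

    def test_too_few_values_fails(self):
        with pytest.raises(FitError):
            p.fit_skew_normal(np.arange(10.0))


class TestSkewNormalCdf:
    def test_symmetric_case_half_at_location(self):
        params = p.SkewNormalParams(xi=2.0, omega=1.5, alpha=0.0,
                                    n_segments=100, loglik=0.0)
        assert p.skew_normal_cdf(2.0, params) == pytest.approx(0.5)

    def test_limits(self):
        params = p.SkewNormalParams(xi=0.0, omega=1.0, alpha=3.0,
                                    n_segments=100, loglik=0.0)
        assert p.skew_normal_cdf(-50.0, params) == pytest.approx(0.0, abs=1e-12)
        assert p.skew_normal_cdf(50.0, params) == pytest.approx(1.0)

    @pytest.mark.parametrize("xi", [-2.0, 0.0, 5.0])
    @pytest.mark.parametrize("omega", [0.5, 1.0, 3.0])
    @pytest.mark.parametrize("alpha", [-4.0, 0.0, 1.5, 4.0])
    def test_matches_quadrature(self, xi, omega, alpha):
        """CDF equals numeric integration of the density to 1e-6."""
        params = p.SkewNormalParams(xi=xi, omega=omega, alpha=alpha,
                                    n_segments=100, loglik=0.0)

        def pdf(t):
            z = (t - xi) / omega
            return (2.0 / omega) * stats.norm.pdf(z) * stats.norm.cdf(alpha * z)

        for x in (xi - omega, xi, xi + 2 * omega):
            numeric, _ = integrate.quad(pdf, xi - 12 * omega, x, limit=200)
            assert p.skew_normal_cdf(x, params) == pytest.approx(
                numeric, abs=1e-6
            )

    def test_monotone(self):
        params = p.SkewNormalParams(xi=1.0, omega=2.0, alpha=-3.0,
                                    n_segments=100, loglik=0.0)
        xs = np.linspace(-10, 10, 200)
        cdf = p.skew_normal_cdf(xs, params)
        assert np.all(np.diff(cdf) >= 0)


def _brute_force_bh(pvals):
    """Step-up definition applied literally: q(i) = min_{j>=i} m p(j)/j."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    for rank_i, idx in enumerate(order, start=1):
        q[idx] = min(
            min(m * pvals[order[j - 1]] / j for j in range(rank_i, m + 1)), 1.0
        )
    return q


class TestBhAdjust:
    def test_worked_example(self):
        out = p.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_equal_values(self):
        assert p.bh_adjust([0.2]) == pytest.approx([0.2])
        assert np.allclose(p.bh_adjust([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            p.bh_adjust([0.5, 1.5])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(4)
        for _ in range(300):
            m = int(rng.integers(1, 40))
            pv = rng.random(m)
            assert np.allclose(p.bh_adjust(pv), _brute_force_bh(list(pv)),
                               atol=0, rtol=0)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        for _ in range(50):
            pv = rng.random(int(rng.integers(2, 60)))
            _, expected, _, _ = multipletests(pv, method="fdr_bh")
            assert np.allclose(p.bh_adjust(pv), expected)


class TestLengthAdjustment:
    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.floats(min_value=1e-6, max_value=0.999),
        st.integers(min_value=500, max_value=10_000),
    )
    def test_exponent_decreasing_in_length(self, raw_p, length):
        shorter = raw_p ** (length / 500)
        longer = raw_p ** ((length + 500) / 500)
        assert longer < shorter
        assert raw_p ** (500 / 500) == raw_p
        assert 1.0 ** (length / 500) == 1.0


@pytest.fixture(scope="module")
def fitted():
    """A 100 kbp community with four deleted genes at 6x coverage."""
    spec = p.CommunitySimSpec(
        genome_length=100_000, n_genes=80,
        gene_length_distribution=(400, 1200, 700),
        mean_depth=6, read_length=250, deleted_fraction=0.05,
        background_fraction=0.0, rng_seed=13,
    )
    c = p.simulate_community(spec)
    records = p.recruit_reads(c.reads, c.reference)
    profile = p.build_profile(records, c.reference)
    params = p.fit_skew_normal(
        [s.mean_depth for s in p.segment_coverages(profile)]
    )
    summary = p.summarize_population(records, profile)
    return c, profile, params, summary


class TestGeneAbsenceTest:
    def test_segment_means(self):
        ref = p.ReferenceGenome(contigs=(("c1", "A" * 1250),))
        rec = p.AlignmentRecord(
            query_id="r", subject_id="c1", percent_identity=100.0,
            alignment_length=250, mismatches=0, gap_opens=0,
            q_start=1, q_end=250, s_start=1, s_end=250,
            evalue=0.0, bit_score=250.0,
        )
        prof = p.build_profile([rec, rec], ref)
        segs = p.segment_coverages(prof)
        assert [s.seg_length for s in segs] == [500, 500, 250]
        assert segs[0].mean_depth == pytest.approx(1.0)  # depth 2 on half
        assert segs[1].mean_depth == 0.0

    def test_deleted_genes_called_absent(self, fitted):
        c, profile, params, summary = fitted
        calls = p.gene_absence_test(c.genes, profile, params, summary=summary)
        by_id = {x.gene_id: x for x in calls}
        for d in c.deletions:
            call = by_id[d.gene_id]
            assert call.mean_coverage == pytest.approx(0.0, abs=0.05)
            assert call.is_candidate
            if d.length >= 500:
                assert call.absent
        false_calls = [
            x for x in calls if x.absent and x.gene_id not in c.deleted_gene_ids
        ]
        assert len(false_calls) <= 1

    def test_invariants_on_calls(self, fitted):
        c, profile, params, summary = fitted
        calls = p.gene_absence_test(c.genes, profile, params, summary=summary)
        for x in calls:
            assert 0.0 <= x.raw_p <= 1.0
            assert 0.0 <= x.length_adjusted_p <= 1.0
            if x.is_candidate and x.gene_length >= 500:
                assert x.length_adjusted_p <= x.raw_p
            assert x.bh_adjusted_p >= x.length_adjusted_p - 1e-12
            if x.absent:
                assert x.is_candidate
            if not x.is_candidate:
                assert x.length_adjusted_p == 1.0

    def test_gates_enforced(self, fitted):
        c, profile, params, _ = fitted
        undetected = p.PopulationSummary(ani=94.0, breadth=0.99, mean_depth=5.0)
        with pytest.raises(GateError, match="ANI gate"):
            p.gene_absence_test(c.genes, profile, params, summary=undetected)

    def test_candidate_rule_threshold(self):
        rule = default_candidate_rule(median_segment_coverage=8.0)
        assert rule(0.5) and not rule(1.0)  # capped at 1.0
        rule_low = default_candidate_rule(median_segment_coverage=2.0)
        assert rule_low(0.4) and not rule_low(0.6)  # 0.25 x median = 0.5


class TestCategorySummary:
    def _call(self, gid, absent=True):
        return p.GeneAbsenceCall(
            gene_id=gid, contig_id="c1", start=0, end=600, gene_length=600,
            mean_coverage=0.0, raw_p=0.001, length_adjusted_p=0.001,
            bh_adjusted_p=0.004, is_candidate=True, absent=absent,
        )

    def test_fractions(self):
        calls = [self._call(f"g{i}") for i in range(10)]
        cmap = {f"g{i}": "regulation" for i in range(3)}
        table = p.summarize_absent_by_category(calls, cmap)
        row = table[table.category == "regulation"].iloc[0]
        assert row.n_absent == 3 and row.fraction == pytest.approx(0.3)
        assert table.fraction.sum() == pytest.approx(1.0)

    def test_no_absent_genes(self):
        table = p.summarize_absent_by_category(
            [self._call("g1", absent=False)], {}
        )
        assert table.empty

    def test_all_unmapped(self):
        table = p.summarize_absent_by_category(
            [self._call("g1"), self._call("g2")], {}
        )
        assert list(table.category) == ["hypothetical/other"]
        assert table.fraction.iloc[0] == 1.0
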