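"""Gene-absence testing from read coverage: the skew-normal resampling test.

The null model says a gene is present in the in-situ population, so its
coverage should look like the coverage of the rest of the genome. The
genome is tiled into 500 bp segments, a skew-normal distribution
f(x) = (2/omega) * phi((x-xi)/omega) * Phi(alpha * (x-xi)/omega)
is fit by maximum likelihood to the per-segment mean depths, and each
candidate gene's mean coverage is converted to a left-tail probability
under that null. Because 500 bp segments are treated as independent tests,
a gene of length L carries the exponent L/500:

    length_adjusted_p = raw_p ** (L / 500)

so longer genes are assessed more stringently for absence. Candidate genes
(those with zero or near-zero coverage) form the family for
Benjamini-Hochberg FDR correction; a gene is called absent when its
BH-adjusted p-value falls below alpha (default 0.025).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import RecruitmentProfile, segment_coverages
from .errors import FitError, GateError, ParameterError
from .population import DetectionGates, PopulationSummary, detect_population
from .simulate import GeneAnnotation

__all__ = [
    "SkewNormalParams",
    "GeneAbsenceCall",
    "fit_skew_normal",
    "skew_normal_cdf",
    "bh_adjust",
    "gene_absence_test",
    "summarize_absent_by_category",
]

#: Largest |skewness| a skew-normal distribution can attain (alpha -> inf).
_MAX_SKEWNORM_SKEW = 0.9952717464311565


@dataclass(frozen=True)
class SkewNormalParams:
    """Fitted null coverage distribution (location xi, scale omega > 0,
    shape alpha; alpha = 0 reduces to the normal)."""

    xi: float
    omega: float
    alpha: float
    n_segments: int
    loglik: float

    def __post_init__(self):
        if self.omega <= 0:
            raise ParameterError("omega must be > 0")

    @property
    def mean(self) -> float:
        return float(stats.skewnorm.mean(self.alpha, loc=self.xi, scale=self.omega))

    @property
    def sd(self) -> float:
        return float(stats.skewnorm.std(self.alpha, loc=self.xi, scale=self.omega))

    @property
    def skewness(self) -> float:
        return float(stats.skewnorm.stats(self.alpha, moments="s"))


def _moment_start(values: np.ndarray) -> tuple[float, float, float]:
    """Method-of-moments starting point for the MLE.

    Sample skewness is clamped to 99% of the attainable skew-normal bound so
    the inversion to (xi, omega, alpha) stays finite.
    """
    m = float(np.mean(values))
    s = float(np.std(values, ddof=0))
    g1 = float(stats.skew(values))
    g1 = float(np.clip(g1, -0.99 * _MAX_SKEWNORM_SKEW, 0.99 * _MAX_SKEWNORM_SKEW))
    a23 = abs(g1) ** (2.0 / 3.0)
    delta = np.sign(g1) * np.sqrt(
        (np.pi / 2.0) * a23 / (a23 + ((4.0 - np.pi) / 2.0) ** (2.0 / 3.0))
    )
    delta = float(np.clip(delta, -0.999, 0.999))
    alpha0 = delta / np.sqrt(1.0 - delta * delta)
    omega0 = s / np.sqrt(max(1.0 - 2.0 * delta * delta / np.pi, 1e-9))
    xi0 = m - omega0 * delta * np.sqrt(2.0 / np.pi)
    return xi0, omega0, alpha0


def fit_skew_normal(values: Sequence[float]) -> SkewNormalParams:
    """Maximum-likelihood skew-normal fit to segment coverage values.

    Initialized by method of moments; deterministic. Fewer than 50 values,
    or all-identical values, raise :class:`FitError`.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 50:
        raise FitError(f"need >= 50 coverage values to fit the null, got {x.size}")
    if np.ptp(x) == 0:
        raise FitError("coverage values are constant; the fit is degenerate")
    xi0, omega0, alpha0 = _moment_start(x)
    a, loc, scale = stats.skewnorm.fit(x, alpha0, loc=xi0, scale=omega0)
    loglik = float(np.sum(stats.skewnorm.logpdf(x, a, loc=loc, scale=scale)))
    return SkewNormalParams(
        xi=float(loc),
        omega=float(scale),
        alpha=float(a),
        n_segments=int(x.size),
        loglik=loglik,
    )


def skew_normal_cdf(x: float | np.ndarray, params: SkewNormalParams):
    """Left-tail probability P(X <= x) under the fitted null."""
    out = stats.skewnorm.cdf(x, params.alpha, loc=params.xi, scale=params.omega)
    return float(out) if np.isscalar(x) else out


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q(i) = min over j >= i of m * p(j) / j on the ascending sort, capped at
    1 — the standard step-up definition.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    out = np.empty_like(q_sorted)
    out[order] = q_sorted
    return out


@dataclass(frozen=True)
class GeneAbsenceCall:
    gene_id: str
    contig_id: str
    start: int
    end: int
    gene_length: int
    mean_coverage: float
    raw_p: float
    length_adjusted_p: float
    bh_adjusted_p: float
    is_candidate: bool
    absent: bool


def default_candidate_rule(median_segment_coverage: float) -> Callable[[float], bool]:
    """The "zero or near-zero coverage" gate for entering the test.

    A gene is a candidate when its mean coverage falls below
    min(1.0, 0.25 x median segment coverage). Without this gate the length
    exponent would flag long genes of perfectly ordinary coverage (raw_p of
    0.5 raised to L/500 becomes tiny for long genes), contradicting the
    test's intent of assessing genes that recruit no or few reads.
    """
    threshold = min(1.0, 0.25 * median_segment_coverage)

    def rule(mean_coverage: float) -> bool:
        return mean_coverage < threshold

    return rule


def gene_absence_test(
    genes: Sequence[GeneAnnotation],
    profile: RecruitmentProfile,
    params: SkewNormalParams,
    summary: PopulationSummary | None = None,
    candidate_rule: Callable[[float], bool] | None = None,
    alpha: float = 0.025,
    gates: DetectionGates | None = None,
    enforce_gates: bool = True,
) -> list[GeneAbsenceCall]:
    """Call genes absent from the in-situ population.

    The test is only meaningful when the population is actually present in
    the metagenome, so the detection gates (ANI > 95, breadth > 0.90, depth
    >= 3) are enforced on ``summary`` first; a failing gate raises
    :class:`GateError` naming it. Per gene: mean high-identity coverage over
    the gene body -> left-tail raw_p under the fitted null -> length
    exponent L/500 for candidates -> BH over the candidate family ->
    absent at ``alpha``. Non-candidates carry p = 1 and are excluded from
    the FDR family.
    """
    if not (0.0 < alpha < 1.0):
        raise ParameterError("alpha must be in (0, 1)")
    if enforce_gates:
        if summary is None:
            raise ParameterError(
                "a PopulationSummary is required to enforce the detection gates "
                "(pass enforce_gates=False to skip at your own risk)"
            )
        detected, reason = detect_population(summary, gates)
        if not detected:
            raise GateError(reason)

    if candidate_rule is None:
        seg_cov = np.array(
            [s.mean_depth for s in segment_coverages(profile)], dtype=float
        )
        candidate_rule = default_candidate_rule(float(np.median(seg_cov)))

    mean_cov = np.empty(len(genes))
    for i, g in enumerate(genes):
        if g.contig_id not in profile.high_depth:
            raise ParameterError(f"gene {g.gene_id}: unknown contig '{g.contig_id}'")
        depth = profile.high_depth[g.contig_id]
        if g.end > depth.size:
            raise ParameterError(
                f"gene {g.gene_id}: span exceeds contig '{g.contig_id}'"
            )
        mean_cov[i] = float(depth[g.start : g.end].mean())

    raw_p = skew_normal_cdf(mean_cov, params)
    raw_p = np.clip(np.atleast_1d(raw_p), 0.0, 1.0)
    is_candidate = np.array([candidate_rule(c) for c in mean_cov], dtype=bool)
    exponents = np.array([g.length / 500.0 for g in genes])
    adj_p = np.ones(len(genes))
    adj_p[is_candidate] = raw_p[is_candidate] ** exponents[is_candidate]

    bh_p = np.ones(len(genes))
    if is_candidate.any():
        bh_p[is_candidate] = bh_adjust(adj_p[is_candidate])
    absent = is_candidate & (bh_p < alpha)

    return [
        GeneAbsenceCall(
            gene_id=g.gene_id,
            contig_id=g.contig_id,
            start=g.start,
            end=g.end,
            gene_length=g.length,
            mean_coverage=float(mean_cov[i]),
            raw_p=float(raw_p[i]),
            length_adjusted_p=float(adj_p[i]),
            bh_adjusted_p=float(bh_p[i]),
            is_candidate=bool(is_candidate[i]),
            absent=bool(absent[i]),
        )
        for i, g in enumerate(genes)
    ]


def summarize_absent_by_category(
    calls: Iterable[GeneAbsenceCall],
    category_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Count and fraction of absent genes per functional category.

    Genes missing from ``category_map`` are pooled as "hypothetical/other".
    Fractions sum to 1 over the absent genes; no absent genes gives an
    empty table.
    """
    category_map = category_map or {}
    rows = [
        category_map.get(c.gene_id, "hypothetical/other")
        for c in calls
        if c.absent
    ]
    if not rows:
        return pd.DataFrame(columns=["category", "n_absent", "fraction"])
    counts = pd.Series(rows).value_counts()
    return pd.DataFrame(
        {
            "category": counts.index,
            "n_absent": counts.to_numpy(),
            "fraction": counts.to_numpy() / counts.sum(),
        }
    ).reset_index(drop=True)
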