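"""Aligner, recruitment filters, tabular I/O, and bin augmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import popscan as p
from popscan._seq import revcomp
from popscan.errors import ParameterError, TableFormatError
from popscan.simulate import sample_alignment_pairs


class TestSmithWaterman:
    def test_identical_sequences(self):
        aln = p.smith_waterman("ACGT", "ACGT", (1, -1, -2))
        assert aln.score == 4
        assert (aln.a_start, aln.a_end, aln.b_start, aln.b_end) == (0, 4, 0, 4)
        assert aln.mismatches == 0

    def test_single_interior_mismatch(self):
        # 7 matches, 1 mismatch: optimal local score 6 spanning both reads.
        aln = p.smith_waterman("ACGTACGT", "ACGAACGT", (1, -1, -2))
        assert aln.score == 6
        assert aln.length == 8
        assert aln.mismatches == 1

    def test_no_common_bases(self):
        aln = p.smith_waterman("AAAA", "TTTT", (1, -1, -2))
        assert aln.score <= 1

    def test_empty_sequence_rejected(self):
        with pytest.raises(ParameterError):
            p.smith_waterman("", "ACGT")

    def test_gap_handling(self):
        # Deleting one base from the middle: gapped alignment wins over
        # any ungapped segment (10 matches - one gap = 8 > 5).
        a = "ACGTACGTACG"
        b = a[:5] + a[6:]
        aln = p.smith_waterman(a, b, (1, -1, -2))
        assert aln.score == 8
        assert aln.gaps == 1

    def test_tie_break_prefers_lowest_start(self):
        # "AC" occurs twice in b; the alignment must use the first.
        aln = p.smith_waterman("AC", "GGACTTAC", (1, -1, -2))
        assert aln.score == 2
        assert aln.b_start == 2


@pytest.fixture(scope="module")
def reference():
    rng = np.random.default_rng(33)
    seq = "".join(rng.choice(list("ACGT"), size=5000))
    return p.ReferenceGenome(contigs=(("c1", seq),))


@pytest.fixture(scope="module")
def binned():
    rng = np.random.default_rng(77)
    seq = "".join(rng.choice(list("ACGT"), size=6000))
    return seq, [("bin_a", "ba_c1", seq)]


class TestRecruitReads:
    def test_exact_substring_full_identity(self, reference):
        seq = reference.contigs[0][1][1000:1150]
        [rec] = p.recruit_reads([("r1", seq)], reference)
        assert rec.percent_identity == 100.0
        assert rec.alignment_length == 150
        assert (rec.s_start, rec.s_end) == (1001, 1150)
        assert rec.mismatches == 0

    def test_three_substitutions_98_percent(self, reference):
        seq = list(reference.contigs[0][1][2000:2150])
        for pos in (10, 75, 148):
            seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
        [rec] = p.recruit_reads([("r1", "".join(seq))], reference)
        assert rec.percent_identity == 98.0
        assert rec.alignment_length == 150
        assert rec.mismatches == 3

    def test_reverse_strand_coordinates(self, reference):
        seq = revcomp(reference.contigs[0][1][3000:3100])
        [rec] = p.recruit_reads([("r1", seq)], reference)
        assert rec.reverse_strand
        assert rec.s_start == 3100 and rec.s_end == 3001
        assert rec.subject_span == (3000, 3100)

    def test_unrelated_reads_not_recruited(self, reference):
        rng = np.random.default_rng(44)
        reads = [
            (f"junk{i}", "".join(rng.choice(list("ACGT"), size=100)))
            for i in range(50)
        ]
        assert p.recruit_reads(reads, reference) == []

    def test_empty_read_rejected(self, reference):
        with pytest.raises(ParameterError):
            p.recruit_reads([("r1", "")], reference)

    def test_oracle_equivalence_on_sampled_pairs(self):
        """Recruiter pass/fail and identity equal the exact-alignment
        optimum (better strand) on planted + unrelated pairs."""
        filt = p.RecruitmentFilter(min_length=70, min_identity=60.0)
        ungapped = (1.0, -1.0, -1000.0)  # oracle restricted to the
        # recruiter's ungapped alignment model
        for pair in sample_alignment_pairs(60, seed=5):
            ref = p.ReferenceGenome(contigs=(("c", pair.reference),))
            recs = p.recruit_reads([("q", pair.read)], ref, filt)
            best = max(
                (p.smith_waterman(s, pair.reference, ungapped) for s in
                 (pair.read, revcomp(pair.read))),
                key=lambda a: a.score,
            )
            oracle_pass = best.length > 0 and filt.passes(
                best.length, best.percent_identity
            )
            assert bool(recs) == oracle_pass
            if recs:
                assert recs[0].percent_identity == round(best.percent_identity, 2)
                assert recs[0].alignment_length == best.length

    def test_filter_monotonicity(self, reference):
        pairs = sample_alignment_pairs(40, seed=9, reference_length_range=(500, 800))
        reads = [(f"r{i}", pr.read) for i, pr in enumerate(pairs)]
        ref = p.ReferenceGenome(
            contigs=tuple((f"c{i}", pr.reference) for i, pr in enumerate(pairs))
        )
        counts = []
        for min_len, min_id in [(30, 50), (70, 60), (70, 90), (75, 95)]:
            filt = p.RecruitmentFilter(min_length=min_len, min_identity=min_id)
            counts.append(len(p.recruit_reads(reads, ref, filt)))
        assert counts == sorted(counts, reverse=True)

    def test_strand_symmetry_of_depth(self, small_community, small_records):
        rc_reads = [(rid, revcomp(s)) for rid, s in small_community.reads[:500]]
        fwd = p.recruit_reads(small_community.reads[:500], small_community.reference)
        rev = p.recruit_reads(rc_reads, small_community.reference)
        pf = p.build_profile(fwd, small_community.reference)
        pr = p.build_profile(rev, small_community.reference)
        for cid in pf.contig_lengths:
            assert np.array_equal(pf.total_depth(cid), pr.total_depth(cid))


class TestAlignmentTable:
    def _records(self, n=50, seed=3):
        rng = np.random.default_rng(seed)
        out = []
        for i in range(n):
            length = int(rng.integers(70, 250))
            mism = int(rng.integers(0, 5))
            start = int(rng.integers(1, 5000))
            rev = bool(rng.random() < 0.5)
            s1, s2 = (start + length - 1, start) if rev else (start, start + length - 1)
            out.append(
                p.AlignmentRecord(
                    query_id=f"q{i}", subject_id="c1",
                    percent_identity=round(100 * (length - mism) / length, 2),
                    alignment_length=length, mismatches=mism, gap_opens=0,
                    q_start=1, q_end=length, s_start=s1, s_end=s2,
                    evalue=0.0, bit_score=float(length - 2 * mism),
                )
            )
        return out

    def test_round_trip(self, tmp_path):
        records = self._records(n=1000)
        path = str(tmp_path / "aln.tsv")
        p.write_alignment_table(records, path)
        assert p.read_alignment_table(path) == records

    def test_reverse_strand_convention(self, tmp_path):
        path = str(tmp_path / "rev.tsv")
        with open(path, "w") as fh:
            fh.write("q\tc\t99.00\t100\t1\t0\t1\t100\t500\t401\t0\t98\n")
        [rec] = p.read_alignment_table(path)
        assert rec.reverse_strand
        assert rec.subject_span == (400, 500)

    def test_malformed_row_names_line(self, tmp_path):
        path = str(tmp_path / "bad.tsv")
        with open(path, "w") as fh:
            fh.write("q\tc\t99.00\t100\t1\t0\t1\t100\t1\t100\t0\t98\n")
            fh.write("q\tc\t99.00\t100\t1\t0\t1\t100\t1\t100\t0\n")  # 11 cols
        with pytest.raises(TableFormatError, match="line 2"):
            p.read_alignment_table(path)


class TestBuildProfile:
    @pytest.fixture()
    def contig(self):
        return p.ReferenceGenome(contigs=(("c1", "A" * 1000),))

    @staticmethod
    def _rec(start, end, ident=100.0, qid="r"):
        length = end - start + 1
        return p.AlignmentRecord(
            query_id=qid, subject_id="c1", percent_identity=ident,
            alignment_length=length,
            mismatches=round(length * (1 - ident / 100)),
            gap_opens=0, q_start=1, q_end=length,
            s_start=start, s_end=end, evalue=0.0, bit_score=float(length),
        )

    def test_single_record_depth_and_segment_mean(self, contig):
        prof = p.build_profile([self._rec(1, 100)], contig)
        assert np.all(prof.high_depth["c1"][:100] == 1)
        assert np.all(prof.high_depth["c1"][100:] == 0)
        segs = p.segment_coverages(prof)
        assert segs[0].mean_depth == pytest.approx(0.2)

    def test_overlap_doubles_depth(self, contig):
        prof = p.build_profile([self._rec(1, 100), self._rec(51, 150)], contig)
        assert np.all(prof.high_depth["c1"][50:100] == 2)

    def test_identity_split_routes_classes(self, contig):
        prof = p.build_profile(
            [self._rec(1, 100, ident=99.0), self._rec(1, 100, ident=80.0)], contig
        )
        assert np.all(prof.high_depth["c1"][:100] == 1)
        assert np.all(prof.low_depth["c1"][:100] == 1)
        assert prof.identity_histogram[99] == 100
        assert prof.identity_histogram[80] == 100

    def test_partial_final_segment(self):
        ref = p.ReferenceGenome(contigs=(("c1", "A" * 1499),))
        prof = p.build_profile([], ref)
        segs = p.segment_coverages(prof)
        assert [s.seg_length for s in segs] == [500, 500, 499]

    def test_span_exceeding_contig_rejected(self, contig):
        with pytest.raises(ParameterError, match="r"):
            p.build_profile([self._rec(950, 1049)], contig)

    def test_conservation_on_recruited_records(self, small_profile):
        assert small_profile.depth_sum() == small_profile.total_aligned_bases
        assert small_profile.identity_histogram.sum() == (
            small_profile.total_aligned_bases
        )

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.lists(
        st.tuples(
            st.integers(min_value=1, max_value=900),
            st.integers(min_value=1, max_value=100),
            st.floats(min_value=0, max_value=100, allow_nan=False),
        ),
        max_size=30,
    ))
    def test_conservation_property(self, spans):
        ref = p.ReferenceGenome(contigs=(("c1", "A" * 1000),))
        records = [
            self._rec(s, min(s + ln - 1, 1000), ident=round(i, 2), qid=f"r{k}")
            for k, (s, ln, i) in enumerate(spans)
        ]
        prof = p.build_profile(records, ref)
        assert prof.depth_sum() == sum(r.alignment_length for r in records)
        assert prof.identity_histogram.sum() == sum(
            r.alignment_length for r in records
        )


class TestAugmentBins:
    @staticmethod
    def _mutate(seq, n, seed):
        rng = np.random.default_rng(seed)
        out = list(seq)
        for pos in rng.choice(len(seq), size=n, replace=False):
            out[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[pos]]
        return "".join(out)

    def test_exact_shared_block_assigned(self, binned):
        seq, bins = binned
        [a] = p.augment_bins(bins, [("u1", seq[1000:4000])])
        assert a.bin_id == "bin_a"
        assert a.alignment_length >= 2000

    def test_low_identity_not_assigned(self, binned):
        seq, bins = binned
        # 0.5% substitutions over 5 kbp -> ~99.5% identity, below 99.7.
        query = self._mutate(seq[:5000], 25, seed=1)
        [a] = p.augment_bins(bins, [("u1", query)])
        assert a.bin_id is None

    def test_short_match_not_assigned(self, binned):
        seq, bins = binned
        # 99.9%-identity block but only 1.5 kbp long.
        query = self._mutate(seq[2000:3500], 1, seed=2)
        [a] = p.augment_bins(bins, [("u1", query)])
        assert a.bin_id is None

    def test_reverse_complement_assigned(self, binned):
        seq, bins = binned
        [a] = p.augment_bins(bins, [("u1", revcomp(seq[500:3500]))])
        assert a.bin_id == "bin_a"
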