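"""Read recruitment: alignment records, filters, the aligner, tabular I/O.

The recruiting aligner is an ungapped seed-and-extend search: exact k-mer
seeds (default 16 bp) locate candidate diagonals on both strands, and each
diagonal is scored exactly (maximum-scoring contiguous segment under +1
match / -1 mismatch), which equals the Smith–Waterman optimum whenever that
optimum is ungapped. A full Smith–Waterman implementation with linear gaps
is provided as the independent testing oracle. Gapped alignments from
external search tools enter through the standard 12-column tabular format.

Internal coordinates are 0-based half-open; the tabular dialect's 1-based
inclusive coordinates (subject start > end encoding the reverse strand) are
converted at the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from . import _seq
from .errors import ParameterError, TableFormatError
from .simulate import ReferenceGenome

__all__ = [
    "AlignmentRecord",
    "RecruitmentFilter",
    "PRESETS",
    "LocalAlignment",
    "smith_waterman",
    "recruit_reads",
    "read_alignment_table",
    "write_alignment_table",
    "augment_bins",
    "BinAssignment",
]


@dataclass(frozen=True)
class AlignmentRecord:
    """One read-to-genome match in the 12-column tabular convention.

    Coordinates are 1-based inclusive; ``s_start > s_end`` encodes a
    reverse-strand match, exactly as the standard tabular dialect does.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float

    def __post_init__(self):
        if self.alignment_length < 1:
            raise ParameterError("alignment_length must be >= 1")
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ParameterError("percent_identity must be within [0, 100]")

    @property
    def reverse_strand(self) -> bool:
        return self.s_start > self.s_end

    @property
    def subject_span(self) -> tuple[int, int]:
        """0-based half-open span on the subject, strand-independent."""
        lo, hi = sorted((self.s_start, self.s_end))
        return lo - 1, hi


@dataclass(frozen=True)
class RecruitmentFilter:
    """Minimum alignment length (bp) and percent identity for retention."""

    min_length: int
    min_identity: float
    best_hit_only: bool = True

    def __post_init__(self):
        if self.min_length < 1:
            raise ParameterError("min_length must be >= 1")
        if not (0.0 <= self.min_identity <= 100.0):
            raise ParameterError("min_identity must be within [0, 100]")

    def passes(self, alignment_length: int, percent_identity: float) -> bool:
        return (
            alignment_length >= self.min_length
            and percent_identity >= self.min_identity
        )


#: Named threshold presets used throughout the analysis:
#: ``plot``       — recruitment-plot retention (>=70 bp, >=60% identity)
#: ``abundance``  — relative-abundance counting (>=200 bp, >=98%)
#: ``crosssite``  — abundance counting for shorter-read metagenomes
#:                  from other locations (>=90 bp, >=98%)
#: ``reassembly`` — read selection for bin re-assembly (>=100 bp, >=98%)
PRESETS: dict[str, RecruitmentFilter] = {
    "plot": RecruitmentFilter(min_length=70, min_identity=60.0),
    "abundance": RecruitmentFilter(min_length=200, min_identity=98.0),
    "crosssite": RecruitmentFilter(min_length=90, min_identity=98.0),
    "reassembly": RecruitmentFilter(min_length=100, min_identity=98.0),
}


# ---------------------------------------------------------------------------
# Smith–Waterman oracle
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LocalAlignment:
    """Optimal local alignment; spans are 0-based half-open."""

    score: float
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    length: int  # alignment columns
    matches: int
    mismatches: int
    gaps: int

    @property
    def percent_identity(self) -> float:
        return 100.0 * self.matches / self.length if self.length else 0.0


def smith_waterman(
    a: str, b: str, scoring: tuple[float, float, float] = (1.0, -1.0, -2.0)
) -> LocalAlignment:
    """Exact Smith–Waterman local alignment with linear gap penalties.

    Ties are broken deterministically: among co-optimal alignments the one
    with the lowest start in ``a``, then in ``b``, is returned. Traceback
    stops at the first zero-scoring cell (local-alignment semantics), so a
    leading mismatch that contributes nothing is not included in the span.
    """
    if not a or not b:
        raise ParameterError("smith_waterman requires non-empty sequences")
    match, mismatch, gap = scoring
    ac = _seq.encode(a)
    bc = _seq.encode(b)
    n, m = ac.size, bc.size
    H = np.zeros((n + 1, m + 1), dtype=np.float64)
    jidx = np.arange(m, dtype=np.float64)
    for i in range(1, n + 1):
        sub = np.where(bc == ac[i - 1], match, mismatch)
        prev = H[i - 1]
        base = np.maximum(prev[:-1] + sub, prev[1:] + gap)
        np.maximum(base, 0.0, out=base)
        # Left dependency H[i,j] = max(base[j], H[i,j-1] + gap) telescopes to
        # a running maximum of base[k] - k*gap along the row.
        t = np.maximum.accumulate(base - jidx * gap)
        H[i, 1:] = t + jidx * gap
    best = H.max()
    if best <= 0:
        return LocalAlignment(0.0, 0, 0, 0, 0, 0, 0, 0, 0)

    cells = np.argwhere(H == best)
    candidates = []
    for i_end, j_end in cells:
        i, j = int(i_end), int(j_end)
        matches = mismatches = gaps = cols = 0
        while i > 0 and j > 0 and H[i, j] > 0:
            s = match if ac[i - 1] == bc[j - 1] else mismatch
            if np.isclose(H[i, j], H[i - 1, j - 1] + s):
                cols += 1
                if ac[i - 1] == bc[j - 1]:
                    matches += 1
                else:
                    mismatches += 1
                i -= 1
                j -= 1
            elif np.isclose(H[i, j], H[i - 1, j] + gap):
                cols += 1
                gaps += 1
                i -= 1
            else:
                cols += 1
                gaps += 1
                j -= 1
        candidates.append(
            LocalAlignment(
                score=float(best),
                a_start=i,
                a_end=int(i_end),
                b_start=j,
                b_end=int(j_end),
                length=cols,
                matches=matches,
                mismatches=mismatches,
                gaps=gaps,
            )
        )
    candidates.sort(key=lambda L: (L.a_start, L.b_start, L.a_end, L.b_end))
    return candidates[0]


# ---------------------------------------------------------------------------
# Seed-and-extend recruiter
# ---------------------------------------------------------------------------


class _KmerIndex:
    """Sorted-array exact k-mer index of one contig."""

    def __init__(self, codes: np.ndarray, k: int):
        self.k = k
        kmers = _seq.kmer_codes(codes, k)
        self.order = np.argsort(kmers, kind="stable").astype(np.int64)
        self.sorted_kmers = kmers[self.order]

    def positions(self, query_kmers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """For each query k-mer, the [lo, hi) range into self.order."""
        lo = np.searchsorted(self.sorted_kmers, query_kmers, side="left")
        hi = np.searchsorted(self.sorted_kmers, query_kmers, side="right")
        return lo, hi


def _best_segment(scores: np.ndarray) -> tuple[float, int, int]:
    """Maximum-sum contiguous segment with stop-at-zero tie-breaking.

    Returns (score, start, end) with the segment chosen exactly as a
    Smith–Waterman traceback would choose it on this diagonal: the running
    score resets after touching zero, and among equal-scoring segments the
    first (left-most after reset) is kept.
    """
    best = 0.0
    best_start = best_end = 0
    cur = 0.0
    cur_start = 0
    for i, s in enumerate(scores):
        if cur <= 0:
            cur = 0.0
            cur_start = i
        cur += s
        if cur > best:
            best = cur
            best_start = cur_start
            best_end = i + 1
    return best, best_start, best_end


@dataclass(frozen=True)
class _Candidate:
    score: float
    subject_id: str
    s_start0: int  # 0-based start on subject (forward coordinates)
    length: int
    mismatches: int
    q_start0: int
    reverse: bool


def _scan_diagonals(
    read_codes: np.ndarray,
    contig_codes: np.ndarray,
    diagonals: Iterable[int],
    match: float = 1.0,
    mismatch: float = -1.0,
) -> list[tuple[float, int, int, int, int, int]]:
    """Exact best ungapped segment on each candidate diagonal.

    Yields (score, read_start, subject_start, length, window_start,
    window_end) per diagonal with a positive-scoring segment; the window is
    the full overlap of the read with the contig on that diagonal (read
    coordinates).
    """
    out = []
    rl = read_codes.size
    gl = contig_codes.size
    for d in diagonals:
        r_lo = max(0, -d)
        r_hi = min(rl, gl - d)
        if r_hi - r_lo < 1:
            continue
        eq = read_codes[r_lo:r_hi] == contig_codes[r_lo + d : r_hi + d]
        scores = np.where(eq, match, mismatch)
        score, seg_start, seg_end = _best_segment(scores)
        if score <= 0:
            continue
        out.append(
            (
                score,
                r_lo + seg_start,
                r_lo + seg_start + d,
                seg_end - seg_start,
                r_lo,
                r_hi,
            )
        )
    return out


def recruit_reads(
    reads: Sequence[tuple[str, str]],
    reference: ReferenceGenome,
    recruitment_filter: RecruitmentFilter = PRESETS["plot"],
    seed_length: int = 16,
) -> list[AlignmentRecord]:
    """Align reads to the reference and keep matches passing the filter.

    Ungapped seed-and-extend on both strands. Each candidate diagonal is
    scored by its exact maximum-scoring segment (+1/-1), which places the
    read; the emitted record then covers the read's full extent on that
    diagonal (clipped at contig ends), so end mismatches count against
    identity exactly as they would for a mapped read. This keeps read-set
    ANI an unbiased estimator of population divergence. With
    ``best_hit_only`` (the default) at most one record per read is
    emitted — the highest-scoring placement, ties broken by
    lexicographically smallest subject id, then smallest subject start — so
    multi-mapping reads contribute coverage exactly once.
    """
    contig_codes = {cid: _seq.encode(seq) for cid, seq in reference.contigs}
    indexes = {
        cid: _KmerIndex(codes, seed_length) for cid, codes in contig_codes.items()
    }
    contig_ids = sorted(contig_codes)
    records: list[AlignmentRecord] = []

    for read_id, seq in reads:
        if not seq:
            raise ParameterError(f"read '{read_id}' is empty")
        fwd = _seq.encode(seq)
        if fwd.size < seed_length:
            continue
        rev = _seq.revcomp_codes(fwd)
        candidates: list[_Candidate] = []
        for cid in contig_ids:
            idx = indexes[cid]
            codes = contig_codes[cid]
            for reverse, rcodes in ((False, fwd), (True, rev)):
                qk = _seq.kmer_codes(rcodes, seed_length)
                lo, hi = idx.positions(qk)
                hit_mask = hi > lo
                if not hit_mask.any():
                    continue
                diags = set()
                for qpos in np.flatnonzero(hit_mask):
                    for gpos in idx.order[lo[qpos] : hi[qpos]]:
                        diags.add(int(gpos) - int(qpos))
                for score, r_start, g_start, _seg_len, w_lo, w_hi in (
                    _scan_diagonals(rcodes, codes, sorted(diags))
                ):
                    # Report the full read extent on this diagonal.
                    d = g_start - r_start
                    length = w_hi - w_lo
                    mism = int(
                        length
                        - np.count_nonzero(
                            rcodes[w_lo:w_hi] == codes[w_lo + d : w_hi + d]
                        )
                    )
                    candidates.append(
                        _Candidate(
                            score=score,
                            subject_id=cid,
                            s_start0=w_lo + d,
                            length=length,
                            mismatches=mism,
                            q_start0=w_lo,
                            reverse=reverse,
                        )
                    )
        if not candidates:
            continue
        candidates.sort(key=lambda c: (-c.score, c.subject_id, c.s_start0, c.reverse))
        chosen = candidates[:1] if recruitment_filter.best_hit_only else candidates
        seen = set()
        for c in chosen:
            pident = 100.0 * (c.length - c.mismatches) / c.length
            if not recruitment_filter.passes(c.length, pident):
                continue
            key = (c.subject_id, c.s_start0, c.length, c.reverse)
            if key in seen:
                continue
            seen.add(key)
            rl = fwd.size
            if not c.reverse:
                q_start, q_end = c.q_start0 + 1, c.q_start0 + c.length
                s_start, s_end = c.s_start0 + 1, c.s_start0 + c.length
            else:
                # Candidate coordinates refer to the reverse-complemented
                # read; report on the original read with subject reversed.
                q_start = rl - (c.q_start0 + c.length) + 1
                q_end = rl - c.q_start0
                s_start, s_end = c.s_start0 + c.length, c.s_start0 + 1
            records.append(
                AlignmentRecord(
                    query_id=read_id,
                    subject_id=c.subject_id,
                    percent_identity=round(pident, 2),
                    alignment_length=c.length,
                    mismatches=c.mismatches,
                    gap_opens=0,
                    q_start=q_start,
                    q_end=q_end,
                    s_start=s_start,
                    s_end=s_end,
                    evalue=0.0,
                    bit_score=float(c.score),
                )
            )
    return records


# ---------------------------------------------------------------------------
# 12-column tabular I/O
# ---------------------------------------------------------------------------

_COLUMNS = (
    "query_id subject_id percent_identity alignment_length mismatches "
    "gap_opens q_start q_end s_start s_end evalue bit_score"
).split()


def write_alignment_table(records: Iterable[AlignmentRecord], path: str) -> None:
    """Write records in the standard 12-column tab-separated dialect."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.query_id}\t{r.subject_id}\t{r.percent_identity:.2f}"
                f"\t{r.alignment_length}\t{r.mismatches}\t{r.gap_opens}"
                f"\t{r.q_start}\t{r.q_end}\t{r.s_start}\t{r.s_end}"
                f"\t{r.evalue:g}\t{r.bit_score:g}\n"
            )


def read_alignment_table(path: str) -> list[AlignmentRecord]:
    """Parse a 12-column tabular alignment file.

    Strand is inferred from subject coordinate order (start > end means
    reverse). A malformed row raises :class:`TableFormatError` naming the
    1-based line number.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise TableFormatError(
                    lineno, f"expected 12 tab-separated columns, found {len(parts)}"
                )
            try:
                records.append(
                    AlignmentRecord(
                        query_id=parts[0],
                        subject_id=parts[1],
                        percent_identity=float(parts[2]),
                        alignment_length=int(parts[3]),
                        mismatches=int(parts[4]),
                        gap_opens=int(parts[5]),
                        q_start=int(parts[6]),
                        q_end=int(parts[7]),
                        s_start=int(parts[8]),
                        s_end=int(parts[9]),
                        evalue=float(parts[10]),
                        bit_score=float(parts[11]),
                    )
                )
            except (ValueError, ParameterError) as exc:
                raise TableFormatError(lineno, str(exc)) from exc
    return records


# ---------------------------------------------------------------------------
# Bin augmentation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BinAssignment:
    contig_id: str
    bin_id: str | None  # None = left unassigned
    percent_identity: float | None = None
    alignment_length: int | None = None


def augment_bins(
    binned_contigs: Sequence[tuple[str, str, str]],
    unbinned_contigs: Sequence[tuple[str, str]],
    min_identity: float = 99.7,
    min_length: int = 2000,
    seed_length: int = 16,
) -> list[BinAssignment]:
    """Assign unbinned contigs to bins by near-identity alignment.

    ``binned_contigs`` are ``(bin_id, contig_id, sequence)``; an unbinned
    contig joins the bin of its best-matching binned contig iff some
    (ungapped) alignment reaches >= ``min_identity`` percent identity over
    >= ``min_length`` bp. Ties go to the higher identity, then the
    lexicographically smallest bin id.
    """
    prepared = []
    for bin_id, contig_id, seq in binned_contigs:
        codes = _seq.encode(seq)
        prepared.append((bin_id, contig_id, codes, _KmerIndex(codes, seed_length)))

    assignments = []
    for contig_id, seq in unbinned_contigs:
        fwd = _seq.encode(seq)
        rev = _seq.revcomp_codes(fwd)
        best: tuple[float, float, str, int] | None = None  # (-score,-ident,bin,len)
        for bin_id, _bcid, codes, idx in prepared:
            for rcodes in (fwd, rev):
                qk = _seq.kmer_codes(rcodes, seed_length)
                if qk.size == 0:
                    continue
                lo, hi = idx.positions(qk)
                hit_mask = hi > lo
                if not hit_mask.any():
                    continue
                diags = set()
                for qpos in np.flatnonzero(hit_mask):
                    for gpos in idx.order[lo[qpos] : hi[qpos]]:
                        diags.add(int(gpos) - int(qpos))
                for score, r_start, g_start, length, _w_lo, _w_hi in (
                    _scan_diagonals(rcodes, codes, sorted(diags))
                ):
                    matches = int(
                        np.count_nonzero(
                            rcodes[r_start : r_start + length]
                            == codes[g_start : g_start + length]
                        )
                    )
                    pident = 100.0 * matches / length
                    if pident < min_identity or length < min_length:
                        continue
                    key = (-score, -pident, bin_id, length)
                    if best is None or key < best:
                        best = key
        if best is None:
            assignments.append(BinAssignment(contig_id=contig_id, bin_id=None))
        else:
            assignments.append(
                BinAssignment(
                    contig_id=contig_id,
                    bin_id=best[2],
                    percent_identity=-best[1],
                    alignment_length=best[3],
                )
            )
    return assignments
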