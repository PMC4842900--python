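"""Per-base recruitment profiles: depth by identity class, segments, histogram.

A :class:`RecruitmentProfile` is the in-memory form of a fragment
recruitment plot: per-base depth split at an identity threshold (default
95%, separating the sequence-discrete population from lower-identity
relatives), mean coverage per consecutive 500 bp segment (the unit of the
gene-absence null model), a smoothed windowed display track, and the
identity histogram of recruited base-positions per 1% identity bin.

Conservation invariant: the summed per-base depth over both classes equals
the summed alignment length over contributing records, exactly. Depth is
deposited over ``alignment_length`` bases starting at the subject span
start, which coincides with the subject span for ungapped records.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .alignment import AlignmentRecord
from .errors import ParameterError
from .simulate import ReferenceGenome

__all__ = [
    "RecruitmentProfile",
    "SegmentCoverage",
    "build_profile",
    "segment_coverages",
]


@dataclass(frozen=True)
class SegmentCoverage:
    """Mean high-identity depth over one tiling segment (500 bp by default,
    shorter for the final partial segment of a contig)."""

    contig_id: str
    seg_start: int  # 0-based
    seg_length: int
    mean_depth: float


@dataclass
class RecruitmentProfile:
    """Depth and identity structure of a set of recruited matches."""

    contig_lengths: dict[str, int]
    high_depth: dict[str, np.ndarray]  # identity >= identity_split
    low_depth: dict[str, np.ndarray]  # identity < identity_split
    identity_histogram: np.ndarray  # base-positions per 1% bin, index 0..100
    identity_split: float = 95.0
    window_size: int = 1000
    segment_size: int = 500
    n_records: int = 0
    total_aligned_bases: int = 0

    @property
    def reference_length(self) -> int:
        return sum(self.contig_lengths.values())

    def total_depth(self, contig_id: str) -> np.ndarray:
        return self.high_depth[contig_id] + self.low_depth[contig_id]

    def depth_sum(self) -> int:
        return int(
            sum(int(d.sum()) for d in self.high_depth.values())
            + sum(int(d.sum()) for d in self.low_depth.values())
        )

    def windowed_track(self, contig_id: str) -> np.ndarray:
        """Mean depth per window (high and low class columns), for display."""
        w = self.window_size
        n = self.contig_lengths[contig_id]
        edges = np.arange(0, n, w)
        out = np.empty((edges.size, 2), dtype=float)
        for col, depth in enumerate(
            (self.high_depth[contig_id], self.low_depth[contig_id])
        ):
            sums = np.add.reduceat(depth.astype(float), edges)
            widths = np.minimum(edges + w, n) - edges
            out[:, col] = sums / widths
        return out


def build_profile(
    records: Iterable[AlignmentRecord],
    reference: ReferenceGenome,
    identity_split: float = 95.0,
    window: int = 1000,
    segment: int = 500,
) -> RecruitmentProfile:
    """Accumulate per-base depth and the identity histogram from records.

    Each record increments depth by one over its subject footprint, routed
    to the high- or low-identity class by ``percent_identity`` compared with
    ``identity_split``. A record whose footprint exceeds its contig raises
    an error naming the record.
    """
    if segment < 1 or window < 1:
        raise ParameterError("segment and window sizes must be >= 1")
    lengths = {cid: len(seq) for cid, seq in reference.contigs}
    # Difference-array accumulation, one cumsum per contig per class.
    diffs = {
        cid: (np.zeros(n + 1, dtype=np.int64), np.zeros(n + 1, dtype=np.int64))
        for cid, n in lengths.items()
    }
    hist = np.zeros(101, dtype=np.int64)
    n_records = 0
    total_bases = 0
    for r in records:
        if r.subject_id not in lengths:
            raise ParameterError(
                f"record {r.query_id}: unknown contig '{r.subject_id}'"
            )
        start, _ = r.subject_span
        end = start + r.alignment_length
        if start < 0 or end > lengths[r.subject_id]:
            raise ParameterError(
                f"record {r.query_id}: span [{start}, {end}) exceeds contig "
                f"'{r.subject_id}' of length {lengths[r.subject_id]}"
            )
        cls = 0 if r.percent_identity >= identity_split else 1
        diff = diffs[r.subject_id][cls]
        diff[start] += 1
        diff[end] -= 1
        hist[min(int(r.percent_identity), 100)] += r.alignment_length
        n_records += 1
        total_bases += r.alignment_length

    high = {cid: np.cumsum(d[0][:-1]) for cid, d in diffs.items()}
    low = {cid: np.cumsum(d[1][:-1]) for cid, d in diffs.items()}
    return RecruitmentProfile(
        contig_lengths=lengths,
        high_depth=high,
        low_depth=low,
        identity_histogram=hist,
        identity_split=identity_split,
        window_size=window,
        segment_size=segment,
        n_records=n_records,
        total_aligned_bases=total_bases,
    )


def segment_coverages(
    profile: RecruitmentProfile, segment: int | None = None
) -> list[SegmentCoverage]:
    """Mean high-identity depth per consecutive segment, tiling each contig.

    The final partial segment at a contig end is kept as its own (shorter)
    segment with its true mean.
    """
    seg = segment or profile.segment_size
    if seg < 1:
        raise ParameterError("segment size must be >= 1")
    out = []
    for cid in sorted(profile.contig_lengths):
        n = profile.contig_lengths[cid]
        depth = profile.high_depth[cid].astype(float)
        edges = np.arange(0, n, seg)
        sums = np.add.reduceat(depth, edges)
        widths = np.minimum(edges + seg, n) - edges
        means = sums / widths
        for e, w, m in zip(edges, widths, means):
            out.append(
                SegmentCoverage(
                    contig_id=cid,
                    seg_start=int(e),
                    seg_length=int(w),
                    mean_depth=float(m),
                )
            )
    return out
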