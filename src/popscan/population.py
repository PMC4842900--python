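"""Population-level summaries: ANI, breadth, depth, abundance, detection.

A population is declared present in a metagenome when three gates all pass:
genome-derived ANI > 95%, genome representation (breadth) > 0.90, and mean
fold-coverage >= 3. Breadth and depth are computed from the high-identity
(>= 95% by default) depth class only, so low-identity relatives cannot
satisfy "genome representation" on behalf of the target population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import AlignmentRecord
from .coverage import RecruitmentProfile
from .errors import NoRecruitmentError, ParameterError

__all__ = [
    "DetectionGates",
    "PopulationSummary",
    "compute_ani",
    "compute_breadth_and_depth",
    "compute_abundance",
    "detect_population",
    "sequence_discrete_score",
    "summarize_population",
]


@dataclass(frozen=True)
class DetectionGates:
    """Cross-site presence gates: ANI strictly above ``ani_min`` percent,
    breadth strictly above ``breadth_min``, mean depth at least ``depth_min``
    (the depth bound is approximate in origin, hence >=)."""

    ani_min: float = 95.0
    breadth_min: float = 0.90
    depth_min: float = 3.0


@dataclass(frozen=True)
class PopulationSummary:
    ani: float
    breadth: float
    mean_depth: float
    relative_abundance: float | None = None
    detected: bool = False
    reason: str = ""
    gates: DetectionGates = DetectionGates()


def compute_ani(
    records: list[AlignmentRecord],
    min_length: int = 70,
    min_identity: float = 60.0,
    weighted: bool = True,
) -> float:
    """Genome-derived average nucleotide identity from recruited matches.

    The mean percent identity over records passing the retention cutoffs
    (>= 70 bp and >= 60% identity by default), length-weighted so each
    aligned base-position counts equally; ``weighted=False`` gives the
    plain per-record mean. Zero qualifying records raise
    :class:`NoRecruitmentError` rather than returning a misleading 0.0.
    """
    lengths = []
    idents = []
    for r in records:
        if r.alignment_length >= min_length and r.percent_identity >= min_identity:
            lengths.append(r.alignment_length)
            idents.append(r.percent_identity)
    if not lengths:
        raise NoRecruitmentError(
            "no recruited matches pass the ANI cutoffs; ANI is undefined"
        )
    lengths = np.asarray(lengths, dtype=float)
    idents = np.asarray(idents, dtype=float)
    if weighted:
        return float(np.sum(lengths * idents) / np.sum(lengths))
    return float(np.mean(idents))


def compute_breadth_and_depth(
    profile: RecruitmentProfile,
) -> tuple[float, float]:
    """Breadth (fraction of positions with high-identity depth >= 1) and
    mean high-identity fold-coverage over the whole reference."""
    total = profile.reference_length
    covered = sum(
        int(np.count_nonzero(d >= 1)) for d in profile.high_depth.values()
    )
    depth_sum = sum(int(d.sum()) for d in profile.high_depth.values())
    return covered / total, depth_sum / total


def compute_abundance(n_recruited: int, n_total_reads: int) -> float:
    """Relative abundance: recruited reads / total metagenome reads."""
    if n_total_reads <= 0:
        raise ParameterError("n_total_reads must be > 0")
    if not (0 <= n_recruited <= n_total_reads):
        raise ParameterError("need 0 <= n_recruited <= n_total_reads")
    return n_recruited / n_total_reads


def detect_population(
    summary: PopulationSummary, gates: DetectionGates | None = None
) -> tuple[bool, str]:
    """Apply the three presence gates; the reason names the first failure."""
    g = gates or summary.gates
    if not summary.ani > g.ani_min:
        return False, "ANI gate"
    if not summary.breadth > g.breadth_min:
        return False, "breadth gate"
    if not summary.mean_depth >= g.depth_min:
        return False, "depth gate"
    return True, "detected"


def summarize_population(
    records: list[AlignmentRecord],
    profile: RecruitmentProfile,
    n_total_reads: int | None = None,
    n_recruited_under_preset: int | None = None,
    gates: DetectionGates | None = None,
    ani_min_length: int = 70,
    ani_min_identity: float = 60.0,
) -> PopulationSummary:
    """Assemble the per-(bin x metagenome) summary and apply the gates."""
    gates = gates or DetectionGates()
    ani = compute_ani(records, min_length=ani_min_length, min_identity=ani_min_identity)
    breadth, mean_depth = compute_breadth_and_depth(profile)
    abundance = None
    if n_total_reads is not None and n_recruited_under_preset is not None:
        abundance = compute_abundance(n_recruited_under_preset, n_total_reads)
    partial = PopulationSummary(
        ani=ani,
        breadth=breadth,
        mean_depth=mean_depth,
        relative_abundance=abundance,
        gates=gates,
    )
    detected, reason = detect_population(partial, gates)
    return PopulationSummary(
        ani=ani,
        breadth=breadth,
        mean_depth=mean_depth,
        relative_abundance=abundance,
        detected=detected,
        reason=reason,
        gates=gates,
    )


def sequence_discrete_score(
    identity_histogram: np.ndarray,
    high_identity_floor: float = 95.0,
) -> tuple[float, bool]:
    """Quantify how sequence-discrete the recruiting population is.

    ``high_id_fraction`` is the share of recruited base-positions at
    >= 95% identity. The discreteness flag additionally requires a coverage
    valley: the histogram mass in [90, 95) must be less than half the mass
    in [95, 100]. An empty histogram raises :class:`NoRecruitmentError`.
    """
    hist = np.asarray(identity_histogram, dtype=float)
    total = hist.sum()
    if total <= 0:
        raise NoRecruitmentError("empty identity histogram; no recruitment")
    floor = int(high_identity_floor)
    high = hist[floor:].sum()
    frac = high / total
    valley = hist[90:floor].sum() < 0.5 * high
    return float(frac), bool(frac >= 0.8 and valley)
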