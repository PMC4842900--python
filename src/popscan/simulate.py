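"""Synthetic community generator with known ground truth.

Emulates the inputs the recruitment analysis consumes: a reference
population-bin genome with annotated genes, an in-situ population diverged
from it at a configurable average nucleotide identity (ANI) with a set of
genuinely excised genes, uniform shotgun reads with substitution-type
sequencing error, and unrelated background community reads.

The model is deliberately minimal where the downstream statistics do not
care: reads are single-end (merged paired-end reads behave as single
alignments downstream), divergence and sequencing error are substitution-only
so that percent-identity arithmetic is exact, and the non-target community is
a single unrelated genome.
"""

from __future__ import annotations

import hashlib
import json
import os
from bisect import bisect_left
from dataclasses import dataclass, replace

import numpy as np

from . import _seq
from .errors import GenePlacementError, ParameterError

__all__ = [
    "ReferenceGenome",
    "GeneAnnotation",
    "CommunitySimSpec",
    "ReadTruth",
    "DeletionRecord",
    "generate_reference",
    "diverge_population",
    "simulate_reads",
    "simulate_community",
    "write_fixture",
    "read_fixture",
    "sample_alignment_pairs",
]

#: Functional labels assigned to synthetic genes, echoing the broad COG-like
#: categories used when summarizing genes lost by in-situ populations.
GENE_CATEGORIES = (
    "transcriptional regulation",
    "carbohydrate transport and metabolism",
    "amino acid transport and metabolism",
    "nutrient transport",
    "hypothetical/other",
)
_CATEGORY_WEIGHTS = (0.10, 0.15, 0.13, 0.09, 0.53)


@dataclass(frozen=True)
class ReferenceGenome:
    """A (possibly multi-contig) genome as an ordered list of contigs."""

    contigs: tuple[tuple[str, str], ...]

    def __post_init__(self):
        ids = [cid for cid, _ in self.contigs]
        if len(set(ids)) != len(ids):
            raise ParameterError("contig ids must be unique")
        for cid, seq in self.contigs:
            if not cid or not seq:
                raise ParameterError("contig ids and sequences must be non-empty")

    @property
    def total_length(self) -> int:
        return sum(len(seq) for _, seq in self.contigs)

    def as_dict(self) -> dict[str, str]:
        return dict(self.contigs)


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene: 0-based half-open coordinates on its contig."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str = "+"
    category: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ParameterError(f"gene {self.gene_id}: need 0 <= start < end")
        if self.strand not in ("+", "-"):
            raise ParameterError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ReadTruth:
    """Ground-truth provenance of one synthetic read."""

    read_id: str
    origin_contig: str  # "" for background reads
    origin_start: int  # -1 for background reads
    strand: str
    n_substitutions: int  # sequencing-error substitutions in this read
    from_background: bool
    overlaps_deleted_gene: bool  # read spans an excision junction


@dataclass(frozen=True)
class DeletionRecord:
    """One excised gene, with its position in both coordinate frames."""

    gene_id: str
    contig_id: str
    ref_start: int
    ref_end: int
    length: int
    junction: int  # position of the excision point in *diverged* coordinates


@dataclass(frozen=True)
class CommunitySimSpec:
    """All knobs of the synthetic community, with study-like defaults.

    Defaults emulate the cross-site comparison the analysis is built for: a
    population diverged at ~99% ANI from the reference bin with 2.5% of its
    genes lost, sequenced to ~5x at 1% substitution error, embedded in an
    unrelated background community. ``read_length`` models merged 2 x 150 bp
    paired-end fragments (~250 bp), which is also why the abundance preset's
    200 bp floor is satisfiable.
    """

    genome_length: int = 500_000
    n_genes: int = 400
    gene_length_distribution: tuple[int, int, int] = (200, 1200, 700)  # min,max,mean
    gc_fraction: float = 0.5
    target_ani: float = 99.1
    deleted_gene_ids: frozenset[str] | None = None
    deleted_fraction: float = 0.025
    mean_depth: float = 5.0
    read_length: int = 250
    seq_error_rate: float = 0.01
    background_fraction: float = 0.3
    rng_seed: int = 0

    def __post_init__(self):
        if not (80.0 <= self.target_ani <= 100.0):
            raise ParameterError("target_ani must be within [80, 100]")
        if self.mean_depth <= 0:
            raise ParameterError("mean_depth must be > 0")
        if not (0.0 <= self.background_fraction < 1.0):
            raise ParameterError("background_fraction must be in [0, 1)")
        if not (0.0 <= self.gc_fraction <= 1.0):
            raise ParameterError("gc_fraction must be in [0, 1]")
        if not (0.0 <= self.seq_error_rate < 1.0):
            raise ParameterError("seq_error_rate must be in [0, 1)")
        if not (0.0 <= self.deleted_fraction <= 1.0):
            raise ParameterError("deleted_fraction must be in [0, 1]")
        lo, hi, mean = self.gene_length_distribution
        if not (1 <= lo <= mean <= hi):
            raise ParameterError("gene lengths must satisfy min <= mean <= max")
        if self.genome_length < 1 or self.n_genes < 0 or self.read_length < 1:
            raise ParameterError("sizes must be positive")

    @property
    def substitution_rate(self) -> float:
        return 1.0 - self.target_ani / 100.0


def _draw_gene_lengths(spec: CommunitySimSpec, rng: np.random.Generator) -> np.ndarray:
    """Gene lengths from a Beta distribution rescaled to [min, max].

    The Beta mean is pinned to the requested mean with a fixed concentration
    of 4, giving a right-skewed, unimodal length profile when the mean sits
    below the midpoint (as in real gene catalogs).
    """
    lo, hi, mean = spec.gene_length_distribution
    if hi == lo:
        return np.full(spec.n_genes, lo, dtype=int)
    frac = (mean - lo) / (hi - lo)
    frac = min(max(frac, 1e-6), 1 - 1e-6)
    conc = 4.0
    draws = rng.beta(frac * conc, (1 - frac) * conc, size=spec.n_genes)
    return np.rint(lo + draws * (hi - lo)).astype(int)


def generate_reference(
    spec: CommunitySimSpec,
) -> tuple[ReferenceGenome, list[GeneAnnotation]]:
    """Generate a random reference genome with non-overlapping genes.

    Deterministic for a fixed ``spec.rng_seed``. Genes are placed uniformly
    at random without overlap, longest first; each gene gets 100 placement
    attempts before the operation fails explicitly rather than silently
    truncating the annotation.
    """
    lo, hi, _ = spec.gene_length_distribution
    if spec.n_genes * hi > spec.genome_length:
        raise GenePlacementError(
            f"cannot place genes: n_genes * max gene length "
            f"({spec.n_genes} * {hi}) exceeds genome_length ({spec.genome_length})"
        )
    rng = np.random.default_rng(spec.rng_seed)
    contig_id = "contig_1"
    sequence = _seq.random_sequence(spec.genome_length, spec.gc_fraction, rng)

    lengths = _draw_gene_lengths(spec, rng)
    # Place longest genes first: identical feasibility, far fewer rejections.
    order = np.argsort(-lengths, kind="stable")
    placed: list[tuple[int, int, int]] = []  # (start, end, original index)
    occupied_starts: list[int] = []  # sorted starts for overlap bisection
    occupied: list[tuple[int, int]] = []

    def overlaps(start: int, end: int) -> bool:
        i = bisect_left(occupied_starts, end)
        if i > 0:
            s, e = occupied[i - 1]
            if e > start:
                return True
        if i < len(occupied):
            s, e = occupied[i]
            if s < end:
                return True
        return False

    for idx in order:
        length = int(lengths[idx])
        ok = False
        for _ in range(100):
            start = int(rng.integers(0, spec.genome_length - length + 1))
            end = start + length
            if not overlaps(start, end):
                j = bisect_left(occupied_starts, start)
                occupied_starts.insert(j, start)
                occupied.insert(j, (start, end))
                placed.append((start, end, int(idx)))
                ok = True
                break
        if not ok:
            raise GenePlacementError(
                f"cannot place genes: no non-overlapping slot found for a "
                f"{length} bp gene after 100 attempts"
            )

    placed.sort()
    genes = []
    strands = rng.choice(["+", "-"], size=len(placed))
    categories = rng.choice(
        len(GENE_CATEGORIES), size=len(placed), p=_CATEGORY_WEIGHTS
    )
    width = max(4, len(str(max(len(placed), 1))))
    for i, (start, end, _) in enumerate(placed):
        genes.append(
            GeneAnnotation(
                gene_id=f"gene_{i + 1:0{width}d}",
                contig_id=contig_id,
                start=start,
                end=end,
                strand=str(strands[i]),
                category=GENE_CATEGORIES[int(categories[i])],
            )
        )
    return ReferenceGenome(contigs=((contig_id, sequence),)), genes


def diverge_population(
    ref: ReferenceGenome,
    genes: list[GeneAnnotation],
    spec: CommunitySimSpec,
) -> tuple[ReferenceGenome, list[DeletionRecord]]:
    """Derive the in-situ population: per-base substitutions plus excisions.

    Substitutions hit each retained base independently at rate
    ``1 - target_ani/100`` and always change the base. Deleted genes are
    excised outright — the population genuinely lacks the sequence — and the
    manifest records each gene with its junction position in the diverged
    coordinate frame (used to flag junction-spanning reads in read truth).
    """
    rng = np.random.default_rng(spec.rng_seed + 1)
    gene_ids = {g.gene_id for g in genes}
    if spec.deleted_gene_ids is not None:
        unknown = set(spec.deleted_gene_ids) - gene_ids
        if unknown:
            raise ParameterError(f"deleted_gene_ids not annotated: {sorted(unknown)}")
        deleted_ids = set(spec.deleted_gene_ids)
    else:
        n_del = int(round(spec.deleted_fraction * len(genes)))
        chosen = rng.choice(len(genes), size=n_del, replace=False) if n_del else []
        deleted_ids = {genes[int(i)].gene_id for i in chosen}

    rate = spec.substitution_rate
    new_contigs = []
    manifest: list[DeletionRecord] = []
    by_contig: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        if g.gene_id in deleted_ids:
            by_contig.setdefault(g.contig_id, []).append(g)

    for contig_id, seq in ref.contigs:
        codes = _seq.encode(seq)
        if rate > 0:
            positions = np.flatnonzero(rng.random(codes.size) < rate)
            codes = _seq.substitute(codes, positions, rng)
        removed = 0
        pieces = []
        cursor = 0
        for g in sorted(by_contig.get(contig_id, []), key=lambda g: g.start):
            pieces.append(codes[cursor : g.start])
            manifest.append(
                DeletionRecord(
                    gene_id=g.gene_id,
                    contig_id=contig_id,
                    ref_start=g.start,
                    ref_end=g.end,
                    length=g.length,
                    junction=g.start - removed,
                )
            )
            removed += g.length
            cursor = g.end
        pieces.append(codes[cursor:])
        new_seq = _seq.decode(np.concatenate(pieces) if len(pieces) > 1 else pieces[0])
        new_contigs.append((contig_id, new_seq))
    manifest.sort(key=lambda d: (d.contig_id, d.ref_start))
    return ReferenceGenome(contigs=tuple(new_contigs)), manifest


def simulate_reads(
    population_genome: ReferenceGenome,
    background_genome: ReferenceGenome | None,
    spec: CommunitySimSpec,
    deletions: list[DeletionRecord] | None = None,
) -> tuple[list[tuple[str, str]], list[ReadTruth]]:
    """Draw uniform single-end reads from the population (+ background).

    The on-target read count is Poisson with mean
    ``mean_depth * population_length / read_length`` (Lander–Waterman), and
    each read is independently a background read with probability
    ``background_fraction``. Start positions are uniform per source contig
    (length-weighted across contigs), strands equiprobable, and sequencing
    errors are independent substitutions at ``seq_error_rate``.
    """
    rng = np.random.default_rng(spec.rng_seed + 2)
    rl = spec.read_length
    for genome, label in ((population_genome, "population"),
                          (background_genome, "background")):
        if genome is None:
            continue
        shortest = min(len(s) for _, s in genome.contigs)
        if rl > shortest:
            raise ParameterError(
                f"read_length {rl} exceeds the shortest {label} contig ({shortest} bp)"
            )
    if spec.background_fraction > 0 and background_genome is None:
        raise ParameterError("background_fraction > 0 requires a background genome")

    expected_on_target = spec.mean_depth * population_genome.total_length / rl
    f = spec.background_fraction
    n_total = int(rng.poisson(expected_on_target / (1.0 - f)))
    from_bg = rng.random(n_total) < f if f > 0 else np.zeros(n_total, dtype=bool)

    junctions: dict[str, np.ndarray] = {}
    for d in deletions or []:
        junctions.setdefault(d.contig_id, [])
    for d in deletions or []:
        junctions[d.contig_id].append(d.junction)
    junctions = {c: np.array(sorted(v)) for c, v in junctions.items()}

    def _prep(genome: ReferenceGenome):
        contigs = [(cid, _seq.encode(s)) for cid, s in genome.contigs]
        starts_avail = np.array([c.size - rl + 1 for _, c in contigs], dtype=float)
        return contigs, starts_avail / starts_avail.sum()

    pop_contigs, pop_w = _prep(population_genome)
    bg_contigs, bg_w = _prep(background_genome) if background_genome else (None, None)

    reads: list[tuple[str, str]] = []
    truth: list[ReadTruth] = []
    width = max(6, len(str(max(n_total, 1))))
    for i in range(n_total):
        bg = bool(from_bg[i])
        contigs, w = (bg_contigs, bg_w) if bg else (pop_contigs, pop_w)
        ci = int(rng.choice(len(contigs), p=w))
        cid, codes = contigs[ci]
        start = int(rng.integers(0, codes.size - rl + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        fragment = codes[start : start + rl]
        n_err = 0
        if spec.seq_error_rate > 0:
            err_pos = np.flatnonzero(rng.random(rl) < spec.seq_error_rate)
            n_err = int(err_pos.size)
            fragment = _seq.substitute(fragment, err_pos, rng)
        else:
            fragment = fragment.copy()
        if strand == "-":
            fragment = _seq.revcomp_codes(fragment)
        spans_junction = False
        if not bg and cid in junctions and junctions[cid].size:
            j = junctions[cid]
            spans_junction = bool(((j > start) & (j < start + rl)).any())
        read_id = f"read_{i + 1:0{width}d}"
        reads.append((read_id, _seq.decode(fragment)))
        truth.append(
            ReadTruth(
                read_id=read_id,
                origin_contig="" if bg else cid,
                origin_start=-1 if bg else start,
                strand=strand,
                n_substitutions=n_err,
                from_background=bg,
                overlaps_deleted_gene=spans_junction,
            )
        )
    return reads, truth


@dataclass(frozen=True)
class Community:
    """Everything one synthetic experiment produced, with ground truth."""

    spec: CommunitySimSpec
    reference: ReferenceGenome
    genes: list[GeneAnnotation]
    population: ReferenceGenome
    deletions: list[DeletionRecord]
    background: ReferenceGenome | None
    reads: list[tuple[str, str]]
    truth: list[ReadTruth]

    @property
    def deleted_gene_ids(self) -> set[str]:
        return {d.gene_id for d in self.deletions}


def simulate_community(spec: CommunitySimSpec) -> Community:
    """Run the full generator: reference → diverged population → reads."""
    reference, genes = generate_reference(spec)
    population, deletions = diverge_population(reference, genes, spec)
    background = None
    if spec.background_fraction > 0:
        bg_spec = replace(
            spec,
            n_genes=0,
            deleted_gene_ids=None,
            deleted_fraction=0.0,
            rng_seed=spec.rng_seed + 7_654_321,
        )
        background, _ = generate_reference(bg_spec)
    reads, truth = simulate_reads(population, background, spec, deletions)
    return Community(
        spec=spec,
        reference=reference,
        genes=genes,
        population=population,
        deletions=deletions,
        background=background,
        reads=reads,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Fixture I/O: FASTA + FASTQ + BED6 + TSV, all plain text, exact round-trip.
# ---------------------------------------------------------------------------

_TRUTH_HEADER = (
    "read_id\torigin_contig\torigin_start\tstrand\tn_substitutions"
    "\tfrom_background\toverlaps_deleted_gene"
)
_DELETION_HEADER = "gene_id\tcontig_id\tref_start\tref_end\tlength\tjunction"


def _write_fasta(path: str, genome: ReferenceGenome, width: int = 70) -> None:
    with open(path, "w") as fh:
        for cid, seq in genome.contigs:
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _read_fasta(path: str) -> ReferenceGenome:
    contigs: list[tuple[str, str]] = []
    cid, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if cid is not None:
                    contigs.append((cid, "".join(chunks)))
                cid, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if cid is not None:
        contigs.append((cid, "".join(chunks)))
    return ReferenceGenome(contigs=tuple(contigs))


def write_fixture(
    genome: ReferenceGenome,
    genes: list[GeneAnnotation],
    reads: list[tuple[str, str]],
    truth: list[ReadTruth],
    out_dir: str,
    deletions: list[DeletionRecord] | None = None,
    population: ReferenceGenome | None = None,
    seed: int | None = None,
) -> dict:
    """Write the community to plain-text files and return a file manifest.

    Layout: ``reference.fasta``, ``genes.bed`` (BED6, 0-based half-open,
    category in a sidecar TSV when present), ``reads.fastq`` (Phred+33,
    constant quality 'I'), ``truth.tsv``, ``deletions.tsv``, and optionally
    ``population.fasta``. Reading the files back reproduces the objects.
    """
    try:
        os.makedirs(out_dir, exist_ok=True)
        probe = os.path.join(out_dir, ".write_probe")
        with open(probe, "w"):
            pass
        os.remove(probe)
    except OSError as exc:
        raise OSError(f"cannot write to '{out_dir}': {exc}") from exc

    paths = {
        "reference": os.path.join(out_dir, "reference.fasta"),
        "genes": os.path.join(out_dir, "genes.bed"),
        "reads": os.path.join(out_dir, "reads.fastq"),
        "truth": os.path.join(out_dir, "truth.tsv"),
        "deletions": os.path.join(out_dir, "deletions.tsv"),
    }
    _write_fasta(paths["reference"], genome)
    if population is not None:
        paths["population"] = os.path.join(out_dir, "population.fasta")
        _write_fasta(paths["population"], population)

    with open(paths["genes"], "w") as fh:
        for g in genes:
            fh.write(f"{g.contig_id}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")
    if any(g.category is not None for g in genes):
        paths["categories"] = os.path.join(out_dir, "gene_categories.tsv")
        with open(paths["categories"], "w") as fh:
            fh.write("gene_id\tcategory\n")
            for g in genes:
                if g.category is not None:
                    fh.write(f"{g.gene_id}\t{g.category}\n")

    with open(paths["reads"], "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")

    with open(paths["truth"], "w") as fh:
        fh.write(_TRUTH_HEADER + "\n")
        for t in truth:
            fh.write(
                f"{t.read_id}\t{t.origin_contig}\t{t.origin_start}\t{t.strand}"
                f"\t{t.n_substitutions}\t{int(t.from_background)}"
                f"\t{int(t.overlaps_deleted_gene)}\n"
            )

    with open(paths["deletions"], "w") as fh:
        fh.write(_DELETION_HEADER + "\n")
        for d in deletions or []:
            fh.write(
                f"{d.gene_id}\t{d.contig_id}\t{d.ref_start}\t{d.ref_end}"
                f"\t{d.length}\t{d.junction}\n"
            )

    manifest = {
        "files": {k: os.path.basename(v) for k, v in paths.items()},
        "n_reads": len(reads),
        "n_genes": len(genes),
        "n_deletions": len(deletions or []),
        "seed": seed,
    }
    manifest_path = os.path.join(out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest["manifest_path"] = manifest_path
    return manifest


def read_fixture(out_dir: str) -> dict:
    """Read back a fixture directory written by :func:`write_fixture`."""
    with open(os.path.join(out_dir, "manifest.json")) as fh:
        manifest = json.load(fh)
    files = manifest["files"]
    genome = _read_fasta(os.path.join(out_dir, files["reference"]))
    population = None
    if "population" in files:
        population = _read_fasta(os.path.join(out_dir, files["population"]))

    categories: dict[str, str] = {}
    if "categories" in files:
        with open(os.path.join(out_dir, files["categories"])) as fh:
            next(fh)
            for line in fh:
                gid, cat = line.rstrip("\n").split("\t")
                categories[gid] = cat
    genes = []
    with open(os.path.join(out_dir, files["genes"])) as fh:
        for line in fh:
            cid, start, end, gid, _score, strand = line.rstrip("\n").split("\t")
            genes.append(
                GeneAnnotation(
                    gene_id=gid,
                    contig_id=cid,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    category=categories.get(gid),
                )
            )

    reads = []
    with open(os.path.join(out_dir, files["reads"])) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            fh.readline()
            fh.readline()
            reads.append((header.rstrip("\n")[1:], seq))

    truth = []
    with open(os.path.join(out_dir, files["truth"])) as fh:
        next(fh)
        for line in fh:
            rid, cid, start, strand, nsub, bg, overlap = line.rstrip("\n").split("\t")
            truth.append(
                ReadTruth(
                    read_id=rid,
                    origin_contig=cid,
                    origin_start=int(start),
                    strand=strand,
                    n_substitutions=int(nsub),
                    from_background=bool(int(bg)),
                    overlaps_deleted_gene=bool(int(overlap)),
                )
            )

    deletions = []
    with open(os.path.join(out_dir, files["deletions"])) as fh:
        next(fh)
        for line in fh:
            gid, cid, rs, re_, ln, jc = line.rstrip("\n").split("\t")
            deletions.append(
                DeletionRecord(
                    gene_id=gid,
                    contig_id=cid,
                    ref_start=int(rs),
                    ref_end=int(re_),
                    length=int(ln),
                    junction=int(jc),
                )
            )
    return {
        "genome": genome,
        "population": population,
        "genes": genes,
        "reads": reads,
        "truth": truth,
        "deletions": deletions,
        "manifest": manifest,
    }


@dataclass(frozen=True)
class AlignmentPair:
    """One (read, reference) validation pair with its ground truth."""

    read: str
    reference: str
    planted: bool
    reverse: bool
    n_substitutions: int
    plant_position: int  # -1 for unrelated pairs


def sample_alignment_pairs(
    n_pairs: int,
    seed: int,
    read_length_range: tuple[int, int] = (40, 80),
    reference_length_range: tuple[int, int] = (500, 2000),
    max_substitutions: int = 4,
    planted_fraction: float = 0.6,
) -> list[AlignmentPair]:
    """Random (read, reference) pairs for validating the recruiting aligner
    against an exact-alignment oracle.

    A planted read is a substring of the reference (either strand) carrying
    interior, well-spaced substitutions (>= 2 bp from each end, >= 3 bp
    apart), so its unique optimal ungapped alignment is the full read and
    its identity is unambiguous. Substitution counts are capped below the
    number of disjoint 16 bp windows so an exact seed always survives.
    Unrelated reads are i.i.d. random sequence.
    """
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n_pairs):
        ref_len = int(rng.integers(*reference_length_range, endpoint=True))
        ref = _seq.random_sequence(ref_len, 0.5, rng)
        read_len = int(rng.integers(*read_length_range, endpoint=True))
        if rng.random() < planted_fraction:
            start = int(rng.integers(0, ref_len - read_len + 1))
            codes = _seq.encode(ref[start : start + read_len])
            k_max = min(max_substitutions, read_len // 16 - 1)
            k = int(rng.integers(0, max(k_max, 0) + 1))
            positions: list[int] = []
            while len(positions) < k:
                cand = int(rng.integers(2, read_len - 2))
                if all(abs(cand - q) >= 3 for q in positions):
                    positions.append(cand)
            codes = _seq.substitute(codes, np.array(positions, dtype=int), rng)
            reverse = bool(rng.random() < 0.5)
            if reverse:
                codes = _seq.revcomp_codes(codes)
            pairs.append(
                AlignmentPair(
                    read=_seq.decode(codes),
                    reference=ref,
                    planted=True,
                    reverse=reverse,
                    n_substitutions=k,
                    plant_position=start,
                )
            )
        else:
            pairs.append(
                AlignmentPair(
                    read=_seq.random_sequence(read_len, 0.5, rng),
                    reference=ref,
                    planted=False,
                    reverse=False,
                    n_substitutions=0,
                    plant_position=-1,
                )
            )
    return pairs


def fixture_checksums(out_dir: str) -> dict[str, str]:
    """SHA-256 of every fixture file (determinism checks)."""
    sums = {}
    for name in sorted(os.listdir(out_dir)):
        path = os.path.join(out_dir, name)
        if os.path.isfile(path):
            with open(path, "rb") as fh:
                sums[name] = hashlib.sha256(fh.read()).hexdigest()
    return sums
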