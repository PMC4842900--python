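"""Pipeline orchestration: simulate -> recruit -> profile -> absence -> report.

Configuration is a sectioned plain-text file (``key = value``), every
threshold defaulting to the analysis' published cutoffs. A run writes every
intermediate artifact plus a JSON manifest recording the config hash, seed,
package version, every threshold in effect, and per-stage timings;
re-running the same config reproduces identical outputs.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

from . import __version__
from .absence import fit_skew_normal, gene_absence_test
from .alignment import (
    PRESETS,
    RecruitmentFilter,
    read_alignment_table,
    recruit_reads,
    write_alignment_table,
)
from .coverage import build_profile, segment_coverages
from .errors import GateError, ParameterError, PipelineStageError
from .population import DetectionGates, summarize_population
from .simulate import CommunitySimSpec, simulate_community, write_fixture

__all__ = ["PipelineConfig", "run_pipeline", "generate_report", "load_config"]

log = logging.getLogger("popscan")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration with published defaults."""

    # inputs: either a fixture directory / explicit files, or simulate
    reference_fasta: str | None = None
    genes_bed: str | None = None
    reads_fastq: str | None = None
    alignments_tsv: str | None = None
    simulate: bool = True
    sim: CommunitySimSpec = field(default_factory=CommunitySimSpec)
    # recruitment
    preset: str = "plot"
    seed_length: int = 16
    identity_split: float = 95.0
    window: int = 1000
    segment: int = 500
    # abundance preset (used for relative abundance alongside the plot preset)
    abundance_preset: str = "abundance"
    # gates and test
    ani_min: float = 95.0
    breadth_min: float = 0.90
    depth_min: float = 3.0
    alpha: float = 0.025
    include_zero_segments: bool = True
    # bookkeeping
    rng_seed: int = 0
    out_dir: str = "popscan_run"

    def __post_init__(self):
        if self.preset not in PRESETS or self.abundance_preset not in PRESETS:
            raise ParameterError(
                f"preset must be one of {sorted(PRESETS)}"
            )
        if not (0.0 < self.alpha < 1.0):
            raise ParameterError("alpha must be in (0, 1)")
        for name, lo, hi, v in (
            ("ani_min", 0.0, 100.0, self.ani_min),
            ("breadth_min", 0.0, 1.0, self.breadth_min),
            ("identity_split", 0.0, 100.0, self.identity_split),
        ):
            if not (lo <= v <= hi):
                raise ParameterError(f"{name} must be within [{lo}, {hi}]")
        if self.depth_min < 0 or self.segment < 1 or self.window < 1:
            raise ParameterError("depth_min/segment/window out of range")

    @property
    def gates(self) -> DetectionGates:
        return DetectionGates(
            ani_min=self.ani_min,
            breadth_min=self.breadth_min,
            depth_min=self.depth_min,
        )


_SIM_KEYS = {f.strip() for f in (
    "genome_length n_genes gene_length_min gene_length_max gene_length_mean "
    "gc_fraction target_ani deleted_fraction mean_depth read_length "
    "seq_error_rate background_fraction"
).split()}
_RUN_KEYS = {
    "reference_fasta", "genes_bed", "reads_fastq", "alignments_tsv",
    "simulate", "preset", "seed_length", "identity_split", "window",
    "segment", "abundance_preset", "ani_min", "breadth_min", "depth_min",
    "alpha", "include_zero_segments", "rng_seed", "out_dir",
}


def load_config(path: str) -> PipelineConfig:
    """Parse a sectioned ``key = value`` config file; unknown keys rejected."""
    parser = configparser.ConfigParser()
    with open(path) as fh:
        parser.read_file(fh)
    known_sections = {"run", "simulate"}
    unknown = set(parser.sections()) - known_sections
    if unknown:
        raise ParameterError(f"unknown config sections: {sorted(unknown)}")

    kwargs: dict = {}
    if parser.has_section("run"):
        for key, value in parser.items("run"):
            if key not in _RUN_KEYS:
                raise ParameterError(f"unknown config key [run] {key}")
            if key in ("simulate", "include_zero_segments"):
                kwargs[key] = parser.getboolean("run", key)
            elif key in ("seed_length", "window", "segment", "rng_seed"):
                kwargs[key] = int(value)
            elif key in ("identity_split", "ani_min", "breadth_min",
                         "depth_min", "alpha"):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
    sim_kwargs: dict = {}
    if parser.has_section("simulate"):
        gl: dict[str, int] = {}
        for key, value in parser.items("simulate"):
            if key not in _SIM_KEYS:
                raise ParameterError(f"unknown config key [simulate] {key}")
            if key.startswith("gene_length_"):
                gl[key.split("_")[-1]] = int(value)
            elif key in ("genome_length", "n_genes", "read_length"):
                sim_kwargs[key] = int(value)
            else:
                sim_kwargs[key] = float(value)
        if gl:
            default = CommunitySimSpec().gene_length_distribution
            sim_kwargs["gene_length_distribution"] = (
                gl.get("min", default[0]),
                gl.get("max", default[1]),
                gl.get("mean", default[2]),
            )
    seed = kwargs.get("rng_seed", 0)
    kwargs["sim"] = CommunitySimSpec(rng_seed=seed, **sim_kwargs)
    return PipelineConfig(**kwargs)


def _config_hash(config: PipelineConfig) -> str:
    # out_dir is a location, not part of the computation's identity.
    blob = json.dumps(
        {**{k: v for k, v in asdict(config).items()
            if k not in ("sim", "out_dir")},
         "sim": asdict(config.sim)},
        sort_keys=True, default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order; returns (and writes) the run manifest."""
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    handler = logging.FileHandler(os.path.join(out, "run.log"))
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    manifest: dict = {
        "popscan_version": __version__,
        "config_hash": _config_hash(config),
        "rng_seed": config.rng_seed,
        "thresholds": {
            "preset": config.preset,
            "preset_min_length": PRESETS[config.preset].min_length,
            "preset_min_identity": PRESETS[config.preset].min_identity,
            "abundance_preset": config.abundance_preset,
            "abundance_min_length": PRESETS[config.abundance_preset].min_length,
            "abundance_min_identity": PRESETS[config.abundance_preset].min_identity,
            "identity_split": config.identity_split,
            "window": config.window,
            "segment": config.segment,
            "ani_min": config.ani_min,
            "breadth_min": config.breadth_min,
            "depth_min": config.depth_min,
            "alpha": config.alpha,
            "seed_length": config.seed_length,
            "include_zero_segments": config.include_zero_segments,
        },
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            t0 = time.monotonic()
            log.info("stage %s: start", name)
            try:
                outputs = fn()
            except Exception as exc:
                manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                _write_manifest(out, manifest)
                log.removeHandler(handler)
                handler.close()
                raise PipelineStageError(name, exc) from exc
            manifest["stages"][name] = {
                "status": "ok",
                "outputs": outputs,
                "seconds": round(time.monotonic() - t0, 3),
            }
            log.info("stage %s: done (%.2fs)", name, time.monotonic() - t0)
            return outputs

        return deco

    state: dict = {}

    @stage("simulate")
    def _simulate():
        if not config.simulate:
            fixture = {
                "genome": None, "genes": [], "reads": [], "truth": [],
                "deletions": [],
            }
            if config.reference_fasta is None:
                raise ParameterError(
                    "simulate = false requires reference_fasta (and reads or "
                    "alignments)"
                )
            from .simulate import _read_fasta  # shared FASTA reader

            fixture["genome"] = _read_fasta(config.reference_fasta)
            if config.genes_bed:
                from .simulate import GeneAnnotation

                genes = []
                with open(config.genes_bed) as fh:
                    for line in fh:
                        parts = line.rstrip("\n").split("\t")
                        genes.append(GeneAnnotation(
                            gene_id=parts[3], contig_id=parts[0],
                            start=int(parts[1]), end=int(parts[2]),
                            strand=parts[5] if len(parts) > 5 else "+",
                        ))
                fixture["genes"] = genes
            if config.reads_fastq:
                reads = []
                with open(config.reads_fastq) as fh:
                    while True:
                        header = fh.readline()
                        if not header:
                            break
                        seq = fh.readline().strip()
                        fh.readline(); fh.readline()
                        reads.append((header.strip()[1:], seq))
                fixture["reads"] = reads
            state.update(fixture)
            return {"source": "external inputs"}
        community = simulate_community(config.sim)
        state["genome"] = community.reference
        state["genes"] = community.genes
        state["reads"] = community.reads
        state["truth"] = community.truth
        state["deletions"] = community.deletions
        fx_dir = os.path.join(out, "fixture")
        write_fixture(
            community.reference, community.genes, community.reads,
            community.truth, fx_dir, deletions=community.deletions,
            population=community.population, seed=config.sim.rng_seed,
        )
        return {"fixture_dir": "fixture", "n_reads": len(community.reads)}

    @stage("recruit")
    def _recruit():
        path = os.path.join(out, "alignments.tsv")
        if config.alignments_tsv:
            records = read_alignment_table(config.alignments_tsv)
        else:
            records = recruit_reads(
                state["reads"], state["genome"], PRESETS[config.preset],
                seed_length=config.seed_length,
            )
        write_alignment_table(records, path)
        state["records"] = records
        return {"alignments": "alignments.tsv", "n_records": len(records)}

    @stage("profile")
    def _profile():
        profile = build_profile(
            state["records"], state["genome"],
            identity_split=config.identity_split,
            window=config.window, segment=config.segment,
        )
        state["profile"] = profile
        ab_filter: RecruitmentFilter = PRESETS[config.abundance_preset]
        n_ab = sum(
            1 for r in state["records"]
            if ab_filter.passes(r.alignment_length, r.percent_identity)
        )
        n_total = len(state["reads"]) if state.get("reads") else None
        summary = summarize_population(
            state["records"], profile,
            n_total_reads=n_total,
            n_recruited_under_preset=n_ab if n_total else None,
            gates=config.gates,
        )
        state["summary"] = summary
        path = os.path.join(out, "summary.tsv")
        with open(path, "w") as fh:
            fh.write("ani\tbreadth\tmean_depth\trelative_abundance\tdetected\treason\n")
            ra = "" if summary.relative_abundance is None else (
                f"{summary.relative_abundance:.6f}")
            fh.write(
                f"{summary.ani:.4f}\t{summary.breadth:.6f}\t{summary.mean_depth:.4f}"
                f"\t{ra}\t{int(summary.detected)}\t{summary.reason}\n"
            )
        return {"summary": "summary.tsv", "detected": summary.detected,
                "reason": summary.reason}

    @stage("absence")
    def _absence():
        profile = state["profile"]
        seg = segment_coverages(profile)
        values = [s.mean_depth for s in seg]
        if not config.include_zero_segments:
            values = [v for v in values if v > 0]
        params = fit_skew_normal(values)
        fit_path = os.path.join(out, "skew_normal_fit.json")
        with open(fit_path, "w") as fh:
            json.dump(
                {"xi": params.xi, "omega": params.omega, "alpha": params.alpha,
                 "n_segments": params.n_segments, "loglik": params.loglik},
                fh, indent=2,
            )
            fh.write("\n")
        try:
            calls = gene_absence_test(
                state["genes"], profile, params,
                summary=state["summary"], alpha=config.alpha,
                gates=config.gates,
            )
        except GateError as exc:
            state["calls"] = []
            return {"fit": "skew_normal_fit.json", "skipped": str(exc)}
        state["calls"] = calls
        state["fit"] = params
        path = os.path.join(out, "gene_absence.tsv")
        with open(path, "w") as fh:
            fh.write(
                "gene_id\tcontig\tstart\tend\tlength\tmean_coverage\traw_p"
                "\tlength_adjusted_p\tbh_adjusted_p\tis_candidate\tabsent\n"
            )
            for c in calls:
                fh.write(
                    f"{c.gene_id}\t{c.contig_id}\t{c.start}\t{c.end}"
                    f"\t{c.gene_length}\t{c.mean_coverage:.4f}\t{c.raw_p:.6g}"
                    f"\t{c.length_adjusted_p:.6g}\t{c.bh_adjusted_p:.6g}"
                    f"\t{int(c.is_candidate)}\t{int(c.absent)}\n"
                )
        n_absent = sum(c.absent for c in calls)
        return {"fit": "skew_normal_fit.json", "calls": "gene_absence.tsv",
                "n_absent": n_absent}

    @stage("report")
    def _report():
        return generate_report(state, out, manifest)

    _write_manifest(out, manifest)
    log.removeHandler(handler)
    handler.close()
    return manifest


def _write_manifest(out_dir: str, manifest: dict) -> None:
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def generate_report(state: dict, out: str, manifest: dict) -> dict:
    """Emit plot-ready TSV series + a one-page text summary.

    Three panel series mirror a fragment recruitment plot: the windowed
    position histogram (coverage by identity class), the per-read
    recruitment points (position x identity), and the identity histogram.
    """
    report_dir = os.path.join(out, "report")
    os.makedirs(report_dir, exist_ok=True)
    records = state.get("records", [])
    outputs: dict = {}
    if not records:
        with open(os.path.join(report_dir, "summary.txt"), "w") as fh:
            fh.write("no recruitment\n")
        return {"summary": "report/summary.txt", "note": "no recruitment"}

    profile = state["profile"]
    with open(os.path.join(report_dir, "position_histogram.tsv"), "w") as fh:
        fh.write("contig\twindow_start\thigh_identity_cov\tlow_identity_cov\n")
        for cid in sorted(profile.contig_lengths):
            track = profile.windowed_track(cid)
            for i, (hi, lo) in enumerate(track):
                fh.write(f"{cid}\t{i * profile.window_size}\t{hi:.4f}\t{lo:.4f}\n")
    with open(os.path.join(report_dir, "recruitment_points.tsv"), "w") as fh:
        fh.write("contig\ts_start\ts_end\tpercent_identity\n")
        for r in records:
            lo, hi = r.subject_span
            fh.write(f"{r.subject_id}\t{lo}\t{hi}\t{r.percent_identity:.2f}\n")
    with open(os.path.join(report_dir, "id_histogram.tsv"), "w") as fh:
        fh.write("identity_bin\tbase_positions\n")
        for b, v in enumerate(profile.identity_histogram):
            if v:
                fh.write(f"{b}\t{int(v)}\n")
    outputs.update(
        position_histogram="report/position_histogram.tsv",
        recruitment_points="report/recruitment_points.tsv",
        id_histogram="report/id_histogram.tsv",
    )

    truth_deleted = {d.gene_id for d in state.get("deletions", [])}
    summary = state.get("summary")
    calls = state.get("calls", [])
    with open(os.path.join(report_dir, "summary.txt"), "w") as fh:
        fh.write(f"popscan {__version__} run summary\n")
        fh.write("=" * 40 + "\n")
        if summary is not None:
            ra = ("n/a" if summary.relative_abundance is None
                  else f"{100 * summary.relative_abundance:.2f}%")
            fh.write(
                f"ANI: {summary.ani:.2f}%\nbreadth: {summary.breadth:.4f}\n"
                f"mean depth: {summary.mean_depth:.2f}x\n"
                f"relative abundance: {ra}\n"
                f"detected: {summary.detected} ({summary.reason})\n"
            )
        absent = [c for c in calls if c.absent]
        fh.write(f"\nabsent genes called: {len(absent)}\n")
        if absent:
            fh.write("gene_id\tlength\tmean_cov\tbh_p" +
                     ("\ttruly_deleted\n" if truth_deleted else "\n"))
            for c in absent:
                line = (f"{c.gene_id}\t{c.gene_length}\t{c.mean_coverage:.3f}"
                        f"\t{c.bh_adjusted_p:.3g}")
                if truth_deleted:
                    line += f"\t{int(c.gene_id in truth_deleted)}"
                fh.write(line + "\n")
        if calls and truth_deleted:
            called = {c.gene_id for c in absent}
            tp = len(called & truth_deleted)
            fh.write(
                f"\ntruth agreement: {tp}/{len(truth_deleted)} deleted genes "
                f"called, {len(called - truth_deleted)} false calls\n"
            )
    outputs["summary"] = "report/summary.txt"
    return outputs
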