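"""End-to-end pipeline: simulate (or ingest) -> call borders -> annotate ->
compare -> report.

A single global seed deterministically derives one sub-seed per stage and per
sample (via :class:`numpy.random.SeedSequence` spawn keys), so adding a sample
never changes the data of earlier samples and identical config + seed gives
byte-identical outputs. All output files are written only after every stage
has completed, so a failing stage leaves no partial outputs.
"""
from __future__ import annotations

import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import io as lio
from .borders import ChromomereCall, ClusteringParams, call_borders
from .compare import ComparisonConfig, ComparisonReport, compare_chromomeres
from .domains import CompartmentProfile, TadSet
from .features import FeatureProfile, FeatureThresholds, annotate_chromomere
from .intervals import GenomeMap, GenomicInterval, ReadPlacement
from .simulate import (
    ChromomereMapSpec,
    ChromomereSite,
    ClassProfile,
    DissectionSimSpec,
    TadSetSpec,
    generate_chromomere_map,
    generate_compartment_profile,
    generate_gene_repeat_annotations,
    generate_tad_set,
    neighbors_in_map,
)

logger = logging.getLogger("lbcmap")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass(frozen=True)
class SyntheticSpec:
    """What to simulate in synthetic mode."""

    genome: Mapping[str, int]
    common_span_range: tuple[int, int] = (1_500_000, 3_500_000)
    marker_span_range: tuple[int, int] = (4_000_000, 5_000_000)
    marker_fraction: float = 0.1
    n_reads: int = 1000
    contamination_rate: float = 0.02
    spillover_rate: float = 0.05
    duplicate_rate: float = 0.1
    bin_size: int = 100_000
    mean_block_bins: int = 12
    tad_presets: tuple[str, ...] = ("DI-like", "Armatus-like")
    class_profiles: Mapping[str, ClassProfile] | None = None


@dataclass(frozen=True)
class RealPaths:
    """Input files in real mode; reads are one BED per dissected sample."""

    chrom_sizes: str
    reads: Mapping[str, str]  # sample_id -> BED path
    compartments: str
    tad_sets: Mapping[str, str]  # set name -> BED path
    genes: str | None = None
    repeats: str | None = None


@dataclass(frozen=True)
class PipelineConfig:
    mode: str = "synthetic"  # "synthetic" or "real"
    seed: int = 0
    synthetic: SyntheticSpec | None = None
    real: RealPaths | None = None
    clustering: ClusteringParams = field(default_factory=ClusteringParams)
    comparison: ComparisonConfig = field(default_factory=ComparisonConfig)
    feature_thresholds: FeatureThresholds = field(default_factory=FeatureThresholds)

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "synthetic" and self.synthetic is None:
            raise ValueError("synthetic mode requires a 'synthetic' section")
        if self.mode == "real" and self.real is None:
            raise ValueError("real mode requires a 'real' section")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PipelineConfig":
        kwargs: dict = {}
        kwargs["mode"] = raw.get("mode", "synthetic")
        kwargs["seed"] = int(raw.get("seed", 0))
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = dict(raw["synthetic"])
            if "class_profiles" in syn and syn["class_profiles"] is not None:
                syn["class_profiles"] = {
                    kind: ClassProfile(**params)
                    for kind, params in syn["class_profiles"].items()
                }
            for key in ("common_span_range", "marker_span_range", "tad_presets"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            kwargs["synthetic"] = SyntheticSpec(**syn)
        if "real" in raw and raw["real"] is not None:
            kwargs["real"] = RealPaths(**raw["real"])
        if "clustering" in raw:
            kwargs["clustering"] = ClusteringParams(**raw["clustering"])
        if "comparison" in raw:
            kwargs["comparison"] = ComparisonConfig(**raw["comparison"])
        if "feature_thresholds" in raw:
            kwargs["feature_thresholds"] = FeatureThresholds(**raw["feature_thresholds"])
        return cls(**kwargs)


def derive_seed(global_seed: int, *key: object) -> int:
    """Stable per-stage / per-sample sub-seed below 2**31.

    Uses CRC32 of the key parts (process-independent, unlike ``hash``) as a
    SeedSequence spawn key, so adding a sample never perturbs earlier ones.
    """
    hashed = tuple(zlib.crc32(str(k).encode()) for k in key)
    seq = np.random.SeedSequence(entropy=global_seed, spawn_key=hashed)
    return int(seq.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class SyntheticInputs:
    """Everything the analysis stages consume, plus the ground truth."""

    genome: GenomeMap
    sites: tuple[ChromomereSite, ...]
    reads: Mapping[str, tuple[ReadPlacement, ...]]  # chromomere_id -> reads
    profiles: Mapping[str, CompartmentProfile]
    tadsets: tuple[TadSet, ...]
    genes: tuple[GenomicInterval, ...]
    repeats: tuple[GenomicInterval, ...]


_PRESETS = {
    "DI-like": TadSetSpec.di_like,
    "Armatus-like": TadSetSpec.armatus_like,
}


def build_synthetic_inputs(spec: SyntheticSpec, seed: int) -> SyntheticInputs:
    """Generate one coherent synthetic study from a single global seed."""
    genome = GenomeMap(spec.genome)
    sites = generate_chromomere_map(
        ChromomereMapSpec(
            genome=genome,
            common_span_range=spec.common_span_range,
            marker_span_range=spec.marker_span_range,
            marker_fraction=spec.marker_fraction,
            seed=derive_seed(seed, "map"),
        )
    )
    reads: dict[str, tuple[ReadPlacement, ...]] = {}
    for i, site in enumerate(sites):
        sim = DissectionSimSpec(
            n_reads=spec.n_reads,
            contamination_rate=spec.contamination_rate,
            spillover_rate=spec.spillover_rate,
            duplicate_rate=spec.duplicate_rate,
            seed=derive_seed(seed, "sample", site.chromomere_id),
        )
        reads[site.chromomere_id] = tuple(
            simulate_sample_for_site(sites, i, sim, genome)
        )
    profiles = generate_compartment_profile(
        genome, spec.bin_size, spec.mean_block_bins,
        seed=derive_seed(seed, "compartments"),
    )
    tadsets = tuple(
        generate_tad_set(genome, _PRESETS[name](seed=derive_seed(seed, "tads", name)))
        for name in spec.tad_presets
    )
    genes, repeats = generate_gene_repeat_annotations(
        sites, spec.class_profiles, seed=derive_seed(seed, "annotations")
    )
    return SyntheticInputs(
        genome=genome, sites=tuple(sites), reads=reads, profiles=profiles,
        tadsets=tadsets, genes=tuple(genes), repeats=tuple(repeats),
    )


def simulate_sample_for_site(
    sites: Sequence[ChromomereSite],
    index: int,
    sim: DissectionSimSpec,
    genome: GenomeMap,
) -> list[ReadPlacement]:
    from .simulate import simulate_dissection_sample

    site = sites[index]
    return simulate_dissection_sample(
        site.interval, neighbors_in_map(sites, index), sim, genome,
        sample_id=site.chromomere_id,
    )


@dataclass(frozen=True)
class PipelineResult:
    calls: tuple[ChromomereCall, ...]
    features: tuple[FeatureProfile, ...]
    report: ComparisonReport
    truth: tuple[ChromomereSite, ...] | None  # synthetic mode only
    outdir: Path


def _load_real_inputs(paths: RealPaths):
    genome = lio.read_chrom_sizes(paths.chrom_sizes)
    reads = {
        sample: tuple(lio.read_reads(path, sample, genome))
        for sample, path in paths.reads.items()
    }
    profiles = lio.read_compartment_profile(paths.compartments, genome)
    tadsets = tuple(
        lio.read_tad_set(path, name, genome)
        for name, path in paths.tad_sets.items()
    )
    genes = tuple(lio.read_intervals(paths.genes, genome)) if paths.genes else ()
    repeats = tuple(lio.read_intervals(paths.repeats, genome)) if paths.repeats else ()
    return genome, reads, profiles, tadsets, genes, repeats


def _stage(name: str):
    """Decorator-free stage guard: re-raise any error naming the stage."""
    class _Guard:
        def __enter__(self):
            logger.info("stage %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Guard()


def run_pipeline(
    config: PipelineConfig, outdir: str | Path, seed: int | None = None
) -> PipelineResult:
    """Run the full pipeline and write its outputs under ``outdir``.

    Outputs: ``calls.bed`` + ``calls.tsv`` (called chromomeres with QC),
    ``report.tsv`` + ``summary.tsv`` (domain comparison), ``features.tsv``
    (gene/repeat profiles), ``run_log.yaml``; in synthetic mode additionally
    ``truth_map.bed`` and ``border_errors.tsv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed

    truth: tuple[ChromomereSite, ...] | None = None
    with _stage("inputs"):
        if config.mode == "synthetic":
            assert config.synthetic is not None
            inputs = build_synthetic_inputs(config.synthetic, seed)
            genome, reads = inputs.genome, inputs.reads
            profiles, tadsets = inputs.profiles, inputs.tadsets
            genes, repeats = inputs.genes, inputs.repeats
            truth = inputs.sites
        else:
            assert config.real is not None
            genome, reads, profiles, tadsets, genes, repeats = _load_real_inputs(
                config.real
            )

    with _stage("border_calling"):
        calls = tuple(
            call_borders(sample_id, sample_reads, config.clustering)
            for sample_id, sample_reads in reads.items()
        )

    with _stage("feature_profiles"):
        features = tuple(
            annotate_chromomere(call, list(genes), list(repeats),
                                config.feature_thresholds)
            for call in calls
            if not call.ambiguous
        )

    with _stage("domain_comparison"):
        included = (
            calls
            if config.comparison.include_ambiguous
            else tuple(c for c in calls if not c.ambiguous)
        )
        report = compare_chromomeres(included, profiles, list(tadsets),
                                     config.comparison)

    with _stage("report"):
        _write_outputs(outdir, config, seed, calls, features, report, truth)

    return PipelineResult(calls=calls, features=features, report=report,
                          truth=truth, outdir=outdir)


def _write_outputs(outdir, config, seed, calls, features, report, truth) -> None:
    lio.write_intervals(
        [c.interval for c in calls],
        outdir / "calls.bed",
        names=[c.sample_id for c in calls],
        scores=[c.n_reads_main for c in calls],
    )
    lio.write_calls(calls, outdir / "calls.tsv")
    lio.write_report(report, outdir / "report.tsv", outdir / "summary.tsv")

    with open(outdir / "features.tsv", "w") as handle:
        handle.write("sample_id\tgene_count\tgene_density\trepeat_fraction\tclass\n")
        for f in features:
            handle.write(
                f"{f.sample_id}\t{f.gene_count}\t{f.gene_density:.6f}\t"
                f"{f.repeat_fraction:.6f}\t{f.class_label}\n"
            )

    if truth is not None:
        lio.write_intervals(
            [s.interval for s in truth],
            outdir / "truth_map.bed",
            names=[f"{s.chromomere_id}|{s.kind}" for s in truth],
        )
        by_id = {c.sample_id: c for c in calls}
        with open(outdir / "border_errors.tsv", "w") as handle:
            handle.write(
                "chromomere_id\ttrue_start\ttrue_end\tcalled_start\tcalled_end\t"
                "err_left\terr_right\tambiguous\n"
            )
            for site in truth:
                call = by_id[site.chromomere_id]
                handle.write(
                    f"{site.chromomere_id}\t{site.interval.start}\t"
                    f"{site.interval.end}\t{call.interval.start}\t"
                    f"{call.interval.end}\t"
                    f"{abs(call.interval.start - site.interval.start)}\t"
                    f"{abs(call.interval.end - site.interval.end)}\t"
                    f"{'true' if call.ambiguous else 'false'}\n"
                )

    versions = _versions()
    log = {
        "seed": seed,
        "config": _config_dict(config),
        "versions": versions,
        "n_calls": len(calls),
        "n_included": report.summary.n_included,
    }
    with open(outdir / "run_log.yaml", "w") as handle:
        yaml.safe_dump(log, handle, sort_keys=True)


def _config_dict(config: PipelineConfig) -> dict:
    raw = asdict(config)
    if raw.get("synthetic") and raw["synthetic"].get("genome") is not None:
        raw["synthetic"]["genome"] = dict(raw["synthetic"]["genome"])
    return raw


def _versions() -> dict[str, str]:
    import pandas

    from . import __version__

    return {
        "lbcmap": __version__,
        "numpy": np.__version__,
        "pandas": pandas.__version__,
    }
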