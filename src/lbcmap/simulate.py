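"""Synthetic inputs with the statistical structure the analysis assumes.

The generators stand in for the study's raw inputs: a chromomere tiling of a
chromosome (adjacent microdissection targets), mapped-read samples per
dissected chromomere (with PCR duplicates, whole-chromosome contamination and
spillover into the neighboring chromomeres), a binned A/B compartment profile,
two TAD call sets of different granularity, and gene/repeat annotations with
class-dependent density.

Every generator takes an explicit integer seed and is deterministic given it;
there is no global random state.
"""
from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .domains import CompartmentProfile, TadSet
from .intervals import GenomicInterval, GenomeMap, ReadPlacement

MB = 1_000_000

COMMON = "common"
MARKER = "marker"


@dataclass(frozen=True)
class ChromomereSite:
    """One entry of a ground-truth chromomere map."""

    chromomere_id: str
    interval: GenomicInterval
    kind: str  # "common" or "marker"


@dataclass(frozen=True)
class ChromomereMapSpec:
    """Tiling parameters for a synthetic chromomere map.

    Defaults mirror the measured size classes: common chromomeres span
    1.5-3.5 Mb, large loopless marker chromomeres 4-5 Mb.
    """

    genome: GenomeMap
    common_span_range: tuple[int, int] = (1_500_000, 3_500_000)
    marker_span_range: tuple[int, int] = (4_000_000, 5_000_000)
    marker_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.common_span_range, self.marker_span_range):
            if not 0 < lo < hi:
                raise ValueError("span ranges need 0 < min < max")
        if not 0.0 <= self.marker_fraction <= 1.0:
            raise ValueError("marker_fraction must be in [0, 1]")


@dataclass(frozen=True)
class DissectionSimSpec:
    """Read-sample model for one microdissected chromomere.

    Fragment lengths follow a triangular law (min 150, mode 200, max 350 bp),
    matching the library's observed range and peak. ``contamination_rate``
    reads map uniformly anywhere on the chromosome; ``spillover_rate`` reads
    map into a randomly chosen adjacent chromomere (the FISH-observed signal
    in neighbors); ``duplicate_rate`` is the chance a read is an exact-position
    PCR copy of an earlier read.
    """

    n_reads: int = 1000
    fragment_length: tuple[int, int, int] = (150, 200, 350)  # (min, mode, max)
    contamination_rate: float = 0.02
    spillover_rate: float = 0.05
    duplicate_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if self.contamination_rate + self.spillover_rate >= 1.0:
            raise ValueError("contamination_rate + spillover_rate must be < 1")
        lo, mode, hi = self.fragment_length
        if not lo <= mode <= hi or lo <= 0:
            raise ValueError("fragment_length must satisfy 0 < min <= mode <= max")


@dataclass(frozen=True)
class TadSetSpec:
    """Size model for one synthetic TAD call set.

    TAD lengths are gamma-distributed with mean ``mean_tad_length`` and
    coefficient of variation ``length_dispersion``; consecutive TADs are
    separated by exponentially distributed gaps of mean ``boundary_gap``.
    """

    name: str
    mean_tad_length: int
    length_dispersion: float = 0.4
    boundary_gap: int = 0
    min_tad_length: int = 5_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_tad_length <= 0:
            raise ValueError("mean_tad_length must be positive")
        if self.boundary_gap < 0:
            raise ValueError("boundary_gap must be >= 0")
        if self.length_dispersion <= 0:
            raise ValueError("length_dispersion must be positive")

    @classmethod
    def di_like(cls, seed: int = 0) -> "TadSetSpec":
        """Coarse preset (directionality-index-style calls, mean 1.0 Mb)."""
        return cls(name="DI-like", mean_tad_length=1_000_000,
                   length_dispersion=0.4, boundary_gap=50_000, seed=seed)

    @classmethod
    def armatus_like(cls, seed: int = 0) -> "TadSetSpec":
        """Fine preset (Armatus-style calls, mean 0.4 Mb)."""
        return cls(name="Armatus-like", mean_tad_length=400_000,
                   length_dispersion=0.4, boundary_gap=10_000, seed=seed)


@dataclass(frozen=True)
class ClassProfile:
    """Annotation density for one chromomere class."""

    gene_density: float  # genes per Mb
    repeat_fraction: float  # target covered-base fraction

    def __post_init__(self) -> None:
        if self.gene_density < 0:
            raise ValueError("gene_density must be >= 0")
        if not 0.0 <= self.repeat_fraction < 1.0:
            raise ValueError("repeat_fraction must be in [0, 1)")


#: Default class profiles: common chromomeres are gene-dense and repeat-poor,
#: marker chromomeres nearly gene-free and strongly repeat-enriched.
DEFAULT_CLASS_PROFILES: dict[str, ClassProfile] = {
    COMMON: ClassProfile(gene_density=5.0, repeat_fraction=0.1),
    MARKER: ClassProfile(gene_density=0.5, repeat_fraction=0.5),
}


def generate_chromomere_map(spec: ChromomereMapSpec) -> list[ChromomereSite]:
    """Tile every chromosome of the genome left-to-right with chromomeres.

    Spans are drawn uniformly from the class range; each chromomere is a
    marker with probability ``marker_fraction``. The tiling is gap-free and
    overlap-free; the last chromomere is truncated at the chromosome end.
    """
    rng = np.random.default_rng(spec.seed)
    sites: list[ChromomereSite] = []
    min_span = spec.common_span_range[0]
    if spec.marker_fraction >= 1.0:
        min_span = spec.marker_span_range[0]
    for chrom, length in spec.genome.items():
        if length < min_span:
            raise ValueError(
                f"chromosome {chrom!r} ({length} bp) is shorter than the "
                f"minimal chromomere span ({min_span} bp)"
            )
        pos = 0
        index = 0
        while pos < length:
            is_marker = rng.random() < spec.marker_fraction
            lo, hi = (spec.marker_span_range if is_marker
                      else spec.common_span_range)
            span = int(rng.integers(lo, hi, endpoint=True))
            end = min(pos + span, length)
            index += 1
            sites.append(
                ChromomereSite(
                    chromomere_id=f"{chrom}_cm{index:03d}",
                    interval=GenomicInterval(chrom, pos, end),
                    kind=MARKER if is_marker else COMMON,
                )
            )
            pos = end
    return sites


def neighbors_in_map(
    sites: Sequence[ChromomereSite], index: int
) -> tuple[GenomicInterval | None, GenomicInterval | None]:
    """Left/right neighbor intervals of ``sites[index]`` on the same chromosome."""
    site = sites[index]
    left = sites[index - 1].interval if index > 0 else None
    if left is not None and left.chrom != site.interval.chrom:
        left = None
    right = sites[index + 1].interval if index + 1 < len(sites) else None
    if right is not None and right.chrom != site.interval.chrom:
        right = None
    return left, right


def _draw_fragment_length(rng: np.random.Generator, model: tuple[int, int, int]) -> int:
    lo, mode, hi = model
    return int(round(rng.triangular(lo, mode, hi)))


def simulate_dissection_sample(
    true_interval: GenomicInterval,
    neighbors: tuple[GenomicInterval | None, GenomicInterval | None],
    spec: DissectionSimSpec,
    genome: GenomeMap,
    sample_id: str = "sample",
) -> list[ReadPlacement]:
    """Simulate the mapped reads of one dissected chromomere.

    Each read starts uniformly in the true chromomere with probability
    ``1 - c - s``, uniformly anywhere on the chromosome with probability ``c``
    (contamination), or uniformly in a randomly chosen adjacent chromomere
    with probability ``s`` (spillover). If no neighbor exists, spillover draws
    fall back to the true interval. Reads are clipped at the chromosome end.
    """
    genome.validate_interval(true_interval)
    rng = np.random.default_rng(spec.seed)
    chrom_len = genome[true_interval.chrom]
    available = [n for n in neighbors if n is not None]
    reads: list[ReadPlacement] = []
    for i in range(spec.n_reads):
        if reads and rng.random() < spec.duplicate_rate:
            copy_of = reads[int(rng.integers(0, len(reads)))]
            reads.append(replace(copy_of, name=f"{sample_id}_r{i:05d}"))
            continue
        u = rng.random()
        if u < spec.contamination_rate:
            source = GenomicInterval(true_interval.chrom, 0, chrom_len)
        elif u < spec.contamination_rate + spec.spillover_rate and available:
            source = available[int(rng.integers(0, len(available)))]
        else:
            source = true_interval
        start = int(rng.integers(source.start, source.end))
        length = _draw_fragment_length(rng, spec.fragment_length)
        end = min(start + length, chrom_len)
        if end <= start:  # fully clipped; place the minimal 1 bp read
            end = start + 1
        reads.append(
            ReadPlacement(
                interval=GenomicInterval(true_interval.chrom, start, end),
                sample_id=sample_id,
                name=f"{sample_id}_r{i:05d}",
            )
        )
    return reads


def generate_compartment_profile(
    genome: GenomeMap,
    bin_size: int = 100_000,
    mean_block_bins: int = 12,
    seed: int = 0,
) -> dict[str, CompartmentProfile]:
    """Alternating A/B block profiles covering each chromosome.

    Block lengths are a geometric number of bins (mean ``mean_block_bins``)
    times ``bin_size``; all internal boundaries are bin-aligned and the blocks
    cover the chromosome completely (the last block is truncated at the end).
    """
    if mean_block_bins < 1:
        raise ValueError("mean_block_bins must be >= 1")
    rng = np.random.default_rng(seed)
    profiles: dict[str, CompartmentProfile] = {}
    for chrom, length in genome.items():
        label = "A" if rng.random() < 0.5 else "B"
        blocks: list[tuple[GenomicInterval, str]] = []
        pos = 0
        while pos < length:
            n_bins = int(rng.geometric(1.0 / mean_block_bins))
            end = min(pos + n_bins * bin_size, length)
            blocks.append((GenomicInterval(chrom, pos, end), label))
            label = "B" if label == "A" else "A"
            pos = end
        profiles[chrom] = CompartmentProfile.from_blocks(chrom, blocks, bin_size)
    return profiles


def generate_tad_set(genome: GenomeMap, spec: TadSetSpec) -> TadSet:
    """Sorted, disjoint TADs over every chromosome, per the size model."""
    rng = np.random.default_rng(spec.seed)
    shape = 1.0 / spec.length_dispersion**2
    scale = spec.mean_tad_length * spec.length_dispersion**2
    tads: list[GenomicInterval] = []
    for chrom, length in genome.items():
        if spec.mean_tad_length >= length:
            raise ValueError(
                f"mean_tad_length {spec.mean_tad_length} is not smaller than "
                f"chromosome {chrom!r} ({length} bp)"
            )
        pos = 0
        while True:
            gap = int(round(rng.exponential(spec.boundary_gap))) if spec.boundary_gap else 0
            pos += gap
            tad_len = max(spec.min_tad_length, int(round(rng.gamma(shape, scale))))
            if pos + tad_len > length:
                break
            tads.append(GenomicInterval(chrom, pos, pos + tad_len))
            pos += tad_len
    return TadSet.from_intervals(spec.name, tads)


def _place_nonoverlapping(
    rng: np.random.Generator,
    region: GenomicInterval,
    length: int,
    occupied_starts: list[int],
    occupied_ends: list[int],
    max_attempts: int = 200,
) -> GenomicInterval | None:
    """Rejection-sample one interval of ``length`` inside ``region`` avoiding overlaps."""
    if length > region.length:
        return None
    for _ in range(max_attempts):
        start = int(rng.integers(region.start, region.end - length + 1))
        end = start + length
        i = bisect.bisect_left(occupied_starts, end)
        if i > 0 and occupied_ends[i - 1] > start:
            continue
        occupied_starts.insert(i, start)
        occupied_ends.insert(i, end)
        return GenomicInterval(region.chrom, start, end)
    return None


def generate_gene_repeat_annotations(
    sites: Sequence[ChromomereSite],
    class_profiles: dict[str, ClassProfile] | None = None,
    seed: int = 0,
    gene_length_range: tuple[int, int] = (5_000, 50_000),
    repeat_length_range: tuple[int, int] = (500, 5_000),
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Per-chromomere gene and repeat annotations with class-dependent density.

    Gene counts are Poisson(density x span in Mb) with genes placed
    non-overlapping inside the chromomere; repeats are placed non-overlapping
    until the class's target covered fraction is reached (final coverage is
    within one repeat length of the target).
    """
    profiles = class_profiles or DEFAULT_CLASS_PROFILES
    rng = np.random.default_rng(seed)
    genes: list[GenomicInterval] = []
    repeats: list[GenomicInterval] = []
    for site in sites:
        profile = profiles[site.kind]
        span = site.interval.length
        # genes
        starts: list[int] = []
        ends: list[int] = []
        n_genes = int(rng.poisson(profile.gene_density * span / MB))
        for _ in range(n_genes):
            length = int(rng.integers(*gene_length_range, endpoint=True))
            length = min(length, span)
            placed = _place_nonoverlapping(rng, site.interval, length, starts, ends)
            if placed is not None:
                genes.append(placed)
        # repeats
        if profile.repeat_fraction >= 1.0:
            raise ValueError("repeat coverage target must be < 1")
        target = int(profile.repeat_fraction * span)
        covered = 0
        starts, ends = [], []
        while covered < target:
            length = int(rng.integers(*repeat_length_range, endpoint=True))
            length = min(length, span)
            placed = _place_nonoverlapping(rng, site.interval, length, starts, ends)
            if placed is None:
                break  # packing saturated; coverage is as close as placement allows
            repeats.append(placed)
            covered += placed.length
    return genes, repeats
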