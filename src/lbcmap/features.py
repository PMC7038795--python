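"""Gene density and repeat content of called chromomeres.

A gene belongs to the chromomere that contains its midpoint, so over a
complete tiling every gene is counted exactly once. Repeat content is the
fraction of chromomere bases covered by the union of repeat intervals, not
the sum of their lengths, so overlapping repeat annotations are not double
counted. A coarse qualitative class (gene_rich / repeat_rich / mixed) is
assigned from configurable thresholds.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .borders import ChromomereCall
from .intervals import GenomicInterval

GENE_RICH = "gene_rich"
REPEAT_RICH = "repeat_rich"
MIXED = "mixed"


@dataclass(frozen=True)
class FeatureThresholds:
    """Class-assignment thresholds (configuration, not biology)."""

    gene_rich_min: float = 4.0  # genes/Mb at or above which a chromomere is gene-rich
    repeat_rich_min: float = 0.3  # repeat fraction at or above which it can be repeat-rich
    gene_poor_max: float = 1.0  # genes/Mb at or below which repeat-rich applies


@dataclass(frozen=True)
class FeatureProfile:
    sample_id: str
    gene_count: int
    gene_density: float  # genes per Mb
    repeat_fraction: float  # covered-base fraction of the chromomere
    class_label: str


def union_coverage(region: GenomicInterval, intervals: Iterable[GenomicInterval]) -> int:
    """Bases of ``region`` covered by the union of ``intervals``."""
    clipped = sorted(
        (max(iv.start, region.start), min(iv.end, region.end))
        for iv in intervals
        if iv.chrom == region.chrom and iv.start < region.end and iv.end > region.start
    )
    covered = 0
    current_start = current_end = None
    for start, end in clipped:
        if current_end is None or start > current_end:
            if current_end is not None:
                covered += current_end - current_start
            current_start, current_end = start, end
        else:
            current_end = max(current_end, end)
    if current_end is not None:
        covered += current_end - current_start
    return covered


def count_genes_by_midpoint(
    region: GenomicInterval, genes: Iterable[GenomicInterval]
) -> int:
    """Genes whose midpoint lies within ``region`` (half-open)."""
    return sum(
        1
        for g in genes
        if g.chrom == region.chrom and region.contains_point(g.midpoint)
    )


def classify(
    gene_density: float, repeat_fraction: float, thresholds: FeatureThresholds
) -> str:
    if (
        repeat_fraction >= thresholds.repeat_rich_min
        and gene_density <= thresholds.gene_poor_max
    ):
        return REPEAT_RICH
    if (
        gene_density >= thresholds.gene_rich_min
        and repeat_fraction < thresholds.repeat_rich_min
    ):
        return GENE_RICH
    return MIXED


def annotate_chromomere(
    call: ChromomereCall,
    genes: Sequence[GenomicInterval],
    repeats: Sequence[GenomicInterval],
    thresholds: FeatureThresholds | None = None,
) -> FeatureProfile:
    """Gene density, repeat content and class for one unambiguous call.

    Ambiguous calls are refused: their borders are unreliable, so any density
    computed from them would be too.
    """
    if call.ambiguous:
        raise ValueError(
            f"chromomere {call.sample_id!r} has ambiguous borders and is "
            "excluded from feature profiling"
        )
    thresholds = thresholds or FeatureThresholds()
    region = call.interval
    gene_count = count_genes_by_midpoint(region, genes)
    gene_density = gene_count / call.size_mb
    repeat_fraction = union_coverage(region, repeats) / region.length
    return FeatureProfile(
        sample_id=call.sample_id,
        gene_count=gene_count,
        gene_density=gene_density,
        repeat_fraction=repeat_fraction,
        class_label=classify(gene_density, repeat_fraction, thresholds),
    )
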