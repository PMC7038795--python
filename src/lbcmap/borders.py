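"""Chromomere border calling from mapped-read positions.

The borders of a dissected chromomere are taken from the alignment itself:
reads are sorted, split into clusters wherever the gap between consecutive
reads exceeds a threshold, the cluster holding the most reads becomes the
main cluster, and single reads distant from it are excluded before the
extreme read coordinates define the called interval. Calls whose main cluster
is weakly supported, or that have a sizable rival cluster, are flagged
ambiguous and excluded from downstream summaries.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .intervals import GenomicInterval, ReadPlacement

MB = 1_000_000


@dataclass(frozen=True)
class ClusteringParams:
    """Parameters of the cluster segmentation and ambiguity rules.

    gap_threshold
        Split clusters at inter-read gaps exceeding this many bp. The default
        (1 Mb) sits below the smallest expected chromomere span (1.5 Mb) and
        far above typical read spacing at useful depth.
    min_main_fraction
        The main cluster must hold at least this fraction of reads, else the
        call is ambiguous.
    second_cluster_max_fraction
        Any rival cluster at or above this fraction makes the call ambiguous.
    collapse_duplicates
        Collapse reads with identical start and end (PCR copies) before
        clustering.
    exclude_distant
        After selecting the main cluster, drop sparse terminal runs of reads
        separated from its body by gaps larger than any spacing observed among
        its central reads (see :func:`exclude_distant_reads`); applied only to
        clusters of at least ``min_trim_reads`` reads, below which spacing
        statistics carry no signal. This is the exclusion of single reads
        distant from the main cluster; disable it to make the call exactly
        the extreme coordinates of the gap-threshold main cluster.
    """

    gap_threshold: int = MB
    min_main_fraction: float = 0.8
    second_cluster_max_fraction: float = 0.25
    collapse_duplicates: bool = True
    exclude_distant: bool = True
    min_trim_reads: int = 20

    def __post_init__(self) -> None:
        if self.gap_threshold <= 0:
            raise ValueError("gap_threshold must be positive")
        if not 0 < self.min_main_fraction <= 1:
            raise ValueError("min_main_fraction must be in (0, 1]")
        if not 0 <= self.second_cluster_max_fraction < 1:
            raise ValueError("second_cluster_max_fraction must be in [0, 1)")


@dataclass(frozen=True)
class ChromomereCall:
    """An inferred chromomere interval with its read-support statistics."""

    sample_id: str
    interval: GenomicInterval
    size_mb: float
    n_reads_total: int
    n_reads_main: int
    n_clusters: int
    ambiguous: bool


def _sorted_unique(reads: Sequence[ReadPlacement], collapse: bool) -> list[ReadPlacement]:
    ordered = sorted(reads, key=lambda r: (r.interval.start, r.interval.end))
    if not collapse:
        return ordered
    out: list[ReadPlacement] = []
    seen: set[tuple[int, int]] = set()
    for read in ordered:
        key = (read.interval.start, read.interval.end)
        if key not in seen:
            seen.add(key)
            out.append(read)
    return out


def split_into_clusters(
    reads: Sequence[ReadPlacement], params: ClusteringParams | None = None
) -> list[list[ReadPlacement]]:
    """Split one chromosome's reads into clusters at large inter-read gaps.

    Reads are sorted by start (duplicates collapsed first when configured);
    a new cluster begins whenever ``current.start - previous.end`` exceeds
    ``gap_threshold``. Clusters are returned left to right and partition the
    reads.
    """
    params = params or ClusteringParams()
    if not reads:
        raise ValueError("no reads to cluster")
    chroms = {r.interval.chrom for r in reads}
    if len(chroms) > 1:
        raise ValueError(
            f"reads span multiple chromosomes ({sorted(chroms)}); "
            "cluster each chromosome separately"
        )
    ordered = _sorted_unique(reads, params.collapse_duplicates)
    clusters: list[list[ReadPlacement]] = [[ordered[0]]]
    for prev, curr in zip(ordered, ordered[1:]):
        if curr.interval.start - prev.interval.end > params.gap_threshold:
            clusters.append([curr])
        else:
            clusters[-1].append(curr)
    return clusters


def _gaps(reads: Sequence[ReadPlacement]) -> list[int]:
    """Non-negative spacings between consecutive sorted reads (start - prev end)."""
    return [
        max(0, b.interval.start - a.interval.end)
        for a, b in zip(reads, reads[1:])
    ]


def exclude_distant_reads(
    cluster: Sequence[ReadPlacement],
    min_reads: int = 20,
    max_noise_per_side: int = 12,
    background_ratio: float = 60.0,
) -> list[ReadPlacement]:
    """Exclude terminal runs of reads too sparse to belong to the cluster body.

    Reads inside a chromomere arrive as a dense Poisson process; stray reads
    merged into the cluster (spillover into a neighbor, contamination) form a
    much sparser one at its edges. Trimming a terminal run is worthwhile when
    the genomic span it removes outweighs the reads it sacrifices, which for a
    density ratio ``background_ratio`` between cluster body and background
    reduces to scoring every inter-read gap ``g`` as ``1 - g / tau`` with
    ``tau = mean central spacing x ln(background_ratio)``, and keeping the
    maximum-scoring contiguous run of reads around the cluster's center
    (a maximum-subarray trim). Distant single reads and sparse chains score
    negative and are dropped; a dense run of reads beyond even a large gap
    scores positive and is kept.

    The central spacing is estimated with the outermost ``max_noise_per_side``
    reads (or m/10 if larger) on each side excluded, since that is where stray
    reads sit. Clusters below ``min_reads`` reads are returned unchanged:
    their spacing statistics carry no signal.
    """
    reads = list(cluster)
    m = len(reads)
    if m < min_reads:
        return reads
    b = min(max(max_noise_per_side, m // 10), m // 4)
    central_gaps = _gaps(reads[b : m - b])
    if not central_gaps:
        return reads
    mean_gap = sum(central_gaps) / len(central_gaps)
    tau = mean_gap * math.log(background_ratio)
    if tau <= 0:
        return reads

    gaps = _gaps(reads)
    scores = [1.0 - g / tau for g in gaps]
    center = m // 2

    # best contiguous run containing the central read: extend the boundary
    # outward whenever the cumulative gap score stays non-negative
    best, cum, left = 0.0, 0.0, center
    for k in range(center - 1, -1, -1):
        cum += scores[k]
        if cum >= best:
            best, left = cum, k
    best, cum, right = 0.0, 0.0, center
    for k in range(center, m - 1):
        cum += scores[k]
        if cum >= best:
            best, right = cum, k + 1
    return reads[left : right + 1]


def call_borders(
    sample_id: str,
    reads: Sequence[ReadPlacement],
    params: ClusteringParams | None = None,
) -> ChromomereCall:
    """Call one chromomere's borders from its mapped reads.

    The main cluster is the gap-threshold cluster holding the most reads
    (ties go to the leftmost cluster and mark the call ambiguous). The call is
    also ambiguous when the main cluster holds less than ``min_main_fraction``
    of the reads or any rival cluster holds at least
    ``second_cluster_max_fraction``. With ``exclude_distant`` (default) the
    distant-read exclusion is applied to the main cluster before its extreme
    read coordinates become the called interval.
    """
    params = params or ClusteringParams()
    clusters = split_into_clusters(reads, params)
    n_total = sum(len(c) for c in clusters)
    sizes = [len(c) for c in clusters]
    best = max(sizes)
    main_index = sizes.index(best)  # leftmost on ties
    tie = sizes.count(best) > 1

    main_fraction = best / n_total
    rival_fraction = max(
        (s / n_total for i, s in enumerate(sizes) if i != main_index), default=0.0
    )
    ambiguous = (
        tie
        or main_fraction < params.min_main_fraction
        or rival_fraction >= params.second_cluster_max_fraction
    )

    main = clusters[main_index]
    if params.exclude_distant:
        main = exclude_distant_reads(main, params.min_trim_reads)

    start = min(r.interval.start for r in main)
    end = max(r.interval.end for r in main)
    interval = GenomicInterval(main[0].interval.chrom, start, end)
    return ChromomereCall(
        sample_id=sample_id,
        interval=interval,
        size_mb=interval.length / MB,
        n_reads_total=n_total,
        n_reads_main=len(main),
        n_clusters=len(clusters),
        ambiguous=ambiguous,
    )
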