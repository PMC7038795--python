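"""Shared fixtures and independent brute-force oracles."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lbcmap import GenomeMap, GenomicInterval, ReadPlacement

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def genome() -> GenomeMap:
    return GenomeMap({"chr4": 90_000_000, "chr11": 20_000_000})


def make_reads(
    positions, chrom: str = "chr4", length: int = 250, sample_id: str = "s"
) -> list[ReadPlacement]:
    """Reads of fixed length at the given start positions."""
    return [
        ReadPlacement(GenomicInterval(chrom, int(p), int(p) + length), sample_id)
        for p in positions
    ]


def oracle_main_run(reads, gap_threshold: int, collapse_duplicates: bool = True):
    """Brute-force largest gap-free contiguous subsequence of sorted reads.

    Enumerates every contiguous subsequence (via a prefix count of
    threshold-violating gaps), keeps the one with most reads (leftmost on
    ties), and returns (subsequence, interval, clusters) where clusters are
    the maximal gap-free runs. Independent of the package's linear scan.
    """
    ordered = sorted(reads, key=lambda r: (r.interval.start, r.interval.end))
    if collapse_duplicates:
        seen, unique = set(), []
        for r in ordered:
            key = (r.interval.start, r.interval.end)
            if key not in seen:
                seen.add(key)
                unique.append(r)
        ordered = unique
    n = len(ordered)
    bad = [
        1 if b.interval.start - a.interval.end > gap_threshold else 0
        for a, b in zip(ordered, ordered[1:])
    ]
    cum = [0]
    for v in bad:
        cum.append(cum[-1] + v)
    best = None  # (size, i, j)
    for i in range(n):
        for j in range(i, n):
            if cum[j] - cum[i] == 0:
                size = j - i + 1
                if best is None or size > best[0]:
                    best = (size, i, j)
    _, i, j = best
    run = ordered[i : j + 1]
    interval = GenomicInterval(
        run[0].interval.chrom,
        min(r.interval.start for r in run),
        max(r.interval.end for r in run),
    )
    # maximal gap-free runs, for cluster-partition comparison
    clusters, start = [], 0
    for k, v in enumerate(bad):
        if v:
            clusters.append(ordered[start : k + 1])
            start = k + 1
    clusters.append(ordered[start:])
    return run, interval, clusters


def random_read_instance(rng: np.random.Generator, max_reads: int = 200):
    """A random clustered read instance: 1-3 dense clusters plus stray reads."""
    chrom_len = 50_000_000
    n_clusters = int(rng.integers(1, 4))
    reads = []
    remaining = int(rng.integers(1, max_reads + 1))
    for _ in range(n_clusters):
        if remaining <= 0:
            break
        size = int(rng.integers(1, remaining + 1))
        remaining -= size
        center = int(rng.integers(0, chrom_len - 3_000_000))
        spread = int(rng.integers(50_000, 2_000_000))
        starts = rng.integers(center, center + spread, size)
        reads.extend(make_reads(starts, chrom="chrT"))
    n_stray = min(remaining, int(rng.integers(0, 6)))
    if n_stray:
        reads.extend(
            make_reads(rng.integers(0, chrom_len - 400, n_stray), chrom="chrT")
        )
    if not reads:
        reads = make_reads([int(rng.integers(0, chrom_len - 400))], chrom="chrT")
    return reads
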