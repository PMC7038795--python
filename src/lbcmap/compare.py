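"""Comparison of chromomere intervals with interphase chromatin domains.

Three per-chromomere measurements, mirroring the comparative analysis a
chromomere map invites once somatic Hi-C domain coordinates are available:

* A/B compartment fractions: the fraction of chromomere bases overlapped by
  A blocks, B blocks, and by no block (``frac_NA``); the three always sum to 1.
* Border switches: whether at least one A<->B switch point lies within a
  window (default +-500 kb) of the left/right chromomere border.
* Fractional TAD counts: a TAD wholly inside the chromomere counts 1, a TAD
  partially overlapping it (including one that contains it) counts 0.5, so
  counts live on the half-integer scale.

Cohort summaries (per-TAD-set mean/min/max counts, the pooled border-switch
proportion) are computed over non-ambiguous chromomeres by default.
"""
from __future__ import annotations

import math
import warnings
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .borders import ChromomereCall
from .domains import CompartmentProfile, TadSet
from .intervals import GenomicInterval


@dataclass(frozen=True)
class ComparisonConfig:
    switch_window: int = 500_000  # bp each side of a border
    include_ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.switch_window <= 0:
            raise ValueError("switch_window must be positive")


def compartment_fractions(
    chromomere: GenomicInterval, profile: CompartmentProfile
) -> tuple[float, float, float]:
    """(frac_A, frac_B, frac_NA) of the chromomere against the profile."""
    if chromomere.chrom != profile.chrom:
        raise ValueError(
            f"chromomere on {chromomere.chrom!r} but profile on {profile.chrom!r}"
        )
    length = chromomere.length
    covered = {"A": 0, "B": 0}
    for block, label in profile.blocks:
        covered[label] += chromomere.overlap_length(block)
    frac_a = covered["A"] / length
    frac_b = covered["B"] / length
    return frac_a, frac_b, 1.0 - frac_a - frac_b


def detect_border_switch(
    border: int, profile: CompartmentProfile, window: int = 500_000
) -> bool:
    """True iff a compartment switch point lies within ``border +- window``.

    The window is closed on both ends and clipped at the chromosome; switch
    points are shared boundaries of abutting A/B blocks (gaps do not switch).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    lo = max(0, border - window)
    hi = border + window
    points = profile.switch_points()
    i = bisect_left(points, lo)
    return i < len(points) and points[i] <= hi


def count_tads_fractional(chromomere: GenomicInterval, tadset: TadSet) -> float:
    """Half-integer TAD count: contained TADs count 1, partial overlaps 0.5.

    A TAD that strictly contains the chromomere is a partial overlap (0.5);
    zero-length abutment at a shared half-open boundary does not count.
    """
    count = 0.0
    for tad in tadset.on_chromosome(chromomere.chrom):
        if chromomere.overlap_length(tad) == 0:
            continue
        count += 1.0 if chromomere.contains(tad) else 0.5
    return count


@dataclass(frozen=True)
class ChromomereComparison:
    """Per-chromomere comparison record (one report row)."""

    sample_id: str
    interval: GenomicInterval
    size_mb: float
    ambiguous: bool
    frac_a: float
    frac_b: float
    frac_na: float
    tad_counts: Mapping[str, float]
    switch_left: bool
    switch_right: bool


@dataclass(frozen=True)
class ComparisonSummary:
    n_included: int
    switch_proportion: float
    switch_proportion_left: float
    switch_proportion_right: float
    tad_stats: Mapping[str, tuple[float, float, float]]  # name -> (mean, min, max)


@dataclass(frozen=True)
class ComparisonReport:
    rows: tuple[ChromomereComparison, ...]
    summary: ComparisonSummary
    tad_set_names: tuple[str, ...]


def compare_chromomere(
    call: ChromomereCall,
    profile: CompartmentProfile | None,
    tadsets: Sequence[TadSet],
    config: ComparisonConfig | None = None,
) -> ChromomereComparison:
    """Build one comparison row; ``profile=None`` means no compartment data
    for the chromosome (all bases NA, no switches)."""
    config = config or ComparisonConfig()
    interval = call.interval
    if profile is not None:
        frac_a, frac_b, frac_na = compartment_fractions(interval, profile)
        switch_left = detect_border_switch(interval.start, profile, config.switch_window)
        switch_right = detect_border_switch(interval.end, profile, config.switch_window)
    else:
        frac_a, frac_b, frac_na = 0.0, 0.0, 1.0
        switch_left = switch_right = False
    return ChromomereComparison(
        sample_id=call.sample_id,
        interval=interval,
        size_mb=call.size_mb,
        ambiguous=call.ambiguous,
        frac_a=frac_a,
        frac_b=frac_b,
        frac_na=frac_na,
        tad_counts={ts.name: count_tads_fractional(interval, ts) for ts in tadsets},
        switch_left=switch_left,
        switch_right=switch_right,
    )


def summarize_comparison(
    rows: Sequence[ChromomereComparison],
    config: ComparisonConfig | None = None,
    tad_set_names: Sequence[str] | None = None,
) -> ComparisonSummary:
    """Cohort summary over included (by default, non-ambiguous) chromomeres.

    The border-switch proportion pools left and right indicators:
    (number of true indicators) / (2 x included chromomeres).
    """
    config = config or ComparisonConfig()
    included = [r for r in rows if config.include_ambiguous or not r.ambiguous]
    if tad_set_names is None:
        tad_set_names = tuple(rows[0].tad_counts) if rows else ()
    nan = float("nan")
    if not included:
        warnings.warn("no chromomeres included in summary; statistics are NA")
        return ComparisonSummary(
            n_included=0,
            switch_proportion=nan,
            switch_proportion_left=nan,
            switch_proportion_right=nan,
            tad_stats={name: (nan, nan, nan) for name in tad_set_names},
        )
    n = len(included)
    left = sum(r.switch_left for r in included)
    right = sum(r.switch_right for r in included)
    tad_stats = {}
    for name in tad_set_names:
        counts = [r.tad_counts[name] for r in included]
        tad_stats[name] = (sum(counts) / n, min(counts), max(counts))
    return ComparisonSummary(
        n_included=n,
        switch_proportion=(left + right) / (2 * n),
        switch_proportion_left=left / n,
        switch_proportion_right=right / n,
        tad_stats=tad_stats,
    )


def compare_chromomeres(
    calls: Sequence[ChromomereCall],
    profiles: Mapping[str, CompartmentProfile],
    tadsets: Sequence[TadSet],
    config: ComparisonConfig | None = None,
) -> ComparisonReport:
    """Full comparison: one row per call plus the cohort summary."""
    config = config or ComparisonConfig()
    names = tuple(ts.name for ts in tadsets)
    rows = tuple(
        compare_chromomere(call, profiles.get(call.interval.chrom), tadsets, config)
        for call in calls
    )
    summary = summarize_comparison(rows, config, names)
    return ComparisonReport(rows=rows, summary=summary, tad_set_names=names)
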