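"""Compartment fractions, border switches, fractional TAD counts, summaries."""
from __future__ import annotations

import math
import warnings

import numpy as np
import pytest

from lbcmap import (
    ComparisonConfig,
    CompartmentProfile,
    GenomicInterval,
    TadSet,
    compartment_fractions,
    count_tads_fractional,
    detect_border_switch,
    summarize_comparison,
)
from lbcmap.compare import ChromomereComparison

MB = 1_000_000


def alternating_profile(chrom_len: int, block: int, chrom="c") -> CompartmentProfile:
    blocks = []
    label = "A"
    pos = 0
    while pos < chrom_len:
        end = min(pos + block, chrom_len)
        blocks.append((GenomicInterval(chrom, pos, end), label))
        label = "B" if label == "A" else "A"
        pos = end
    return CompartmentProfile.from_blocks(chrom, blocks)


class TestCompartmentFractions:
    def test_proportional_overlap(self):
        profile = CompartmentProfile.from_blocks("c", [
            (GenomicInterval("c", 0, 250_000), "A"),
            (GenomicInterval("c", 250_000, MB), "B"),
        ])
        fracs = compartment_fractions(GenomicInterval("c", 0, MB), profile)
        assert fracs == pytest.approx((0.25, 0.75, 0.0))

    def test_chromomere_inside_single_b_block_is_pure_b(self):
        profile = CompartmentProfile.from_blocks("c", [
            (GenomicInterval("c", 0, 10 * MB), "B"),
        ])
        fracs = compartment_fractions(GenomicInterval("c", 2 * MB, 6 * MB), profile)
        assert fracs == pytest.approx((0.0, 1.0, 0.0))

    def test_uncovered_remainder_is_na(self):
        profile = CompartmentProfile.from_blocks("c", [
            (GenomicInterval("c", 0, 900_000), "A"),
        ])
        fracs = compartment_fractions(GenomicInterval("c", 0, MB), profile)
        assert fracs == pytest.approx((0.9, 0.0, 0.1))

    def test_chromosome_mismatch_rejected(self):
        profile = alternating_profile(MB, 100_000)
        with pytest.raises(ValueError):
            compartment_fractions(GenomicInterval("other", 0, MB), profile)

    def test_fractions_sum_to_one_on_random_pairs(self):
        rng = np.random.default_rng(21)
        for _ in range(300):
            chrom_len = int(rng.integers(2, 40)) * MB
            profile = alternating_profile(chrom_len, int(rng.integers(1, 30)) * 100_000)
            start = int(rng.integers(0, chrom_len - MB))
            chromomere = GenomicInterval("c", start, start + int(rng.integers(1, MB)))
            a, b, na = compartment_fractions(chromomere, profile)
            assert abs(a + b + na - 1.0) < 1e-9

    def test_matches_per_base_counting_on_small_chromosomes(self):
        rng = np.random.default_rng(33)
        for _ in range(20):
            chrom_len = int(rng.integers(200_000, MB))
            labels = np.zeros(chrom_len, dtype=np.int8)  # 0 NA, 1 A, 2 B
            blocks, pos = [], 0
            while pos < chrom_len:
                size = int(rng.integers(10_000, 200_000))
                end = min(pos + size, chrom_len)
                kind = int(rng.integers(0, 3))
                if kind:
                    label = "A" if kind == 1 else "B"
                    blocks.append((GenomicInterval("c", pos, end), label))
                    labels[pos:end] = kind
                pos = end
            profile = CompartmentProfile.from_blocks("c", blocks)
            start = int(rng.integers(0, chrom_len - 10))
            end = int(rng.integers(start + 1, chrom_len))
            chromomere = GenomicInterval("c", start, end)
            a, b, na = compartment_fractions(chromomere, profile)
            window = labels[start:end]
            assert a == pytest.approx((window == 1).mean(), abs=1e-12)
            assert b == pytest.approx((window == 2).mean(), abs=1e-12)


class TestBorderSwitch:
    def test_switch_inside_window_detected(self):
        profile = CompartmentProfile.from_blocks("c", [
            (GenomicInterval("c", 0, 600_000), "A"),
            (GenomicInterval("c", 600_000, 2 * MB), "B"),
        ])
        assert detect_border_switch(400_000, profile, 500_000)

    def test_switch_beyond_window_not_detected(self):
        profile = CompartmentProfile.from_blocks("c", [
            (GenomicInterval("c", 0, MB), "A"),
            (GenomicInterval("c", MB, 2 * MB), "B"),
        ])
        assert not detect_border_switch(400_000, profile, 500_000)
        # the window is closed: a switch exactly at border + window counts
        assert detect_border_switch(500_000, profile, 500_000)

    def test_gap_boundaries_are_not_switches(self):
        profile = CompartmentProfile.from_blocks("c", [
            (GenomicInterval("c", 0, MB), "A"),
            (GenomicInterval("c", 1_200_000, 2 * MB), "B"),
        ])
        assert not detect_border_switch(MB, profile, 500_000)

    def test_block_length_twice_window_switches_everywhere(self):
        # alternating blocks of exactly 2 x window: away from the chromosome
        # ends, every bin-aligned border is within one window of a switch
        # point (distance to the nearest switch <= half a block = window)
        window = 500_000
        profile = alternating_profile(20 * MB, 2 * window)
        for border in range(window, 20 * MB - window + 1, 100_000):
            assert detect_border_switch(border, profile, window)

    @pytest.mark.parametrize("block_mb,expected", [(1, 1.0), (2, 0.5), (4, 0.25)])
    def test_analytic_switch_law(self, block_mb, expected):
        """For alternating blocks of length L the probability that a uniform
        border sees a switch within +-w is min(1, 2w/L)."""
        window = 500_000
        chrom_len = 96 * MB
        profile = alternating_profile(chrom_len, block_mb * MB)
        rng = np.random.default_rng(block_mb)
        borders = rng.integers(window, chrom_len - window, 1000)
        hits = sum(
            detect_border_switch(int(b), profile, window) for b in borders
        )
        sigma = math.sqrt(1000 * expected * (1 - expected))
        assert abs(hits - 1000 * expected) <= max(3 * sigma, 1)

    def test_switch_detection_monotone_in_window(self):
        profile = alternating_profile(10 * MB, 700_000)
        rng = np.random.default_rng(4)
        borders = rng.integers(0, 10 * MB, 200)
        prev = 0
        for window in (100_000, 300_000, 500_000, 900_000):
            hits = sum(detect_border_switch(int(b), profile, window) for b in borders)
            assert hits >= prev
            prev = hits


def brute_force_tad_count(chromomere: GenomicInterval, tads) -> float:
    """Independent per-TAD classifier."""
    total = 0.0
    for tad in tads:
        if tad.chrom != chromomere.chrom:
            continue
        lo = max(tad.start, chromomere.start)
        hi = min(tad.end, chromomere.end)
        if hi <= lo:
            continue  # no overlap (half-open abutment included)
        fully_inside = chromomere.start <= tad.start and tad.end <= chromomere.end
        total += 1.0 if fully_inside else 0.5
    return total


class TestFractionalTadCount:
    def test_inside_plus_partial(self):
        tads = TadSet.from_intervals("t", [
            GenomicInterval("c", 100_000, 300_000),
            GenomicInterval("c", 900_000, 1_100_000),
        ])
        assert count_tads_fractional(GenomicInterval("c", 0, MB), tads) == 1.5

    def test_no_overlap_counts_zero(self):
        tads = TadSet.from_intervals("t", [GenomicInterval("c", 2 * MB, 3 * MB)])
        assert count_tads_fractional(GenomicInterval("c", 0, MB), tads) == 0.0
        # half-open abutment at a shared boundary is not an overlap
        tads2 = TadSet.from_intervals("t", [GenomicInterval("c", MB, 2 * MB)])
        assert count_tads_fractional(GenomicInterval("c", 0, MB), tads2) == 0.0

    def test_containing_tad_counts_half(self):
        tads = TadSet.from_intervals("t", [GenomicInterval("c", 0, 5 * MB)])
        assert count_tads_fractional(GenomicInterval("c", MB, 2 * MB), tads) == 0.5

    def test_matches_bruteforce_classifier_and_half_integer_scale(self):
        rng = np.random.default_rng(77)
        for _ in range(200):
            tads, pos = [], 0
            for _ in range(int(rng.integers(1, 50))):
                pos += int(rng.integers(0, 200_000))
                length = int(rng.integers(50_000, 1_500_000))
                tads.append(GenomicInterval("c", pos, pos + length))
                pos += length
            tadset = TadSet.from_intervals("t", tads)
            start = int(rng.integers(0, pos))
            chromomere = GenomicInterval("c", start, start + int(rng.integers(1, 4 * MB)))
            count = count_tads_fractional(chromomere, tadset)
            assert count == brute_force_tad_count(chromomere, tads)
            assert (2 * count) == int(2 * count)

    def test_count_never_decreases_when_chromomere_extends(self):
        rng = np.random.default_rng(55)
        tads = TadSet.from_intervals("t", [
            GenomicInterval("c", i * MB, i * MB + 800_000) for i in range(30)
        ])
        for _ in range(100):
            start = int(rng.integers(MB, 25 * MB))
            chromomere = GenomicInterval("c", start, start + int(rng.integers(1, 3 * MB)))
            base = count_tads_fractional(chromomere, tads)
            grown = GenomicInterval(
                "c",
                max(0, start - int(rng.integers(0, MB))),
                chromomere.end + int(rng.integers(0, MB)),
            )
            assert count_tads_fractional(grown, tads) >= base


def row(sample_id, tad_counts, switch_left, switch_right, ambiguous=False):
    return ChromomereComparison(
        sample_id=sample_id,
        interval=GenomicInterval("c", 0, MB),
        size_mb=1.0, ambiguous=ambiguous,
        frac_a=0.5, frac_b=0.5, frac_na=0.0,
        tad_counts=tad_counts,
        switch_left=switch_left, switch_right=switch_right,
    )


class TestSummaries:
    def test_mean_min_max_and_pooled_switch_proportion(self):
        rows = [
            row("a", {"DI": 1.5}, True, False),
            row("b", {"DI": 3.5}, True, False),
        ]
        summary = summarize_comparison(rows)
        assert summary.tad_stats["DI"] == (2.5, 1.5, 3.5)
        assert summary.switch_proportion == 0.5
        assert summary.n_included == 2

    def test_no_switches_gives_zero_proportion(self):
        summary = summarize_comparison([row("a", {"DI": 1.0}, False, False)])
        assert summary.switch_proportion == 0.0

    def test_ambiguous_rows_excluded_by_default(self):
        rows = [
            row("a", {"DI": 1.0}, True, True),
            row("b", {"DI": 9.0}, False, False, ambiguous=True),
        ]
        assert summarize_comparison(rows).n_included == 1
        config = ComparisonConfig(include_ambiguous=True)
        assert summarize_comparison(rows, config).n_included == 2

    def test_zero_included_rows_yield_nan_summary_with_warning(self):
        rows = [row("a", {"DI": 1.0}, False, False, ambiguous=True)]
        with pytest.warns(UserWarning, match="no chromomeres"):
            summary = summarize_comparison(rows)
        assert summary.n_included == 0
        assert math.isnan(summary.switch_proportion)
        assert all(math.isnan(v) for v in summary.tad_stats["DI"])
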