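"""Interphase chromatin-domain containers: A/B compartment profiles and TAD sets.

A :class:`CompartmentProfile` is an ordered, non-overlapping tiling of one
chromosome by intervals labeled ``"A"`` (open/active) or ``"B"`` (closed/
silent), typically derived from a Hi-C contact-matrix eigenvector at a fixed
bin resolution (100 kb here). Gaps between blocks are allowed and represent
bins with no compartment assignment.

A :class:`TadSet` holds the sorted, pairwise-disjoint intervals of one
TAD-calling algorithm (e.g. a directionality-index caller or Armatus), possibly
spanning several chromosomes.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .intervals import GenomicInterval

COMPARTMENT_LABELS = ("A", "B")


@dataclass(frozen=True)
class CompartmentProfile:
    """Labeled A/B interval tiling of a single chromosome."""

    chrom: str
    blocks: tuple[tuple[GenomicInterval, str], ...]
    bin_size: int = 100_000

    @classmethod
    def from_blocks(
        cls,
        chrom: str,
        blocks: Iterable[tuple[GenomicInterval, str]],
        bin_size: int = 100_000,
    ) -> "CompartmentProfile":
        """Build a profile, merging adjacent same-label blocks.

        Blocks must be on ``chrom``, sorted by start and non-overlapping;
        gaps are permitted and remain uncovered.
        """
        merged: list[tuple[GenomicInterval, str]] = []
        for interval, label in blocks:
            if label not in COMPARTMENT_LABELS:
                raise ValueError(f"compartment label must be A or B, got {label!r}")
            if interval.chrom != chrom:
                raise ValueError(
                    f"block {interval} not on profile chromosome {chrom!r}"
                )
            if merged:
                prev, prev_label = merged[-1]
                if interval.start < prev.end:
                    raise ValueError(
                        f"overlapping compartment blocks: {prev} and {interval}"
                    )
                if prev_label == label and interval.start == prev.end:
                    merged[-1] = (
                        GenomicInterval(chrom, prev.start, interval.end),
                        label,
                    )
                    continue
            merged.append((interval, label))
        return cls(chrom=chrom, blocks=tuple(merged), bin_size=bin_size)

    def __len__(self) -> int:
        return len(self.blocks)

    def switch_points(self) -> list[int]:
        """Positions where an A block abuts a B block (or vice versa).

        A boundary next to an uncovered gap is *not* a switch point: a switch
        requires two abutting blocks of opposite label.
        """
        points = []
        for (left, left_label), (right, right_label) in zip(self.blocks, self.blocks[1:]):
            if left.end == right.start and left_label != right_label:
                points.append(left.end)
        return points

    def covered_length(self) -> int:
        return sum(iv.length for iv, _ in self.blocks)


@dataclass(frozen=True)
class TadSet:
    """Sorted, pairwise-disjoint TAD intervals from one calling algorithm."""

    name: str
    tads: tuple[GenomicInterval, ...]

    @classmethod
    def from_intervals(cls, name: str, tads: Iterable[GenomicInterval]) -> "TadSet":
        ordered = tuple(sorted(tads, key=lambda iv: (iv.chrom, iv.start, iv.end)))
        for a, b in zip(ordered, ordered[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise ValueError(f"overlapping TADs: {a} and {b}")
        return cls(name=name, tads=ordered)

    def __len__(self) -> int:
        return len(self.tads)

    def on_chromosome(self, chrom: str) -> tuple[GenomicInterval, ...]:
        return tuple(iv for iv in self.tads if iv.chrom == chrom)
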