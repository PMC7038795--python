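"""Coordinate primitives shared by every pipeline stage.

All coordinates in this package are 0-based, half-open ``[start, end)``
(BED-native); the length of an interval is ``end - start``. Keeping a single
convention everywhere removes the usual off-by-one error class when mixing
BED, bedGraph and chrom.sizes inputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A chromosome-anchored span ``[start, end)`` in base pairs.

    Empty and negative spans are rejected: every interval in the pipeline
    represents at least one base.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not isinstance(self.start, int) or not isinstance(self.end, int):
            raise TypeError("interval coordinates must be integers")
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Integer midpoint (floor), used for point-assignment rules."""
        return (self.start + self.end) // 2

    def overlap_length(self, other: "GenomicInterval") -> int:
        """Number of shared bases with ``other`` (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def expanded(self, left: int = 0, right: int = 0, *, max_end: int | None = None) -> "GenomicInterval":
        """Return a copy grown by ``left``/``right`` bp, clipped at 0 / ``max_end``."""
        start = max(0, self.start - left)
        end = self.end + right
        if max_end is not None:
            end = min(end, max_end)
        return GenomicInterval(self.chrom, start, end)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


class GenomeMap:
    """Ordered chromosome-name -> length (bp) mapping (a chrom.sizes table)."""

    def __init__(self, entries: Mapping[str, int] | Iterable[tuple[str, int]]):
        items = list(entries.items()) if isinstance(entries, Mapping) else list(entries)
        self._lengths: dict[str, int] = {}
        for name, length in items:
            if name in self._lengths:
                raise ValueError(f"duplicate chromosome name {name!r}")
            if int(length) <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
            self._lengths[str(name)] = int(length)
        if not self._lengths:
            raise ValueError("genome map is empty")

    def __getitem__(self, chrom: str) -> int:
        return self._lengths[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def __iter__(self) -> Iterator[str]:
        return iter(self._lengths)

    def __len__(self) -> int:
        return len(self._lengths)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GenomeMap) and other._lengths == self._lengths

    @property
    def chromosomes(self) -> list[str]:
        return list(self._lengths)

    def items(self) -> Iterable[tuple[str, int]]:
        return self._lengths.items()

    def validate_interval(self, interval: GenomicInterval) -> None:
        """Raise ``ValueError`` if the interval is not inside this genome."""
        if interval.chrom not in self._lengths:
            raise ValueError(f"unknown chromosome {interval.chrom!r}")
        if interval.end > self._lengths[interval.chrom]:
            raise ValueError(
                f"interval {interval} extends past chromosome end "
                f"({self._lengths[interval.chrom]} bp)"
            )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GenomeMap({self._lengths!r})"


@dataclass(frozen=True)
class ReadPlacement:
    """One mapped sequencing read: its genomic interval plus sample provenance."""

    interval: GenomicInterval
    sample_id: str = ""
    name: str = ""
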