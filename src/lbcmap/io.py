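"""Readers and writers for the plain-text genomic formats the pipeline touches.

Formats: BED3/BED6 (reads, TADs, genes, repeats, called chromomeres), a
bedGraph-like 4-column compartment file, UCSC chrom.sizes, and the TSV
comparison report. Parsing is strict: malformed lines raise
:class:`FormatError` naming the offending line number, and coordinates are
validated against a :class:`~lbcmap.intervals.GenomeMap` when one is supplied.

All numeric report fields are written with a fixed 6-decimal format so that
identical reports are byte-identical on disk.
"""
from __future__ import annotations

import math
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

from .domains import CompartmentProfile, TadSet
from .intervals import GenomicInterval, GenomeMap, ReadPlacement

if TYPE_CHECKING:  # pragma: no cover
    from .compare import ComparisonReport


class FormatError(ValueError):
    """A file did not conform to its declared dialect."""


def _split_line(line: str, path: str, lineno: int, min_fields: int) -> list[str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < min_fields:
        raise FormatError(
            f"{path}:{lineno}: expected at least {min_fields} tab-separated "
            f"fields, got {len(fields)}"
        )
    return fields


def _parse_coords(fields: Sequence[str], path: str, lineno: int) -> GenomicInterval:
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
    try:
        return GenomicInterval(fields[0], start, end)
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: {exc}") from exc


def read_chrom_sizes(path: str | Path) -> GenomeMap:
    """Read a two-column ``name<TAB>length`` chrom.sizes file."""
    entries: list[tuple[str, int]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if not line.strip():
                continue
            fields = _split_line(line, str(path), lineno, 2)
            try:
                entries.append((fields[0], int(fields[1])))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer length") from exc
    return GenomeMap(entries)


def write_chrom_sizes(genome: GenomeMap, path: str | Path) -> None:
    with open(path, "w") as handle:
        for name, length in genome.items():
            handle.write(f"{name}\t{length}\n")


def read_intervals(
    path: str | Path,
    genome: GenomeMap | None = None,
    *,
    with_names: bool = False,
) -> list[GenomicInterval] | list[tuple[GenomicInterval, str]]:
    """Read a BED3/BED6 file in file order; fields beyond the sixth are ignored.

    With ``with_names=True`` each interval is paired with its BED name column
    (empty string for BED3 rows).
    """
    out: list = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = _split_line(line, str(path), lineno, 3)
            interval = _parse_coords(fields, str(path), lineno)
            if genome is not None:
                try:
                    genome.validate_interval(interval)
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if with_names:
                name = fields[3] if len(fields) > 3 else ""
                out.append((interval, name))
            else:
                out.append(interval)
    return out


def write_intervals(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    *,
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
) -> None:
    """Write BED3 (default) or BED6 (when names and/or scores are given)."""
    intervals = list(intervals)
    with open(path, "w") as handle:
        for i, iv in enumerate(intervals):
            if names is None and scores is None:
                handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                name = names[i] if names is not None else "."
                score = scores[i] if scores is not None else 0
                handle.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t+\n"
                )


def read_reads(path: str | Path, sample_id: str, genome: GenomeMap | None = None) -> list[ReadPlacement]:
    """Read mapped-read positions (BED) into :class:`ReadPlacement` records."""
    return [
        ReadPlacement(interval=iv, sample_id=sample_id, name=name)
        for iv, name in read_intervals(path, genome, with_names=True)
    ]


def write_reads(reads: Iterable[ReadPlacement], path: str | Path) -> None:
    reads = list(reads)
    write_intervals(
        [r.interval for r in reads],
        path,
        names=[r.name or r.sample_id or "." for r in reads],
    )


def _value_to_label(raw: str, path: str, lineno: int) -> str | None:
    """Map the compartment value column to a label: A/B literals or sign of a score.

    Positive scores are A, negative are B; zero scores mean "no assignment"
    and become an uncovered gap.
    """
    token = raw.strip()
    if token in ("A", "B"):
        return token
    try:
        score = float(token)
    except ValueError as exc:
        raise FormatError(
            f"{path}:{lineno}: compartment value must be A, B or a number, got {raw!r}"
        ) from exc
    if score > 0:
        return "A"
    if score < 0:
        return "B"
    return None


def read_compartment_profile(
    path: str | Path, genome: GenomeMap
) -> dict[str, CompartmentProfile]:
    """Read a 4-column compartment file into per-chromosome profiles.

    Rows are ``chrom  start  end  value`` with value either a literal A/B
    label or a signed score. Adjacent same-label rows are merged; overlapping
    rows are a format error; zero-score rows become gaps.
    """
    per_chrom: dict[str, list[tuple[GenomicInterval, str]]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = _split_line(line, str(path), lineno, 4)
            interval = _parse_coords(fields, str(path), lineno)
            try:
                genome.validate_interval(interval)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            label = _value_to_label(fields[3], str(path), lineno)
            if label is not None:
                per_chrom.setdefault(interval.chrom, []).append((interval, label))
    profiles: dict[str, CompartmentProfile] = {}
    for chrom, blocks in per_chrom.items():
        blocks.sort(key=lambda pair: pair[0].start)
        try:
            profiles[chrom] = CompartmentProfile.from_blocks(chrom, blocks)
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return profiles


def write_compartment_profile(
    profiles: dict[str, CompartmentProfile] | CompartmentProfile, path: str | Path
) -> None:
    if isinstance(profiles, CompartmentProfile):
        profiles = {profiles.chrom: profiles}
    with open(path, "w") as handle:
        for chrom in profiles:
            for interval, label in profiles[chrom].blocks:
                handle.write(f"{chrom}\t{interval.start}\t{interval.end}\t{label}\n")


def read_tad_set(
    path: str | Path, name: str | None = None, genome: GenomeMap | None = None
) -> TadSet:
    """Read one TAD-caller's intervals (BED3); set name defaults to the file stem."""
    intervals = read_intervals(path, genome)
    return TadSet.from_intervals(name or Path(path).stem, intervals)


def write_tad_set(tadset: TadSet, path: str | Path) -> None:
    write_intervals(tadset.tads, path)


# --- chromomere call table --------------------------------------------------

CALL_COLUMNS = [
    "sample_id", "chrom", "start", "end", "size_mb",
    "n_reads_total", "n_reads_main", "n_clusters", "ambiguous",
]


def write_calls(calls: Iterable, path: str | Path) -> None:
    """Write called chromomeres as a TSV (per-sample QC table)."""
    with open(path, "w") as handle:
        handle.write("\t".join(CALL_COLUMNS) + "\n")
        for c in calls:
            handle.write(
                "\t".join(
                    _fmt(v)
                    for v in (
                        c.sample_id, c.interval.chrom, c.interval.start,
                        c.interval.end, c.size_mb, c.n_reads_total,
                        c.n_reads_main, c.n_clusters, c.ambiguous,
                    )
                )
                + "\n"
            )


def read_calls(path: str | Path) -> list:
    """Read a call table written by :func:`write_calls`."""
    from .borders import ChromomereCall

    calls = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header != CALL_COLUMNS:
            raise FormatError(f"{path}:1: unexpected call-table header")
        for lineno, line in enumerate(handle, 2):
            if not line.strip():
                continue
            fields = _split_line(line, str(path), lineno, len(CALL_COLUMNS))
            interval = _parse_coords(
                [fields[1], fields[2], fields[3]], str(path), lineno
            )
            calls.append(
                ChromomereCall(
                    sample_id=fields[0],
                    interval=interval,
                    size_mb=float(fields[4]),
                    n_reads_total=int(fields[5]),
                    n_reads_main=int(fields[6]),
                    n_clusters=int(fields[7]),
                    ambiguous=fields[8] == "true",
                )
            )
    return calls


# --- comparison report ------------------------------------------------------

def _fmt(value: float | bool | int | str) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return "NA" if math.isnan(value) else f"{value:.6f}"
    return str(value)


def report_columns(tad_set_names: Sequence[str]) -> list[str]:
    cols = ["sample_id", "chrom", "start", "end", "size_mb", "ambiguous",
            "frac_A", "frac_B", "frac_NA"]
    cols += [f"tads_{name}" for name in tad_set_names]
    cols += ["switch_left", "switch_right"]
    return cols


def write_report(
    report: "ComparisonReport",
    path: str | Path,
    summary_path: str | Path | None = None,
) -> None:
    """Write the per-chromomere table plus a summary file.

    One row per chromomere, fixed column order, 6-decimal floats; writing the
    same report twice yields byte-identical files. The summary (cohort means,
    ranges, the pooled border-switch proportion) goes to ``summary_path``
    (default: ``<path>`` with a ``.summary.tsv`` suffix). With zero included
    chromomeres the summary statistics are emitted as NA.
    """
    names = report.tad_set_names
    cols = report_columns(names)
    with open(path, "w") as handle:
        handle.write("\t".join(cols) + "\n")
        for row in report.rows:
            values = [
                row.sample_id, row.interval.chrom, row.interval.start,
                row.interval.end, row.size_mb, row.ambiguous,
                row.frac_a, row.frac_b, row.frac_na,
            ]
            values += [row.tad_counts[name] for name in names]
            values += [row.switch_left, row.switch_right]
            handle.write("\t".join(_fmt(v) for v in values) + "\n")

    if summary_path is None:
        summary_path = Path(path).with_suffix(".summary.tsv")
    s = report.summary
    with open(summary_path, "w") as handle:
        handle.write("statistic\tvalue\n")
        handle.write(f"n_included\t{s.n_included}\n")
        handle.write(f"switch_proportion\t{_fmt(s.switch_proportion)}\n")
        handle.write(f"switch_proportion_left\t{_fmt(s.switch_proportion_left)}\n")
        handle.write(f"switch_proportion_right\t{_fmt(s.switch_proportion_right)}\n")
        for name in names:
            mean, lo, hi = s.tad_stats[name]
            handle.write(f"tads_{name}_mean\t{_fmt(mean)}\n")
            handle.write(f"tads_{name}_min\t{_fmt(lo)}\n")
            handle.write(f"tads_{name}_max\t{_fmt(hi)}\n")
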