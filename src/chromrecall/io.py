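"""Readers and writers for the plain-text formats the pipeline exchanges.

Formats: BED3/BED6(+summit offset) for peaks, BED for tags (one cut site per
record, taken at the 5' end), bedGraph for coverage, 2-column TSV for
chromosome sizes, and TSV with a header row for expression tables.
"""

from __future__ import annotations

import os
from typing import Iterable, List, Sequence, Set, Tuple

import pandas as pd

from .core import GenomeLayout, GenomicInterval, Peak, TagLibrary

__all__ = [
    "BedParseError",
    "read_peaks_bed",
    "write_peaks_bed",
    "read_tags",
    "write_tags_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_expression_tsv",
    "write_expression_tsv",
    "filter_chromosomes",
]

MITOCHONDRIAL = frozenset({"chrM"})


class BedParseError(ValueError):
    """A malformed record, reported with its 1-based line number."""

    def __init__(self, path: str, lineno: int, message: str) -> None:
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


def _bed_lines(path: str):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_peaks_bed(path: str, library_name: str = "") -> List[Peak]:
    """Read peaks from BED.

    Columns 1-3 are chrom/start/end. Optional column 4 is the peak name,
    column 5 the signal score, column 6 the strand (ignored) and column 7 a
    summit offset relative to ``start`` (narrowPeak-style). Without a summit
    column the summit defaults to the interval midpoint,
    ``floor((start + end) / 2)``; without a score the signal is 0.
    """
    peaks: List[Peak] = []
    for lineno, fields in _bed_lines(path):
        if len(fields) < 3:
            raise BedParseError(path, lineno, f"expected >= 3 columns, got {len(fields)}")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise BedParseError(path, lineno, f"non-integer coordinate: {exc}") from None
        if end <= start:
            raise BedParseError(path, lineno, f"rejected record: end {end} <= start {start}")
        name = fields[3] if len(fields) > 3 and fields[3] != "." else ""
        signal = 0.0
        if len(fields) > 4 and fields[4] not in (".", ""):
            try:
                signal = float(fields[4])
            except ValueError:
                raise BedParseError(path, lineno, f"non-numeric score {fields[4]!r}") from None
        if len(fields) > 6 and fields[6] not in (".", ""):
            try:
                summit = start + int(fields[6])
            except ValueError:
                raise BedParseError(
                    path, lineno, f"non-integer summit offset {fields[6]!r}"
                ) from None
            if not (start <= summit < end):
                raise BedParseError(path, lineno, f"summit {summit} outside [{start}, {end})")
        else:
            summit = (start + end) // 2
        peaks.append(
            Peak(
                interval=GenomicInterval(chrom, start, end),
                summit=summit,
                signal=signal,
                source=library_name,
                name=name,
            )
        )
    return peaks


def write_peaks_bed(peaks: Iterable[Peak], path: str) -> None:
    """Write peaks as BED6 + summit-offset column (round-trips exactly)."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name or '.'}\t"
                f"{p.signal!r}\t.\t{p.summit - p.start}\n"
            )


def read_tags(path: str, total_unique_reads: int, name: str = "") -> TagLibrary:
    """Read a tag BED into a :class:`TagLibrary` of cut sites.

    Each record contributes one cut site at its 5' position: ``start`` for
    the + strand (or when no strand column is present), ``end - 1`` for the
    - strand. No Tn5 offset correction is applied; shifted input, if wanted,
    must be shifted upstream.
    """
    if total_unique_reads <= 0:
        raise ValueError(f"total_unique_reads must be positive, got {total_unique_reads}")
    sites: dict[str, list[int]] = {}
    for lineno, fields in _bed_lines(path):
        if len(fields) < 3:
            raise BedParseError(path, lineno, f"expected >= 3 columns, got {len(fields)}")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise BedParseError(path, lineno, f"non-integer coordinate: {exc}") from None
        if end <= start:
            raise BedParseError(path, lineno, f"rejected record: end {end} <= start {start}")
        strand = fields[5] if len(fields) > 5 else "+"
        cut = end - 1 if strand == "-" else start
        sites.setdefault(chrom, []).append(cut)
    if not name:
        name = os.path.splitext(os.path.basename(path))[0]
    return TagLibrary(name=name, cut_sites=sites, total_unique_reads=total_unique_reads)


def write_tags_bed(
    records: Iterable[Tuple[str, int, int, str]], path: str
) -> None:
    """Write tag records as BED6; each record is (chrom, start, end, strand)."""
    with open(path, "w") as fh:
        for i, (chrom, start, end, strand) in enumerate(records):
            fh.write(f"{chrom}\t{start}\t{end}\tr{i}\t0\t{strand}\n")


def read_bedgraph(path: str) -> List[Tuple[GenomicInterval, float]]:
    out: List[Tuple[GenomicInterval, float]] = []
    for lineno, fields in _bed_lines(path):
        if len(fields) != 4:
            raise BedParseError(path, lineno, f"bedGraph needs 4 columns, got {len(fields)}")
        out.append(
            (GenomicInterval(fields[0], int(fields[1]), int(fields[2])), float(fields[3]))
        )
    return out


def write_bedgraph(coverage: Iterable[Tuple[GenomicInterval, float]], path: str) -> None:
    """Write per-interval scaled coverage; values keep full float precision."""
    with open(path, "w") as fh:
        for iv, value in coverage:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{value!r}\n")


def read_chrom_sizes(path: str) -> GenomeLayout:
    """Read a UCSC-style 2-column chromosome sizes TSV."""
    lengths = {}
    for lineno, fields in _bed_lines(path):
        if len(fields) < 2:
            raise BedParseError(path, lineno, "chrom sizes needs 2 columns")
        lengths[fields[0]] = int(fields[1])
    return GenomeLayout(lengths)


def write_chrom_sizes(layout: GenomeLayout, path: str) -> None:
    with open(path, "w") as fh:
        for chrom, length in layout.lengths.items():
            fh.write(f"{chrom}\t{length}\n")


def read_expression_tsv(path: str) -> pd.DataFrame:
    """Read a genes x samples table of non-negative normalized tag counts."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene identifiers: {dups[:5]}")
    if (df.values < 0).any():
        raise ValueError("expression values must be non-negative")
    return df


def write_expression_tsv(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index_label="gene_id")


def filter_chromosomes(records: Sequence, exclude_names: Set[str] = MITOCHONDRIAL) -> list:
    """Drop records on excluded chromosomes (mitochondrial by default).

    Works on anything exposing ``.chrom`` (Peak, GenomicInterval) or on
    tuples whose first element is the chromosome name. Survivor order is
    preserved.
    """

    def chrom_of(rec) -> str:
        if hasattr(rec, "chrom"):
            return rec.chrom
        return rec[0]

    return [rec for rec in records if chrom_of(rec) not in exclude_names]
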