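"""Readers and writers for the genomic file formats the pipeline consumes.

All coordinates are 0-based half-open (BED-native) throughout the package,
so BED input and output need no conversion. Supported formats:

* BED3 / BED6 for generic intervals,
* ENCODE narrowPeak (10 columns) for peaks with summits,
* BED6 where each record is one aligned read ("read tags"),
* TSV with a header row for counts, matrices and tabular results.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

_VALID_STRANDS = {"+", "-", "."}

# Text written as '-' in BED; the unicode minus sometimes survives copy/paste.
_STRAND_ALIASES = {"−": "-"}


class FormatError(ValueError):
    """A malformed record in a genomic text file (carries the line number)."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` with optional strand/score."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"strand must be one of +, -, . (got {self.strand!r})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp (half-open semantics)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class PeakSummit:
    """Single-base summit of a called peak, with the caller's peak score."""

    chrom: str
    pos: int
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"summit position must be >= 0, got {self.pos}")


@dataclass(frozen=True)
class ReadTag:
    """The 5' end of one aligned read; strand is mandatory (shifting needs it)."""

    chrom: str
    five_prime: int
    strand: str

    def __post_init__(self) -> None:
        if self.five_prime < 0:
            raise ValueError(f"5' position must be >= 0, got {self.five_prime}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"read tag strand must be + or -, got {self.strand!r}")


@dataclass
class GeneAnnotation:
    """TSS annotation: one row per transcript (gene_id, chrom, tss, strand)."""

    table: pd.DataFrame

    REQUIRED = ("gene_id", "chrom", "tss", "strand")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"annotation lacks columns: {missing}")
        if len(self.table) == 0:
            raise ValueError("annotation is empty")
        if (self.table["tss"] < 0).any():
            raise ValueError("TSS positions must be >= 0")
        bad = set(self.table["strand"]) - _VALID_STRANDS
        if bad:
            raise ValueError(f"invalid strand values: {sorted(bad)}")
        self.table = self.table.reset_index(drop=True)

    @property
    def gene_ids(self) -> list[str]:
        return list(dict.fromkeys(self.table["gene_id"]))

    def __len__(self) -> int:
        return len(self.table)


def _split_line(line: str, lineno: int, min_cols: int, path: str) -> list[str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) == 1:  # tolerate space-separated toy files
        fields = line.split()
    if len(fields) < min_cols:
        raise FormatError(
            f"{path}:{lineno}: expected >= {min_cols} columns, got {len(fields)}"
        )
    return fields


def _parse_coords(fields: Sequence[str], lineno: int, path: str) -> tuple[str, int, int]:
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
    if end <= start:
        raise FormatError(
            f"{path}:{lineno}: end ({end}) must exceed start ({start})"
        )
    return fields[0], start, end


def read_intervals(path: str | Path, fmt: str = "bed6"):
    """Read intervals from a BED3/BED6/narrowPeak file.

    Returns a list of :class:`GenomicInterval`; for ``fmt='narrowPeak'``
    returns ``(intervals, summits)`` where the tenth column's summit offset
    is converted to an absolute position (``start + offset``). An offset of
    -1 (summit absent) falls back to the interval midpoint (floor).

    narrowPeak peak scores are taken from the signalValue column; the BED
    score column is frequently capped or zeroed by peak callers.
    """
    fmt = fmt.lower()
    if fmt not in {"bed3", "bed6", "narrowpeak"}:
        raise ValueError(f"unknown format {fmt!r}")
    min_cols = {"bed3": 3, "bed6": 6, "narrowpeak": 10}[fmt]
    intervals: list[GenomicInterval] = []
    summits: list[PeakSummit] = []
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = _split_line(line, lineno, min_cols, str(path))
            chrom, start, end = _parse_coords(fields, lineno, str(path))
            if fmt == "bed3":
                intervals.append(GenomicInterval(chrom, start, end))
                continue
            name = fields[3]
            strand = _STRAND_ALIASES.get(fields[5], fields[5])
            if strand not in _VALID_STRANDS:
                raise FormatError(f"{path}:{lineno}: bad strand {fields[5]!r}")
            if fmt == "bed6":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad score") from exc
                intervals.append(GenomicInterval(chrom, start, end, strand, score, name))
                continue
            try:
                signal = float(fields[6])
                offset = int(fields[9])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad narrowPeak column") from exc
            intervals.append(GenomicInterval(chrom, start, end, strand, signal, name))
            pos = start + offset if offset >= 0 else start + (end - start) // 2
            summits.append(PeakSummit(chrom, pos, signal))
    if fmt == "narrowpeak":
        return intervals, summits
    return intervals


def write_intervals(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    fmt: str = "bed6",
    summits: Sequence[PeakSummit] | None = None,
) -> None:
    """Write intervals as BED6 or narrowPeak (summits required for the latter)."""
    fmt = fmt.lower()
    intervals = list(intervals)
    with open(path, "w") as handle:
        if fmt == "bed6":
            for iv in intervals:
                handle.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                    f"{iv.score:.10g}\t{iv.strand}\n"
                )
        elif fmt == "narrowpeak":
            if summits is None or len(summits) != len(intervals):
                raise ValueError("narrowPeak output needs one summit per interval")
            for iv, sm in zip(intervals, summits):
                handle.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t"
                    f"{iv.strand}\t{iv.score:.10g}\t-1\t-1\t{sm.pos - iv.start}\n"
                )
        else:
            raise ValueError(f"unknown format {fmt!r}")


def read_tags(path: str | Path) -> list[ReadTag]:
    """Read aligned-read tags from BED6 (one record per read).

    The 5' end is the interval start for '+' reads and ``end - 1`` for '-'
    reads (half-open convention). A missing or '.' strand is an error: the
    downstream 5'-shift is strand-dependent.
    """
    tags: list[ReadTag] = []
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = _split_line(line, lineno, 6, str(path))
            chrom, start, end = _parse_coords(fields, lineno, str(path))
            strand = _STRAND_ALIASES.get(fields[5], fields[5])
            if strand not in {"+", "-"}:
                raise FormatError(
                    f"{path}:{lineno}: read tags require strand + or -, got "
                    f"{fields[5]!r}"
                )
            five_prime = start if strand == "+" else end - 1
            tags.append(ReadTag(chrom, five_prime, strand))
    return tags


def write_tags(
    tags: Iterable[ReadTag], path: str | Path, read_length: int = 50
) -> None:
    """Write read tags as BED6 records of ``read_length`` bp anchored at the 5' end."""
    with open(path, "w") as handle:
        for i, tag in enumerate(tags):
            if tag.strand == "+":
                start, end = tag.five_prime, tag.five_prime + read_length
            else:
                start = max(0, tag.five_prime - read_length + 1)
                end = tag.five_prime + 1
            handle.write(f"{tag.chrom}\t{start}\t{end}\tr{i}\t0\t{tag.strand}\n")


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame as TSV with header; floats at 12 significant digits."""
    frame.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table` (types inferred)."""
    return pd.read_csv(path, sep="\t")


def read_gene_annotation(path: str | Path) -> GeneAnnotation:
    """Read a TSS table (TSV with gene_id, chrom, tss, strand) or BED6.

    In BED6 the interval start is taken as the TSS for '+' transcripts and
    ``end - 1`` for '-' transcripts; the name column is the gene id.
    """
    path = Path(path)
    with open(path) as handle:
        first = handle.readline()
    if first.startswith("gene_id"):
        table = pd.read_csv(path, sep="\t")
        return GeneAnnotation(table)
    rows = []
    for iv in read_intervals(path, "bed6"):
        tss = iv.start if iv.strand != "-" else iv.end - 1
        rows.append({"gene_id": iv.name, "chrom": iv.chrom, "tss": tss,
                     "strand": iv.strand})
    return GeneAnnotation(pd.DataFrame(rows))
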