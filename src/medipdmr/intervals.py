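"""Genomic-interval primitives shared by every pipeline stage.

Coordinates follow the BED convention throughout: 0-based, half-open
``[start, end)``.  Two intervals overlap only if they share at least one
base, so touching intervals (``end == start``) do not overlap and are not
merged.  Inputs in 1-based dialects must be converted at the boundary.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "BedParseError",
    "read_bed",
    "write_bed",
    "merge_overlapping",
    "intersect",
]


class BedParseError(ValueError):
    """Raised for malformed BED lines; the message names the line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome.

    ``strand`` is ``"+"``, ``"-"`` or ``"."`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class IntervalSet:
    """An ordered collection of :class:`GenomicInterval` with optional names.

    Construction sorts by ``(chrom, start, end)``; ``names`` (e.g. gene ids
    for feature BEDs) stay aligned with the intervals.  The set is not
    merged automatically — call :func:`merge_overlapping` for that.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        label: str = "",
        names: Sequence[str] | None = None,
    ) -> None:
        ivs = list(intervals)
        if names is not None:
            if len(names) != len(ivs):
                raise ValueError("names must align with intervals")
            order = sorted(range(len(ivs)), key=lambda i: ivs[i])
            self.intervals = [ivs[i] for i in order]
            self.names: list[str] | None = [str(names[i]) for i in order]
        else:
            self.intervals = sorted(ivs)
            self.names = None
        self.label = label

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)}, label={self.label!r})"

    @property
    def total_length(self) -> int:
        return sum(iv.length for iv in self.intervals)

    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": np.asarray([iv.start for iv in self.intervals], dtype=np.int64),
                "end": np.asarray([iv.end for iv in self.intervals], dtype=np.int64),
                "strand": [iv.strand for iv in self.intervals],
            }
        )
        if self.names is not None:
            df.insert(3, "name", self.names)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label: str = "") -> "IntervalSet":
        strands = df["strand"] if "strand" in df else ["."] * len(df)
        ivs = [
            GenomicInterval(str(c), int(s), int(e), str(st))
            for c, s, e, st in zip(df["chrom"], df["start"], df["end"], strands)
        ]
        names = [str(n) for n in df["name"]] if "name" in df else None
        return cls(ivs, label=label, names=names)


def _is_data_line(line: str) -> bool:
    s = line.strip()
    if not s or s.startswith("#"):
        return False
    return not (s.startswith("track") or s.startswith("browser"))


def read_bed(
    path: str | Path | io.TextIOBase,
    label: str = "",
    normalize_chr_prefix: bool = False,
) -> IntervalSet:
    """Read a BED3/BED6 file into an :class:`IntervalSet`.

    Track, browser and ``#`` comment lines are skipped.  Chromosome names
    are matched exactly downstream; ``normalize_chr_prefix=True`` opts in
    to prepending ``chr`` where missing (never done silently).
    """
    if isinstance(path, io.TextIOBase):
        lines = path.readlines()
        src = getattr(path, "name", "<stream>")
    else:
        src = str(path)
        with open(path) as fh:
            lines = fh.readlines()
    ivs: list[GenomicInterval] = []
    names: list[str] = []
    any_name = False
    for lineno, raw in enumerate(lines, start=1):
        if not _is_data_line(raw):
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise BedParseError(
                f"{src}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}"
            )
        chrom = fields[0]
        if normalize_chr_prefix and not chrom.startswith("chr"):
            chrom = "chr" + chrom
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise BedParseError(f"{src}:{lineno}: non-integer coordinate") from exc
        strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
        try:
            ivs.append(GenomicInterval(chrom, start, end, strand))
        except ValueError as exc:
            raise BedParseError(f"{src}:{lineno}: {exc}") from exc
        name = fields[3] if len(fields) >= 4 else "."
        names.append(name)
        any_name = any_name or (len(fields) >= 4)
    return IntervalSet(ivs, label=label, names=names if any_name else None)


def write_bed(iset: IntervalSet, path: str | Path) -> None:
    """Write BED3 (or BED6 when the set carries names or strands)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(iset):
            if iset.names is not None or any(j.strand != "." for j in iset):
                name = iset.names[i] if iset.names is not None else "."
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def merge_overlapping(iset: IntervalSet) -> IntervalSet:
    """Single-linkage union of intervals sharing at least one base.

    Touching half-open intervals (``a.end == b.start``) share no base and
    stay separate.  Names are dropped (a merged interval has no single
    source).  Idempotent; empty in, empty out.
    """
    merged: list[GenomicInterval] = []
    cur: GenomicInterval | None = None
    for iv in iset:  # already sorted
        if cur is not None and iv.chrom == cur.chrom and iv.start < cur.end:
            if iv.end > cur.end:
                cur = GenomicInterval(cur.chrom, cur.start, iv.end)
        else:
            if cur is not None:
                merged.append(cur)
            cur = GenomicInterval(iv.chrom, iv.start, iv.end)
    if cur is not None:
        merged.append(cur)
    return IntervalSet(merged, label=iset.label)


def intersect(a: IntervalSet, b: IntervalSet) -> pd.DataFrame:
    """All pairs of intervals from ``a`` and ``b`` sharing >=1 base.

    Returns a table with one row per overlapping pair:
    ``a_index, a_chrom, a_start, a_end, b_index, b_chrom, b_start, b_end,
    overlap`` where ``overlap = min(ends) - max(starts)``.  Indices refer to
    positions within each (sorted) input set, so callers can map back to
    names.
    """
    rows: list[tuple] = []
    a_by_chrom: dict[str, list[tuple[int, GenomicInterval]]] = {}
    for i, iv in enumerate(a):
        a_by_chrom.setdefault(iv.chrom, []).append((i, iv))
    b_by_chrom: dict[str, list[tuple[int, GenomicInterval]]] = {}
    for j, iv in enumerate(b):
        b_by_chrom.setdefault(iv.chrom, []).append((j, iv))
    for chrom in sorted(set(a_by_chrom) & set(b_by_chrom)):
        av, bv = a_by_chrom[chrom], b_by_chrom[chrom]
        b_starts = np.asarray([iv.start for _, iv in bv])
        b_ends = np.asarray([iv.end for _, iv in bv])
        # b is sorted by start; ends need not be monotone.  Candidates for a
        # given a-interval are b's with start < a.end and end > a.start; the
        # running max of ends bounds where the latter can first hold.
        b_cummax_end = np.maximum.accumulate(b_ends)
        for i, iva in av:
            hi = int(np.searchsorted(b_starts, iva.end, side="left"))
            lo = int(np.searchsorted(b_cummax_end, iva.start, side="right"))
            for k in range(lo, hi):
                if b_ends[k] > iva.start:
                    j, ivb = bv[k]
                    ov = min(iva.end, ivb.end) - max(iva.start, ivb.start)
                    rows.append(
                        (i, chrom, iva.start, iva.end, j, ivb.chrom, ivb.start, ivb.end, ov)
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "a_index", "a_chrom", "a_start", "a_end",
            "b_index", "b_chrom", "b_start", "b_end", "overlap",
        ],
    )


def write_intersect_table(table: pd.DataFrame, path: str | Path) -> None:
    """Deterministic TSV serialization of an intersect table (with header)."""
    table.to_csv(path, sep="\t", index=False)
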