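"""Consensus peakset construction and fragment counting.

Per-sample peaksets are merged single-linkage across the pooled peaks of
all samples (DiffBind-style consensus); a merged region's support is the
number of distinct samples contributing at least one overlapping peak,
and regions supported by fewer than ``min_samples`` samples are dropped.
Sex chromosomes are removed before modeling.  The count matrix assigns a
fragment to the region containing its start base, so every fragment
counts at most once and library-size accounting stays exact.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .intervals import IntervalSet

DEFAULT_SEX_CHROMS = ("chrX", "chrY")

__all__ = [
    "build_consensus",
    "remove_sex_chromosomes",
    "count_fragments",
    "write_consensus_bed",
]


def build_consensus(
    peaksets: Mapping[str, IntervalSet], min_samples: int = 3
) -> pd.DataFrame:
    """Merge pooled peaks into consensus regions with a support filter.

    Returns a table ``region_id, chrom, start, end, length, support``
    sorted by genomic position, where support counts distinct samples with
    >=1 peak overlapping the merged region.  Permutation-invariant in
    sample order.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    if not peaksets:
        raise ValueError("need at least one peakset")
    recs: list[tuple[str, int, int, int]] = []
    for si, sample in enumerate(sorted(peaksets)):
        for iv in peaksets[sample]:
            recs.append((iv.chrom, iv.start, iv.end, si))
    rows: list[tuple[str, int, int, int]] = []
    if recs:
        recs.sort()
        cur_chrom, cur_start, cur_end = recs[0][0], recs[0][1], recs[0][2]
        cur_samples = {recs[0][3]}
        for chrom, start, end, si in recs[1:]:
            if chrom == cur_chrom and start < cur_end:
                cur_end = max(cur_end, end)
                cur_samples.add(si)
            else:
                rows.append((cur_chrom, cur_start, cur_end, len(cur_samples)))
                cur_chrom, cur_start, cur_end = chrom, start, end
                cur_samples = {si}
        rows.append((cur_chrom, cur_start, cur_end, len(cur_samples)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "support"])
    df = df[df["support"] >= min_samples].reset_index(drop=True)
    df.insert(0, "region_id", [f"R{i + 1:05d}" for i in range(len(df))])
    df["length"] = df["end"] - df["start"]
    return df[["region_id", "chrom", "start", "end", "length", "support"]]


def remove_sex_chromosomes(
    regions: pd.DataFrame, sex_chroms: tuple[str, ...] = DEFAULT_SEX_CHROMS
) -> pd.DataFrame:
    """Drop regions on the given chromosomes; all others pass unchanged."""
    keep = ~regions["chrom"].isin(sex_chroms)
    return regions[keep].reset_index(drop=True)


def count_fragments(
    fragments: Mapping[str, IntervalSet], regions: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Region-by-sample fragment counts plus per-sample library sizes.

    A fragment is counted for the region containing its start base
    (regions are non-overlapping, so assignment is unique); fragments
    starting outside every region count toward the library size only.
    Library size = total fragments of the sample.
    """
    starts_by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, sub in regions.groupby("chrom"):
        order = np.argsort(sub["start"].to_numpy(), kind="mergesort")
        starts_by_chrom[chrom] = (
            sub["start"].to_numpy()[order],
            sub["end"].to_numpy()[order],
            sub.index.to_numpy()[order],
        )
    n_r = len(regions)
    samples = list(fragments)
    counts = np.zeros((n_r, len(samples)), dtype=np.int64)
    libsizes = np.zeros(len(samples), dtype=np.int64)
    row_of = {idx: i for i, idx in enumerate(regions.index)}
    for si, sample in enumerate(samples):
        fs = fragments[sample]
        libsizes[si] = len(fs)
        by_chrom: dict[str, list[int]] = {}
        for iv in fs:
            by_chrom.setdefault(iv.chrom, []).append(iv.start)
        for chrom, fstarts in by_chrom.items():
            if chrom not in starts_by_chrom:
                continue
            rs, re, ridx = starts_by_chrom[chrom]
            fstarts_arr = np.asarray(fstarts)
            j = np.searchsorted(rs, fstarts_arr, side="right") - 1
            ok = (j >= 0) & (fstarts_arr < re[np.clip(j, 0, None)])
            for jj in j[ok]:
                counts[row_of[ridx[jj]], si] += 1
    counts_df = pd.DataFrame(counts, index=regions["region_id"].to_numpy(),
                             columns=samples)
    counts_df.index.name = "region_id"
    return counts_df, pd.Series(libsizes, index=samples, name="library_size")


def write_consensus_bed(regions: pd.DataFrame, path: str | Path) -> None:
    """BED-like TSV: chrom, start, end, region_id, support."""
    regions[["chrom", "start", "end", "region_id", "support"]].to_csv(
        path, sep="\t", index=False, header=False
    )
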