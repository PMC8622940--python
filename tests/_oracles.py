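"""Independent brute-force oracles used across the test suite.

Everything here works per base (occupancy bitmaps) or by exhaustive
enumeration, deliberately ignoring the package's own algorithms.
"""

from __future__ import annotations

import itertools

import numpy as np


def bitmap_merge(intervals: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """Merge via per-base occupancy: maximal runs of covered bases.

    Coordinates are doubled so that touching half-open intervals (which
    share no base and must stay separate) leave a one-slot gap: interval
    [s, e) covers slots 2s .. 2e-2.
    """
    out = []
    for chrom in sorted({c for c, _, _ in intervals}):
        ivs = [(s, e) for c, s, e in intervals if c == chrom]
        hi = 2 * max(e for _, e in ivs)
        cov = np.zeros(hi + 1, dtype=bool)
        for s, e in ivs:
            cov[2 * s : 2 * e - 1] = True
        start = None
        for pos in range(hi + 1):
            if cov[pos] and start is None:
                start = pos
            elif not cov[pos] and start is not None:
                out.append((chrom, start // 2, (pos - 1) // 2 + 1))
                start = None
        if start is not None:
            out.append((chrom, start // 2, hi // 2))
    return out


def bitmap_intersect(
    a: list[tuple[str, int, int]], b: list[tuple[str, int, int]]
) -> set[tuple[int, int, int]]:
    """All (i, j, overlap) pairs by brute-force base counting."""
    out = set()
    for i, (ca, sa, ea) in enumerate(a):
        for j, (cb, sb, eb) in enumerate(b):
            if ca != cb:
                continue
            ov = sum(1 for x in range(sa, ea) if sb <= x < eb)
            if ov > 0:
                out.add((i, j, ov))
    return out


def bitmap_consensus(
    peaksets: dict[str, list[tuple[str, int, int]]], min_samples: int
) -> list[tuple[str, int, int, int]]:
    """Consensus regions + support via per-base occupancy of pooled peaks."""
    pooled = [iv for ivs in peaksets.values() for iv in ivs]
    if not pooled:
        return []
    merged = bitmap_merge(pooled)
    out = []
    for chrom, s, e in merged:
        support = sum(
            1
            for ivs in peaksets.values()
            if any(c == chrom and st < e and s < en for c, st, en in ivs)
        )
        if support >= min_samples:
            out.append((chrom, s, e, support))
    return out


def bh_stepup(p: np.ndarray) -> np.ndarray:
    """Textbook Benjamini-Hochberg step-up: q_i = min_{p_(j) >= p_i} p_(j) m/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    q = np.empty(m)
    for i, pi in enumerate(p):
        candidates = [
            pj * m / rank
            for rank, pj in enumerate(sorted(p), start=1)
            if pj >= pi
        ]
        q[i] = min(min(candidates), 1.0)
    return q


def exhaustive_subset_tail(
    indicator: np.ndarray, k: int, observed: int, direction: str = "ge"
) -> float:
    """P(feature count >=/<= observed) over all C(n, k) subsets."""
    n = len(indicator)
    total = hits = 0
    for comb in itertools.combinations(range(n), k):
        c = int(indicator[list(comb)].sum())
        ok = c >= observed if direction == "ge" else c <= observed
        total += 1
        hits += ok
    return hits / total


def exhaustive_mean_tail(scores: np.ndarray, k: int, observed_mean: float) -> float:
    """P(mean of a random k-subset >= observed) by exhaustive enumeration."""
    n = len(scores)
    total = hits = 0
    for comb in itertools.combinations(range(n), k):
        total += 1
        hits += float(np.mean(scores[list(comb)])) >= observed_mean - 1e-12
    return hits / total
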