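"""DMR classification, sex-tier reassignment, direction and size summaries.

Per-region significance flags in the three contrasts define the category:

* PAE-specific — significant in PAEvCON and PAEvPF but not PFvCON;
* PF-specific  — significant in PFvCON and PAEvPF but not PAEvCON;
* shared       — significant in both PAEvCON and PFvCON.

The rules are mutually exclusive.  A region called in the combined-sex
(sex-concordant) tier that is also called, same category, in a single-sex
tier is treated as driven by that sex and removed from the concordant
tier; the sex tiers are never altered.  Direction (up-/down-methylated)
and a >=1.5-fold robustness flag come from the two contrasts that define
the category, and the balance of up vs down calls is tested against a
50/50 split with a Monte-Carlo chi-squared test (add-one simulated
p-value, as R's ``chisq.test(..., simulate.p.value=TRUE)`` computes it).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CATEGORIES = ("PAE_specific", "PF_specific", "shared")
FOLD_THRESHOLD_LOG2 = math.log2(1.5)

__all__ = [
    "classify_region",
    "classify_table",
    "reassign_sex_tiers",
    "direction_and_robustness",
    "direction_chisq_mc",
    "DirectionTestResult",
    "summarize_dmrs",
]


def classify_region(pae_v_con: bool, pae_v_pf: bool, pf_v_con: bool) -> str:
    """Map the three significance flags to a category (or ``"none"``)."""
    if pae_v_con and pae_v_pf and not pf_v_con:
        return "PAE_specific"
    if pf_v_con and pae_v_pf and not pae_v_con:
        return "PF_specific"
    if pae_v_con and pf_v_con:
        return "shared"
    return "none"


# defining contrasts per category; the second PF entry is sign-flipped so
# direction reads as PF-vs-others ("down in PF" = negative both)
_DEFINING = {
    "PAE_specific": (("PAEvCON", 1.0), ("PAEvPF", 1.0)),
    "PF_specific": (("PFvCON", 1.0), ("PAEvPF", -1.0)),
    "shared": (("PAEvCON", 1.0), ("PFvCON", 1.0)),
}


def direction_and_robustness(
    category: str, logfc: dict[str, float]
) -> tuple[str, bool]:
    """Direction and >=1.5-fold flag from the category's defining contrasts.

    ``up`` when both (sign-adjusted) defining log fold changes are
    positive, ``down`` when both negative, else ``inconsistent``; robust
    when both exceed log2(1.5) in magnitude.
    """
    if category not in _DEFINING:
        raise ValueError(f"unknown category {category!r}")
    vals = [sign * logfc[name] for name, sign in _DEFINING[category]]
    if all(v > 0 for v in vals):
        direction = "up"
    elif all(v < 0 for v in vals):
        direction = "down"
    else:
        direction = "inconsistent"
    robust = all(abs(v) >= FOLD_THRESHOLD_LOG2 for v in vals)
    return direction, robust


def classify_table(
    contrast_table: pd.DataFrame,
    regions: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Turn one tier's long-format contrast table into DMR calls.

    Returns one row per region with a non-``none`` category:
    ``region_id, tier, category, direction, robust_1p5fold, size_bp``.
    ``regions`` (with chrom/start/end) supplies sizes when given.
    """
    wide_q = contrast_table.pivot(index="region_id", columns="contrast", values="q")
    wide_fc = contrast_table.pivot(index="region_id", columns="contrast", values="logFC")
    tier = contrast_table["tier"].iloc[0] if "tier" in contrast_table else "unknown"
    sig = wide_q < alpha
    rows = []
    for rid in wide_q.index:
        cat = classify_region(
            bool(sig.at[rid, "PAEvCON"]),
            bool(sig.at[rid, "PAEvPF"]),
            bool(sig.at[rid, "PFvCON"]),
        )
        if cat == "none":
            continue
        direction, robust = direction_and_robustness(
            cat, wide_fc.loc[rid].to_dict()
        )
        rows.append(
            {
                "region_id": rid,
                "tier": tier,
                "category": cat,
                "direction": direction,
                "robust_1p5fold": robust,
            }
        )
    calls = pd.DataFrame(
        rows, columns=["region_id", "tier", "category", "direction", "robust_1p5fold"]
    )
    if regions is not None and len(calls):
        sizes = (regions["end"] - regions["start"]).to_numpy()
        size_of = dict(zip(regions["region_id"], sizes))
        calls["size_bp"] = calls["region_id"].map(size_of)
    else:
        calls["size_bp"] = pd.array([pd.NA] * len(calls), dtype="Int64")
    return calls


def reassign_sex_tiers(
    concordant: pd.DataFrame, female: pd.DataFrame, male: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Assign DMRs found in both a sex tier and the concordant tier to the sex tier.

    A concordant call whose (region_id, category) also appears in the
    female or male tier is removed from the concordant tier — it is taken
    to be driven primarily by that sex.  Sex tiers are returned unchanged.
    A region called in both sex tiers is kept in both, with a warning.
    """
    fem_keys = set(zip(female["region_id"], female["category"]))
    mal_keys = set(zip(male["region_id"], male["category"]))
    both = fem_keys & mal_keys
    if both:
        logger.warning(
            "%d DMR(s) appear in both the female and male tiers; kept in both",
            len(both),
        )
    drop = concordant.apply(
        lambda r: (r["region_id"], r["category"]) in fem_keys
        or (r["region_id"], r["category"]) in mal_keys,
        axis=1,
    ) if len(concordant) else pd.Series(dtype=bool)
    out_conc = concordant[~drop].reset_index(drop=True) if len(concordant) else concordant
    return out_conc, female.reset_index(drop=True), male.reset_index(drop=True)


@dataclass(frozen=True)
class DirectionTestResult:
    """Monte-Carlo chi-squared test of up/down balance against 50/50."""

    n_up: int
    n_down: int
    chi2: float
    p_sim: float
    B: int


def direction_chisq_mc(
    n_up: int, n_down: int, B: int = 2000, seed: int | None = 0
) -> DirectionTestResult:
    """Goodness-of-fit chi-squared vs an expected 50% split, simulated p.

    chi2 = (n_up - E)^2/E + (n_down - E)^2/E with E = n/2; replicate
    tables are Binomial(n, 1/2) and
    ``p_sim = (1 + #{replicate chi2 >= observed}) / (B + 1)``.
    The smallest attainable p is 1/(B+1); with an odd total every
    replicate ties or exceeds the most balanced observable split, so
    near-balanced odd splits give exactly 1.
    """
    n = n_up + n_down
    if n < 1:
        raise ValueError("need at least one classified DMR")
    if B < 1:
        raise ValueError("B must be >= 1")
    expected = n / 2.0
    chi2 = (n_up - expected) ** 2 / expected + (n_down - expected) ** 2 / expected
    rng = np.random.Generator(np.random.PCG64(seed))
    rep_up = rng.binomial(n, 0.5, size=B)
    rep_chi2 = (rep_up - expected) ** 2 / expected + (
        (n - rep_up) - expected
    ) ** 2 / expected
    p_sim = (1.0 + int((rep_chi2 >= chi2).sum())) / (B + 1.0)
    return DirectionTestResult(n_up=n_up, n_down=n_down, chi2=float(chi2),
                               p_sim=float(p_sim), B=B)


def summarize_dmrs(calls: pd.DataFrame) -> dict:
    """Size range/median plus counts by tier x category x direction."""
    out: dict = {"n_total": int(len(calls))}
    sizes = calls["size_bp"].dropna().astype(float)
    if len(sizes):
        out["size_min"] = float(sizes.min())
        out["size_max"] = float(sizes.max())
        out["size_median"] = float(sizes.median())
    counts = (
        calls.groupby(["tier", "category", "direction"], observed=True)
        .size()
        .rename("n")
        .reset_index()
        if len(calls)
        else pd.DataFrame(columns=["tier", "category", "direction", "n"])
    )
    out["counts"] = counts
    return out
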