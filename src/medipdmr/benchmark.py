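"""In-memory composition of the pipeline plus recovery scoring.

Used to validate the method on synthetic cohorts: run counts through
normalization, three-tier testing and classification without touching
disk, then compare the final DMR calls against the generator's planted
truth (sensitivity, empirical false-discovery proportion and direction
agreement per category).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import classify, differential, normalize
from .consensus import remove_sex_chromosomes
from .simulate import CATEGORIES, SyntheticStudy

__all__ = ["analyze_study", "score_recovery"]


def analyze_study(
    study: SyntheticStudy,
    alpha: float = 0.05,
    moderate: bool = True,
    sex_chroms: tuple[str, ...] = ("chrX", "chrY"),
) -> dict:
    """Normalize, test and classify one synthetic cohort in memory.

    Returns regions (autosomal), per-tier contrast tables, the final DMR
    calls after sex-tier reassignment, and the truth restricted to tested
    regions.
    """
    regions = remove_sex_chromosomes(study.regions, sex_chroms)
    counts = study.counts.reindex(regions["region_id"])
    lengths = regions.set_index("region_id")["length"]
    mat = normalize.log_transform(normalize.rpkm(counts, lengths, study.library_sizes))
    batch = pd.Series(
        study.design["batch"].to_numpy(), index=study.design["sample_id"]
    )
    if batch.nunique() > 1:
        mat, _ = normalize.combat_adjust(
            mat, batch, normalize.build_protected_design(study.design)
        )
    tables: dict[str, pd.DataFrame] = {}
    calls: dict[str, pd.DataFrame] = {}
    for tier in differential.TIERS:
        tab = differential.run_tier(mat, study.design, tier, moderate=moderate)
        tables[tier] = tab
        calls[tier] = classify.classify_table(tab, regions, alpha=alpha)
    conc, fem, mal = classify.reassign_sex_tiers(
        calls["concordant"], calls["female"], calls["male"]
    )
    final_calls = pd.concat([conc, fem, mal], ignore_index=True)
    truth = study.truth[study.truth["region_id"].isin(regions["region_id"])]
    return {
        "regions": regions,
        "matrix": mat,
        "tables": tables,
        "final_calls": final_calls,
        "truth": truth.reset_index(drop=True),
    }


def score_recovery(final_calls: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Per-category recovery of planted DMRs.

    A planted region counts as recovered when any tier's final calls
    contain it with the planted category; a call is a false discovery
    when the region was not planted with that category.  Direction
    agreement is judged over correctly categorised calls.  Returns one
    row per category with ``sensitivity`` (pooled and per planted tier),
    ``fdr`` and ``direction_agreement``.
    """
    truth = truth.set_index("region_id")
    detected = set(zip(final_calls["region_id"], final_calls["category"]))
    rows = []
    for cat in CATEGORIES:
        planted = truth[truth["category"] == cat]
        n_planted = len(planted)
        hit = sum((rid, cat) in detected for rid in planted.index)
        per_tier = {}
        for tier in ("concordant", "female", "male"):
            sub = planted[planted["tier"] == tier]
            per_tier[tier] = (
                sum((rid, cat) in detected for rid in sub.index) / len(sub)
                if len(sub)
                else np.nan
            )
        called = final_calls[final_calls["category"] == cat]
        false = sum(
            truth.loc[rid, "category"] != cat for rid in called["region_id"]
        )
        dir_tot = dir_ok = 0
        for row in called.itertuples(index=False):
            t = truth.loc[row.region_id]
            if t["category"] == cat and t["direction"] in ("up", "down"):
                dir_tot += 1
                dir_ok += t["direction"] == row.direction
        rows.append(
            {
                "category": cat,
                "n_planted": n_planted,
                "n_called": len(called),
                "sensitivity": hit / n_planted if n_planted else np.nan,
                "sensitivity_concordant": per_tier["concordant"],
                "sensitivity_female": per_tier["female"],
                "sensitivity_male": per_tier["male"],
                "fdr": false / len(called) if len(called) else 0.0,
                "direction_agreement": dir_ok / dir_tot if dir_tot else np.nan,
            }
        )
    return pd.DataFrame(rows)
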