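"""Gene-score resampling (GSR) pathway enrichment and gene-list overlap.

Each gene is scored -log10 of the best (smallest) p-value over the
regions annotated to it for a given contrast.  A gene set's observed
statistic is the mean member score; its null is built by resampling the
same number of scores from all scored genes without replacement, with an
add-one empirical p-value and BH correction across retained sets.  Sets
outside the [min_size, max_size] bounds (counted over scored members)
are excluded.  A multifunctionality diagnostic re-runs the test with the
most promiscuous genes' scores removed and flags sets whose significance
depended on them.  Final pathway lists reuse the DMR contrast-
intersection logic (PAE-specific / PF-specific / shared) at the set
level, and external gene lists are overlapped case-insensitively.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .classify import classify_region
from .differential import bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "gene_scores",
    "gsr_test",
    "multifunctionality_check",
    "final_pathway_sets",
    "gene_list_overlap",
]


def gene_scores(
    contrast_table: pd.DataFrame, annotation: pd.DataFrame, contrast: str
) -> pd.DataFrame:
    """Per-gene scores: -log10 of the gene's best region p for one contrast.

    ``annotation`` maps region_id to semicolon-joined gene ids.  Genes
    with no annotated region are simply absent (logged at debug level).
    Returns ``gene_id, score, n_regions`` sorted by gene id.
    """
    sub = contrast_table[contrast_table["contrast"] == contrast]
    pmap = dict(zip(sub["region_id"], sub["p"]))
    best: dict[str, float] = {}
    nreg: dict[str, int] = {}
    for rid, genes in zip(annotation["region_id"], annotation["gene_ids"]):
        if rid not in pmap or not isinstance(genes, str) or not genes:
            continue
        p = pmap[rid]
        for g in genes.split(";"):
            if not g:
                continue
            nreg[g] = nreg.get(g, 0) + 1
            if g not in best or p < best[g]:
                best[g] = p
    rows = [
        {"gene_id": g, "score": -np.log10(max(best[g], 1e-300)), "n_regions": nreg[g]}
        for g in sorted(best)
    ]
    return pd.DataFrame(rows, columns=["gene_id", "score", "n_regions"])


def gsr_test(
    scores: pd.DataFrame,
    gene_sets: pd.DataFrame,
    iterations: int = 10_000,
    min_size: int = 2,
    max_size: int = 2000,
    seed: int | None = 0,
    chunk: int = 2000,
) -> pd.DataFrame:
    """Resampling test of mean member score per gene set.

    ``gene_sets`` is long format (set_id, gene_id).  Set size is the
    number of *scored* members; sets outside [min_size, max_size] are
    excluded (logged).  The null for a size-k set resamples k scores from
    the scored-gene universe without replacement, ``iterations`` times;
    ``p_emp = (1 + #{null mean >= observed}) / (iterations + 1)`` and q
    is BH across retained sets.
    """
    if len(scores) < min_size:
        raise ValueError("fewer scored genes than min_size")
    score_of = dict(zip(scores["gene_id"], scores["score"]))
    pool = scores["score"].to_numpy(dtype=float)
    n = len(pool)
    members: dict[str, list[float]] = {}
    for sid, gid in zip(gene_sets["set_id"], gene_sets["gene_id"]):
        if gid in score_of:
            members.setdefault(sid, []).append(score_of[gid])
    kept: list[tuple[str, int, float]] = []
    for sid in sorted(members):
        k = len(members[sid])
        if k < max(min_size, 2) or k > max_size:
            logger.info("gene set %s excluded (scored size %d)", sid, k)
            continue
        kept.append((sid, k, float(np.mean(members[sid]))))
    rng = np.random.Generator(np.random.PCG64(seed))
    # one null ensemble per distinct set size, shared across sets of that size
    null_means: dict[int, np.ndarray] = {}
    for k in sorted({k for _, k, _ in kept}):
        if k >= n:
            null_means[k] = np.full(iterations, pool.mean())
            continue
        means = np.empty(iterations)
        done = 0
        while done < iterations:
            c = min(chunk, iterations - done)
            keys = rng.random((c, n))
            idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
            means[done : done + c] = pool[idx].mean(axis=1)
            done += c
        null_means[k] = means
    rows = []
    for sid, k, obs in kept:
        # tie tolerance: observed and null means take different summation
        # paths, so exact ties can differ by a few ulp; resampling ties
        # must count toward the tail
        eps = 1e-9 * max(1.0, abs(obs))
        tail = int((null_means[k] >= obs - eps).sum())
        rows.append(
            {
                "set_id": sid,
                "size": k,
                "observed_score": obs,
                "p_emp": (1.0 + tail) / (iterations + 1.0),
            }
        )
    out = pd.DataFrame(rows, columns=["set_id", "size", "observed_score", "p_emp"])
    if len(out):
        out["q"] = bh_fdr(out["p_emp"].to_numpy())
    else:
        out["q"] = pd.Series(dtype=float)
    out["multifunctionality_flagged"] = False
    return out


def multifunctionality_check(
    gene_sets: pd.DataFrame,
    results: pd.DataFrame,
    scores: pd.DataFrame,
    k_top: int,
    alpha: float = 0.05,
    iterations: int = 10_000,
    min_size: int = 2,
    max_size: int = 2000,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Flag sets whose significance rests on highly multifunctional genes.

    Gene multifunctionality = number of retained sets containing the
    gene.  The ``k_top`` most multifunctional genes' scores are removed
    and the resampling test is re-run (same seed); a set is flagged when
    its re-run p exceeds ``alpha`` while the original did not.
    ``k_top = 0`` is a no-op.
    """
    if k_top < 0 or k_top > len(scores):
        raise ValueError(
            f"k_top must be in [0, {len(scores)}] (number of scored genes)"
        )
    out = results.copy()
    out["multifunctionality_flagged"] = False
    if k_top == 0 or results.empty:
        return out
    retained = set(results["set_id"])
    in_retained = gene_sets[gene_sets["set_id"].isin(retained)]
    multi = in_retained.groupby("gene_id").size()
    multi = multi.reindex(scores["gene_id"]).fillna(0)
    # deterministic tie-break: count desc, then gene id
    order = sorted(zip(-multi.to_numpy(), scores["gene_id"]))
    drop_genes = {g for _, g in order[:k_top]}
    reduced = scores[~scores["gene_id"].isin(drop_genes)]
    rerun = gsr_test(
        reduced, gene_sets, iterations=iterations, min_size=min_size,
        max_size=max_size, seed=seed,
    ).set_index("set_id")
    for i, row in out.iterrows():
        sid = row["set_id"]
        if sid in rerun.index:
            newly_ns = rerun.at[sid, "p_emp"] > alpha and row["p_emp"] <= alpha
        else:
            newly_ns = row["p_emp"] <= alpha  # set vanished without those genes
        out.at[i, "multifunctionality_flagged"] = bool(newly_ns)
    return out


def final_pathway_sets(
    results_per_contrast: dict[str, pd.DataFrame], alpha: float = 0.05
) -> dict[str, list[str]]:
    """Contrast-intersection of set-level significance, as for DMRs.

    A set counts as significant in a contrast when q < alpha and it is
    not multifunctionality-flagged there.  Returns category ->
    sorted set ids for PAE_specific / PF_specific / shared.
    """
    sig: dict[str, set[str]] = {}
    for contrast, res in results_per_contrast.items():
        ok = res[(res["q"] < alpha) & (~res["multifunctionality_flagged"])]
        sig[contrast] = set(ok["set_id"])
    all_sets = set().union(*sig.values()) if sig else set()
    out: dict[str, list[str]] = {c: [] for c in ("PAE_specific", "PF_specific", "shared")}
    for sid in sorted(all_sets):
        cat = classify_region(
            sid in sig.get("PAEvCON", set()),
            sid in sig.get("PAEvPF", set()),
            sid in sig.get("PFvCON", set()),
        )
        if cat != "none":
            out[cat].append(sid)
    return out


def gene_list_overlap(
    dmr_genes: dict[tuple[str, str], set[str] | list[str]],
    external_lists: dict[str, list[str]],
) -> pd.DataFrame:
    """Case-insensitive overlap of DMR genes with external gene lists.

    ``dmr_genes`` maps (tier, category) to gene symbols; both sides are
    uppercased and deduplicated.  Empty intersections are reported as
    empty strings, one row per list x tier x category.
    """
    rows = []
    for list_name in sorted(external_lists):
        ext = {str(g).upper() for g in external_lists[list_name] if str(g).strip()}
        for (tier, category) in sorted(dmr_genes):
            ours = {str(g).upper() for g in dmr_genes[(tier, category)]}
            hit = sorted(ext & ours)
            rows.append(
                {
                    "list": list_name,
                    "tier": tier,
                    "category": category,
                    "overlap_genes": ";".join(hit),
                    "n_overlap": len(hit),
                }
            )
    return pd.DataFrame(
        rows, columns=["list", "tier", "category", "overlap_genes", "n_overlap"]
    )
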