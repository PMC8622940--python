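"""Custom genomic-feature annotation and permutation enrichment.

Each consensus region receives every feature class it overlaps by at
least one base (CpG island, exon, intron, TSS-200 and TSS-1500
promoters, 5'/3' UTR); a region overlapping both an exon and an intron
of the same gene is additionally an intron/exon boundary, and a region
touching no gene-derived feature is intergenic.  A region can span
multiple features and multiple genes.

Enrichment of a DMR set for each feature is judged against a permutation
null: random subsets of the tested region universe of the same size as
the DMR set (drawn without replacement), with a one-sided add-one
empirical p-value and an enriched/depleted direction label.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .intervals import IntervalSet, intersect

GENE_FEATURES = ("exon", "intron", "promoter200", "promoter1500", "utr5", "utr3")
ALL_FEATURES = GENE_FEATURES + ("intron_exon_boundary", "cpg_island", "intergenic")

# feature-class key -> conventional BED file stem used by the generator
FEATURE_FILE_KEYS = {
    "exon": "exons",
    "intron": "introns",
    "promoter200": "promoter200",
    "promoter1500": "promoter1500",
    "utr5": "utr5",
    "utr3": "utr3",
    "cpg_island": "cpg_islands",
}

__all__ = [
    "annotate_regions",
    "permutation_enrichment",
    "ALL_FEATURES",
    "GENE_FEATURES",
]


def _overlap_hits(
    regions_iset: IntervalSet, feature_iset: IntervalSet
) -> list[tuple[int, str]]:
    """(region index, feature name) pairs for every >=1-base overlap."""
    table = intersect(regions_iset, feature_iset)
    names = feature_iset.names
    out = []
    for a_idx, b_idx in zip(table["a_index"], table["b_index"]):
        name = names[b_idx] if names is not None else "."
        out.append((int(a_idx), name))
    return out


def annotate_regions(
    regions: pd.DataFrame,
    features: dict[str, IntervalSet],
    gene_bodies: IntervalSet | None = None,
) -> pd.DataFrame:
    """Annotate each region with overlapping feature classes and gene ids.

    ``features`` maps class keys (``exon``, ``intron``, ``promoter200``,
    ``promoter1500``, ``utr5``, ``utr3``, ``cpg_island``) to interval
    sets; gene-derived sets should carry gene ids in ``names``.
    ``gene_bodies`` (optional, with names) adds genes whose body overlaps
    a region even where no sub-feature does.

    Returns ``region_id, features, gene_ids`` with semicolon-joined,
    sorted feature and gene lists (``features`` holds ``intergenic``
    when nothing gene-derived overlaps).
    """
    regions_iset = IntervalSet.from_frame(
        regions.rename(columns={"region_id": "name"}), label="regions"
    )
    # from_frame sorts; recover the mapping sorted-position -> region_id
    pos_to_rid = regions_iset.names
    n = len(regions_iset)
    feat_sets: list[set[str]] = [set() for _ in range(n)]
    genes_of: list[set[str]] = [set() for _ in range(n)]
    exon_genes: list[set[str]] = [set() for _ in range(n)]
    intron_genes: list[set[str]] = [set() for _ in range(n)]
    stem_to_class = {v: k for k, v in FEATURE_FILE_KEYS.items()}
    for raw_key, iset in features.items():
        if raw_key == "genes":
            if gene_bodies is None:
                gene_bodies = iset
            continue
        key = stem_to_class.get(raw_key, raw_key)
        if key not in FEATURE_FILE_KEYS:
            raise ValueError(f"unknown feature class {raw_key!r}")
        for ridx, gene in _overlap_hits(regions_iset, iset):
            feat_sets[ridx].add(key)
            if key != "cpg_island" and gene not in (".", ""):
                genes_of[ridx].add(gene)
                if key == "exon":
                    exon_genes[ridx].add(gene)
                elif key == "intron":
                    intron_genes[ridx].add(gene)
    if gene_bodies is not None:
        for ridx, gene in _overlap_hits(regions_iset, gene_bodies):
            if gene not in (".", ""):
                genes_of[ridx].add(gene)
    rows = []
    for i in range(n):
        fs = feat_sets[i]
        if exon_genes[i] & intron_genes[i]:
            fs.add("intron_exon_boundary")
        if not (fs - {"cpg_island"}):
            fs.add("intergenic")
        rows.append(
            {
                "region_id": pos_to_rid[i],
                "features": ";".join(sorted(fs)),
                "gene_ids": ";".join(sorted(genes_of[i])),
            }
        )
    out = pd.DataFrame(rows)
    # restore the input's region order
    order = {rid: k for k, rid in enumerate(regions["region_id"])}
    return out.sort_values("region_id", key=lambda s: s.map(order)).reset_index(
        drop=True
    )


def feature_indicator(annotation: pd.DataFrame) -> pd.DataFrame:
    """Boolean region x feature-class matrix from an annotation table."""
    mat = pd.DataFrame(
        False, index=annotation["region_id"], columns=list(ALL_FEATURES)
    )
    for rid, feats in zip(annotation["region_id"], annotation["features"]):
        for f in str(feats).split(";"):
            if f:
                mat.at[rid, f] = True
    return mat


def permutation_enrichment(
    dmr_ids: list[str],
    background_ids: list[str],
    annotation: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | None = 0,
    chunk: int = 500,
) -> pd.DataFrame:
    """Feature enrichment of a DMR set vs size-matched random subsets.

    Each permutation draws ``len(dmr_ids)`` regions from the background
    without replacement and counts regions per feature class.  For each
    feature, ``p_emp = (1 + #{null >= obs}) / (n_perm + 1)`` when the
    observed count is at or above the null mean (direction ``enriched``),
    and symmetrically with <= when below (``depleted``).

    Returns one row per feature class: observed count and proportion,
    null mean, empirical p, direction, n_perm.
    """
    dmr_ids = list(dmr_ids)
    bg = list(background_ids)
    if not dmr_ids:
        raise ValueError("empty DMR set")
    if not set(dmr_ids) <= set(bg):
        raise ValueError("DMR ids must be a subset of the background")
    k, n = len(dmr_ids), len(bg)
    if k > n:
        raise ValueError("DMR set larger than background")
    ind = feature_indicator(annotation).loc[bg]
    M = ind.to_numpy()  # n x F
    obs = ind.loc[dmr_ids].to_numpy().sum(axis=0)
    rng = np.random.Generator(np.random.PCG64(seed))
    null_counts = np.empty((n_perm, M.shape[1]), dtype=np.int64)
    done = 0
    while done < n_perm:
        c = min(chunk, n_perm - done)
        keys = rng.random((c, n))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k] if k < n else (
            np.tile(np.arange(n), (c, 1))
        )
        null_counts[done : done + c] = M[idx].sum(axis=1)
        done += c
    null_mean = null_counts.mean(axis=0)
    rows = []
    for fi, feat in enumerate(ind.columns):
        if obs[fi] >= null_mean[fi]:
            direction = "enriched"
            tail = int((null_counts[:, fi] >= obs[fi]).sum())
        else:
            direction = "depleted"
            tail = int((null_counts[:, fi] <= obs[fi]).sum())
        rows.append(
            {
                "feature": feat,
                "observed_count": int(obs[fi]),
                "observed_prop": obs[fi] / k,
                "null_mean": float(null_mean[fi]),
                "p_emp": (1.0 + tail) / (n_perm + 1.0),
                "direction": direction,
                "n_perm": n_perm,
            }
        )
    return pd.DataFrame(rows)
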