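"""Synthetic cohort generator mirroring the study design.

The real experiment profiles DNA-methylation enrichment (meDIP-seq) in rat
prefrontal cortex across three prenatal treatment groups — control (CON),
pair-fed (PF) and prenatal-alcohol-exposed (PAE) — with 5 females and
5 males per group (30 animals, at most one pup per sex per litter).  This
module reproduces that design statistically so every downstream stage can
be exercised and validated without external data:

* a fully crossed group x sex design table with litter and batch labels;
* a miniature genome annotation (genes with exon/intron structure,
  TSS-200 and TSS-1500 promoters, UTRs, CpG islands) on a few autosomes
  plus one sex chromosome;
* non-overlapping enrichment regions with negative-binomially distributed
  fragment counts, multiplicative (log2-additive) batch effects,
  log-normal library-size factors, and planted differentially methylated
  regions (DMRs) in every tier x category x direction cell;
* per-sample peaksets (jittered, with dropout) and fragment intervals
  that reproduce the count matrix exactly;
* random gene sets plus one set enriched for genes hosting planted DMRs.

Regions on the sex chromosome receive sex-dependent baselines on purpose:
a pipeline that fails to drop them produces visible artifacts.

Everything is driven by one integer seed; identical configuration and
seed give identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalSet, write_bed

GROUPS = ("CON", "PF", "PAE")
SEXES = ("F", "M")
TIERS = ("concordant", "female", "male")
CATEGORIES = ("PAE_specific", "PF_specific", "shared")
DIRECTIONS = ("up", "down")

__all__ = [
    "SimulationConfig",
    "GenomeAnnotation",
    "SyntheticStudy",
    "generate_design",
    "generate_genome_annotation",
    "generate_regions_counts",
    "generate_peaksets_fragments",
    "generate_gene_sets",
    "simulate_study",
    "write_study",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generative model (defaults are the study conditions)."""

    seed: int = 0
    n_per_cell: int = 5          # animals per group x sex cell
    n_batches: int = 2
    n_regions: int = 5000
    nb_dispersion: float = 0.1   # NB variance = mu + phi * mu^2
    batch_effect: float = 0.5    # log2 shift of each batch after the first
    effect_size: float = 1.0     # |log2| shift of planted DMRs
    dmr_fraction: float = 0.10   # fraction of regions planted as DMRs
    dropout_prob: float = 0.05   # per-sample peak dropout
    libsize_log2_sd: float = 0.2
    baseline_rate: float = 0.25  # expected fragments per base at unit library factor
    baseline_log2_sd: float = 0.5
    background_fragment_rate: float = 1.0  # off-region fragments per expected on-region fragment
    sex_chrom_fraction: float = 0.04
    sex_chrom_female_boost: float = 1.0  # extra log2 baseline for females on chrX
    chroms: tuple[str, ...] = ("chr1", "chr2", "chr3", "chr4")
    sex_chrom: str = "chrX"
    chrom_length: int = 30_000_000
    n_genes: int = 400
    region_length_log_mean: float = math.log(465.0)
    region_length_log_sd: float = 0.45
    region_min_length: int = 200
    region_max_length: int = 2000
    gene_region_fraction: float = 0.45  # regions placed to overlap a gene
    fragment_length: int = 150
    n_gene_sets: int = 50

    def __post_init__(self) -> None:
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not (0.0 <= self.dropout_prob <= 1.0):
            raise ValueError("dropout_prob must be in [0, 1]")
        if not (0.0 <= self.dmr_fraction < 1.0):
            raise ValueError("dmr_fraction must be in [0, 1)")


@dataclass
class GenomeAnnotation:
    """Gene table plus per-class feature interval sets.

    ``features`` maps class name (genes, exons, introns, promoter200,
    promoter1500, utr5, utr3, cpg_islands) to an :class:`IntervalSet`;
    gene-derived sets carry the gene id in ``names``.
    """

    genes: pd.DataFrame  # gene_id, chrom, start, end, strand, tss
    features: dict[str, IntervalSet]

    def gene_ids(self) -> list[str]:
        return list(self.genes["gene_id"])


@dataclass
class SyntheticStudy:
    """Bundle of everything one seed generates."""

    config: SimulationConfig
    design: pd.DataFrame
    annotation: GenomeAnnotation
    regions: pd.DataFrame           # region_id, chrom, start, end, length
    counts: pd.DataFrame            # regions x samples
    library_sizes: pd.Series        # per sample: total fragments (incl. background)
    truth: pd.DataFrame             # region_id, tier, category, direction, effect
    gene_sets: pd.DataFrame         # set_id, gene_id
    planted_set_id: str


def _rng(seed_seq: np.random.SeedSequence) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(seed_seq))


def generate_design(
    n_per_cell: int = 5, n_batches: int = 2, seed: int = 0
) -> pd.DataFrame:
    """Fully crossed group x sex design with litter and batch labels.

    Litter ``<group>_L<i>`` contributes exactly one female and one male of
    its group, so no litter appears twice with the same sex.  Batches are
    assigned round-robin within each cell with a per-cell offset, keeping
    batch near-balanced over groups and sexes.
    """
    if n_per_cell < 1:
        raise ValueError("n_per_cell must be >= 1")
    if n_batches < 1:
        raise ValueError("n_batches must be >= 1")
    rng = _rng(np.random.SeedSequence(seed))
    rows = []
    for ci, (group, sex) in enumerate((g, s) for g in GROUPS for s in SEXES):
        offset = int(rng.integers(n_batches))
        for i in range(n_per_cell):
            rows.append(
                {
                    "sample_id": f"{group}_{sex}{i + 1}",
                    "group": group,
                    "sex": sex,
                    "batch": f"B{(i + offset) % n_batches + 1}",
                    "litter": f"{group}_L{i + 1}",
                }
            )
    return pd.DataFrame(rows)


def _partition_gene_body(
    rng: np.random.Generator, start: int, end: int
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Split [start, end) into alternating exon/intron segments.

    First and last segments are exons; together the segments partition the
    body exactly (no gaps, no overlap).
    """
    length = end - start
    n_exons = int(rng.integers(2, 9))
    n_seg = 2 * n_exons - 1
    min_seg = 50
    if length < n_seg * min_seg:
        n_exons = max(1, length // (2 * min_seg))
        n_seg = max(1, 2 * n_exons - 1)
    w = rng.dirichlet(np.ones(n_seg)) * (length - n_seg * min_seg)
    sizes = (w + min_seg).astype(np.int64)
    sizes[-1] += length - int(sizes.sum())
    bounds = start + np.concatenate([[0], np.cumsum(sizes)])
    exons, introns = [], []
    for k in range(n_seg):
        seg = (int(bounds[k]), int(bounds[k + 1]))
        (exons if k % 2 == 0 else introns).append(seg)
    return exons, introns


def generate_genome_annotation(
    config: SimulationConfig, seed_seq: np.random.SeedSequence | None = None
) -> GenomeAnnotation:
    """Lay out genes with exon/intron structure plus promoters, UTRs, CpG islands.

    Genes are placed left to right on the autosomes with random gaps; for
    each gene exons and introns partition the body, the TSS-200 and
    TSS-1500 promoters sit upstream of the TSS on the coding strand, and
    100-bp UTRs cap the first and last exon.  About half the promoters get
    a CpG island; additional islands are intergenic.
    """
    rng = _rng(seed_seq or np.random.SeedSequence(config.seed))
    n_chrom = len(config.chroms)
    genes_per_chrom = [
        config.n_genes // n_chrom + (1 if i < config.n_genes % n_chrom else 0)
        for i in range(n_chrom)
    ]
    gene_rows = []
    feat: dict[str, list[tuple[str, int, int, str, str]]] = {
        k: []
        for k in ("genes", "exons", "introns", "promoter200", "promoter1500",
                  "utr5", "utr3", "cpg_islands")
    }
    gi = 0
    for chrom, n_g in zip(config.chroms, genes_per_chrom):
        # leave room for upstream promoters and keep everything in bounds
        cursor = 5000
        budget = config.chrom_length - 5000
        for _ in range(n_g):
            gap = int(rng.integers(5_000, 50_000))
            glen = int(np.clip(rng.lognormal(math.log(20_000), 0.5), 3_000, 120_000))
            g0 = cursor + gap
            g1 = g0 + glen
            if g1 > budget:
                raise RuntimeError(
                    f"cannot place {n_g} genes on {chrom}: chromosome too short"
                )
            cursor = g1
            gene_id = f"G{gi + 1:04d}"
            gi += 1
            strand = "+" if rng.random() < 0.5 else "-"
            tss = g0 if strand == "+" else g1
            gene_rows.append(
                {"gene_id": gene_id, "chrom": chrom, "start": g0, "end": g1,
                 "strand": strand, "tss": tss}
            )
            feat["genes"].append((chrom, g0, g1, gene_id, strand))
            exons, introns = _partition_gene_body(rng, g0, g1)
            for s, e in exons:
                feat["exons"].append((chrom, s, e, gene_id, strand))
            for s, e in introns:
                feat["introns"].append((chrom, s, e, gene_id, strand))
            if strand == "+":
                feat["promoter200"].append((chrom, tss - 200, tss, gene_id, strand))
                feat["promoter1500"].append((chrom, tss - 1500, tss, gene_id, strand))
                u5 = exons[0]
                u3 = exons[-1]
                feat["utr5"].append((chrom, u5[0], min(u5[0] + 100, u5[1]), gene_id, strand))
                feat["utr3"].append((chrom, max(u3[1] - 100, u3[0]), u3[1], gene_id, strand))
            else:
                feat["promoter200"].append((chrom, tss, tss + 200, gene_id, strand))
                feat["promoter1500"].append((chrom, tss, tss + 1500, gene_id, strand))
                u5 = exons[-1]
                u3 = exons[0]
                feat["utr5"].append((chrom, max(u5[1] - 100, u5[0]), u5[1], gene_id, strand))
                feat["utr3"].append((chrom, u3[0], min(u3[0] + 100, u3[1]), gene_id, strand))
            if rng.random() < 0.5:
                ilen = int(rng.integers(300, 1500))
                c0 = max(0, tss - ilen // 2)
                feat["cpg_islands"].append((chrom, c0, c0 + ilen, ".", "."))
        # intergenic CpG islands beyond the gene-bearing prefix
        for _ in range(max(1, n_g // 10)):
            ilen = int(rng.integers(300, 1500))
            c0 = int(rng.integers(cursor + 10_000, config.chrom_length - ilen))
            feat["cpg_islands"].append((chrom, c0, c0 + ilen, ".", "."))
    features = {
        k: IntervalSet(
            [GenomicInterval(c, s, e, st) for c, s, e, _, st in v],
            label=k,
            names=[n for _, _, _, n, _ in v],
        )
        for k, v in feat.items()
    }
    return GenomeAnnotation(genes=pd.DataFrame(gene_rows), features=features)


def _place_regions(
    rng: np.random.Generator,
    config: SimulationConfig,
    annotation: GenomeAnnotation,
) -> pd.DataFrame:
    """Non-overlapping regions, a fraction targeted at genes, some on chrX."""
    n_x = int(round(config.sex_chrom_fraction * config.n_regions))
    n_auto = config.n_regions - n_x
    n_gene = int(round(config.gene_region_fraction * n_auto))
    lengths = np.clip(
        rng.lognormal(config.region_length_log_mean, config.region_length_log_sd,
                      size=config.n_regions),
        config.region_min_length, config.region_max_length,
    ).astype(np.int64)
    genes = annotation.genes
    rows: list[tuple[str, int, int]] = []
    k = 0
    for _ in range(n_gene):
        g = genes.iloc[int(rng.integers(len(genes)))]
        lo = max(0, int(g["start"]) - 1500)
        hi = max(lo + 1, int(g["end"]) - int(lengths[k]))
        s = int(rng.integers(lo, hi))
        rows.append((str(g["chrom"]), s, s + int(lengths[k])))
        k += 1
    for _ in range(n_auto - n_gene):
        chrom = config.chroms[int(rng.integers(len(config.chroms)))]
        s = int(rng.integers(0, config.chrom_length - int(lengths[k])))
        rows.append((chrom, s, s + int(lengths[k])))
        k += 1
    for _ in range(n_x):
        s = int(rng.integers(0, config.chrom_length - int(lengths[k])))
        rows.append((config.sex_chrom, s, s + int(lengths[k])))
        k += 1
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    # resolve rare collisions by shifting right; keeps the region count fixed.
    # the gap exceeds twice the peak-boundary jitter so per-sample peaks of
    # neighbouring regions can never merge
    min_gap = 80
    prev_end: dict[str, int] = {}
    starts = df["start"].to_numpy().copy()
    ends = df["end"].to_numpy().copy()
    for i in range(len(df)):
        c = df.at[i, "chrom"]
        if c in prev_end and starts[i] < prev_end[c] + min_gap:
            shift = prev_end[c] + min_gap - starts[i]
            starts[i] += shift
            ends[i] += shift
        prev_end[c] = int(ends[i])
    df["start"], df["end"] = starts, ends
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    df.insert(0, "region_id", [f"R{i + 1:05d}" for i in range(len(df))])
    df["length"] = df["end"] - df["start"]
    return df


def _plant_truth(
    rng: np.random.Generator, config: SimulationConfig, regions: pd.DataFrame
) -> pd.DataFrame:
    """Assign tier x category x direction labels to ~dmr_fraction of regions.

    Planting is restricted to autosomal regions (sex-chromosome regions are
    removed before testing, so signal there would be unmeasurable).
    Cells are filled as evenly as possible.
    """
    auto = regions.index[regions["chrom"] != config.sex_chrom].to_numpy()
    n_plant = int(round(config.dmr_fraction * len(regions)))
    n_plant = min(n_plant, len(auto))
    chosen = rng.choice(auto, size=n_plant, replace=False)
    cells = [(t, c, d) for t in TIERS for c in CATEGORIES for d in DIRECTIONS]
    truth = pd.DataFrame(
        {
            "region_id": regions["region_id"],
            "tier": "none",
            "category": "none",
            "direction": "none",
            "effect": 0.0,
        }
    )
    for j, idx in enumerate(np.sort(chosen)):
        t, c, d = cells[j % len(cells)]
        sign = 1.0 if d == "up" else -1.0
        truth.loc[idx, ["tier", "category", "direction"]] = (t, c, d)
        truth.loc[idx, "effect"] = sign * config.effect_size
    return truth


def _effect_matrix(
    truth: pd.DataFrame, design: pd.DataFrame
) -> np.ndarray:
    """Planted log2 shift per (region, sample)."""
    n_r, n_s = len(truth), len(design)
    eff = np.zeros((n_r, n_s))
    grp = design["group"].to_numpy()
    sex = design["sex"].to_numpy()
    for i, row in enumerate(truth.itertuples(index=False)):
        if row.category == "none":
            continue
        if row.tier == "concordant":
            sex_mask = np.ones(n_s, dtype=bool)
        elif row.tier == "female":
            sex_mask = sex == "F"
        else:
            sex_mask = sex == "M"
        if row.category == "PAE_specific":
            grp_mask = grp == "PAE"
        elif row.category == "PF_specific":
            grp_mask = grp == "PF"
        else:
            grp_mask = (grp == "PAE") | (grp == "PF")
        eff[i, sex_mask & grp_mask] = row.effect
    return eff


def generate_regions_counts(
    design: pd.DataFrame,
    config: SimulationConfig,
    annotation: GenomeAnnotation | None = None,
    seed_seq: np.random.SeedSequence | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.Series]:
    """Regions, NB fragment counts, planted-DMR truth and library sizes.

    Counts for region r, sample s are negative binomial with mean
    ``mu_rs = baseline_r * libfactor_s * 2^(batch_s + planted + sexchrom)``
    and dispersion ``nb_dispersion`` (variance ``mu + phi mu^2``);
    ``baseline_r`` scales with region length.  Library size = on-region
    fragments plus a Poisson background component, as for real sequencing
    where most fragments fall outside peaks.
    """
    ss = seed_seq or np.random.SeedSequence(config.seed)
    s_ann, s_cnt = ss.spawn(2)
    if annotation is None:
        annotation = generate_genome_annotation(config, s_ann)
    rng = _rng(s_cnt)
    regions = _place_regions(rng, config, annotation)
    truth = _plant_truth(rng, config, regions)

    n_r, n_s = len(regions), len(design)
    baseline = (
        config.baseline_rate
        * regions["length"].to_numpy()
        * 2.0 ** rng.normal(0.0, config.baseline_log2_sd, size=n_r)
    )
    libfac = 2.0 ** rng.normal(0.0, config.libsize_log2_sd, size=n_s)
    batch_index = pd.Categorical(design["batch"]).codes
    batch_shift = config.batch_effect * batch_index.astype(float)
    log2_shift = np.tile(batch_shift, (n_r, 1)) + _effect_matrix(truth, design)
    on_x = (regions["chrom"] == config.sex_chrom).to_numpy()
    is_f = (design["sex"] == "F").to_numpy()
    log2_shift += np.outer(on_x, is_f) * config.sex_chrom_female_boost

    mu = baseline[:, None] * libfac[None, :] * 2.0 ** log2_shift
    phi = config.nb_dispersion
    n_param = 1.0 / phi
    p_param = n_param / (n_param + mu)
    counts = rng.negative_binomial(n_param, p_param)
    counts_df = pd.DataFrame(
        counts, index=regions["region_id"], columns=design["sample_id"]
    )
    # library size tracks sequencing depth (library factor), not the batch
    # shift: enrichment-efficiency batches change in-peak counts while the
    # total number of sequenced fragments stays set by the sequencer, so
    # RPKM removes depth but leaves batch effects for the EB adjustment
    on_region = counts_df.sum(axis=0).to_numpy()
    target = np.round(
        baseline.sum() * libfac * (1.0 + config.background_fragment_rate)
    ).astype(np.int64)
    background = np.maximum(target - on_region, 0)
    library_sizes = pd.Series(
        on_region + background, index=design["sample_id"], name="library_size"
    )
    return regions, counts_df, truth, library_sizes


def generate_peaksets_fragments(
    regions: pd.DataFrame,
    design: pd.DataFrame,
    config: SimulationConfig,
    counts: pd.DataFrame,
    library_sizes: pd.Series | None = None,
    seed_seq: np.random.SeedSequence | None = None,
) -> tuple[dict[str, IntervalSet], dict[str, IntervalSet]]:
    """Per-sample peak and fragment BED-equivalents.

    Each sample's peakset is the true region set with +/-jittered
    boundaries, each region dropped independently with ``dropout_prob``.
    Fragment starts are placed uniformly inside their region, so counting
    fragments whose start falls in a region reproduces ``counts`` exactly;
    background fragments (library size minus on-region fragments) start
    strictly outside every region.
    """
    rng = _rng(seed_seq or np.random.SeedSequence(config.seed + 1))
    jitter = 30
    peaksets: dict[str, IntervalSet] = {}
    fragments: dict[str, IntervalSet] = {}
    r_chrom = regions["chrom"].to_numpy()
    r_start = regions["start"].to_numpy()
    r_end = regions["end"].to_numpy()
    all_chroms = list(config.chroms) + [config.sex_chrom]
    # per-chromosome sorted region bounds, to keep background starts outside
    bounds = {
        c: (r_start[r_chrom == c], r_end[r_chrom == c]) for c in all_chroms
    }
    flen = config.fragment_length
    for s in design["sample_id"]:
        col = counts[s].to_numpy()
        keep = rng.random(len(regions)) >= config.dropout_prob
        peaks = []
        for i in np.nonzero(keep)[0]:
            a = max(0, int(r_start[i] + rng.integers(-jitter, jitter + 1)))
            b = int(r_end[i] + rng.integers(-jitter, jitter + 1))
            if b <= a:
                b = a + 1
            peaks.append(GenomicInterval(str(r_chrom[i]), a, b))
        peaksets[s] = IntervalSet(peaks, label=s)
        frags: list[GenomicInterval] = []
        for i in np.nonzero(col > 0)[0]:
            starts = rng.integers(r_start[i], r_end[i], size=int(col[i]))
            frags.extend(
                GenomicInterval(str(r_chrom[i]), int(st), int(st) + flen)
                for st in starts
            )
        if library_sizes is not None:
            n_bg = int(library_sizes[s]) - int(col.sum())
            placed = 0
            while placed < n_bg:
                c = all_chroms[int(rng.integers(len(all_chroms)))]
                st = int(rng.integers(0, config.chrom_length - flen))
                bs, be = bounds[c]
                j = np.searchsorted(bs, st, side="right") - 1
                if j >= 0 and st < be[j]:
                    continue  # would start inside a region
                frags.append(GenomicInterval(c, st, st + flen))
                placed += 1
        fragments[s] = IntervalSet(frags, label=s)
    return peaksets, fragments


def generate_gene_sets(
    gene_ids: list[str],
    config: SimulationConfig,
    planted_genes: set[str] | None = None,
    seed_seq: np.random.SeedSequence | None = None,
    min_size: int = 2,
    max_size: int = 2000,
) -> tuple[pd.DataFrame, str]:
    """Random gene sets within [min_size, max_size], plus one planted set.

    The planted set draws >=80% of its members from ``planted_genes``
    (genes hosting planted DMRs), giving the gene-score-resampling stage a
    positive control.  Returns the long-format table and the planted set id.
    """
    if len(gene_ids) < 10:
        raise ValueError("need >= 10 genes to build gene sets")
    rng = _rng(seed_seq or np.random.SeedSequence(config.seed + 2))
    genes = np.asarray(gene_ids)
    hi = min(max_size, len(genes))
    rows: list[tuple[str, str]] = []
    for k in range(config.n_gene_sets):
        size = int(np.clip(round(rng.lognormal(math.log(15), 0.8)), min_size, hi))
        members = rng.choice(genes, size=size, replace=False)
        sid = f"SET{k + 1:03d}"
        rows.extend((sid, g) for g in members)
    planted_id = "SET_PLANTED"
    planted = sorted(planted_genes or ())
    if planted:
        n_core = min(len(planted), 40)
        core = list(rng.choice(np.asarray(planted), size=n_core, replace=False))
        n_noise = max(0, min(int(n_core * 0.25), hi - n_core))
        others = np.asarray([g for g in genes if g not in set(core)])
        noise = list(rng.choice(others, size=n_noise, replace=False)) if n_noise else []
        members = core + noise
        if len(members) >= min_size:
            rows.extend((planted_id, g) for g in members)
    return pd.DataFrame(rows, columns=["set_id", "gene_id"]), planted_id


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate the full synthetic study from one seed."""
    ss = np.random.SeedSequence(config.seed)
    s_design, s_ann, s_cnt, s_sets = ss.spawn(4)
    design = generate_design(config.n_per_cell, config.n_batches,
                             seed=int(s_design.generate_state(1)[0] % (2**31)))
    annotation = generate_genome_annotation(config, s_ann)
    regions, counts, truth, library_sizes = generate_regions_counts(
        design, config, annotation=annotation, seed_seq=s_cnt
    )
    planted_regions = truth.loc[truth["category"] != "none", "region_id"]
    planted_genes = _genes_hosting(regions, planted_regions, annotation)
    gene_sets, planted_set_id = generate_gene_sets(
        annotation.gene_ids(), config, planted_genes, seed_seq=s_sets
    )
    return SyntheticStudy(
        config=config,
        design=design,
        annotation=annotation,
        regions=regions,
        counts=counts,
        library_sizes=library_sizes,
        truth=truth,
        gene_sets=gene_sets,
        planted_set_id=planted_set_id,
    )


def _genes_hosting(
    regions: pd.DataFrame, region_ids: pd.Series, annotation: GenomeAnnotation
) -> set[str]:
    """Gene ids whose body overlaps any of the given regions."""
    sel = regions.set_index("region_id").loc[region_ids]
    genes = annotation.genes
    out: set[str] = set()
    for chrom, sub in sel.groupby("chrom"):
        g = genes[genes["chrom"] == chrom]
        if g.empty:
            continue
        gs = g["start"].to_numpy()
        ge = g["end"].to_numpy()
        gid = g["gene_id"].to_numpy()
        for s, e in zip(sub["start"], sub["end"]):
            hit = (gs < e) & (ge > s)
            out.update(gid[hit])
    return out


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Write all study components as plain TSV/BED under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["design"] = out / "design.tsv"
    study.design.to_csv(paths["design"], sep="\t", index=False)
    paths["regions"] = out / "regions.bed"
    study.regions[["chrom", "start", "end", "region_id"]].to_csv(
        paths["regions"], sep="\t", index=False, header=False
    )
    paths["counts"] = out / "counts.tsv"
    study.counts.to_csv(paths["counts"], sep="\t", index_label="region_id")
    paths["library_sizes"] = out / "library_sizes.tsv"
    study.library_sizes.to_frame().to_csv(paths["library_sizes"], sep="\t",
                                          index_label="sample_id")
    paths["truth"] = out / "truth.tsv"
    study.truth.to_csv(paths["truth"], sep="\t", index=False)
    paths["gene_sets"] = out / "gene_sets.tsv"
    study.gene_sets.to_csv(paths["gene_sets"], sep="\t", index=False)
    featdir = out / "features"
    featdir.mkdir(exist_ok=True)
    for name, iset in study.annotation.features.items():
        p = featdir / f"{name}.bed"
        write_bed(iset, p)
        paths[f"feature_{name}"] = p
    paths["genes_table"] = out / "genes.tsv"
    study.annotation.genes.to_csv(paths["genes_table"], sep="\t", index=False)
    return paths
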