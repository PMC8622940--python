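"""Configuration, seeding and end-to-end orchestration.

One YAML (or dict) config drives every stage with the study defaults:
minimum peak support 3, FDR 0.05, log pseudocount 0.5, 10,000 enrichment
permutations, gene-set-resampling bounds [2, 2000] with 10,000
iterations, and 2,000 Monte-Carlo replicates for the direction test.
A single master seed spawns an independent, fixed-position child seed
per stage, so disabling one stage never shifts another stage's
randomness.  Re-running an identical config reproduces byte-identical
outputs; the run manifest records a hash per output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate, classify, consensus, differential, gsr, normalize, simulate
from .intervals import read_bed

logger = logging.getLogger(__name__)

# fixed stage order; the spawn key of each stage's seed is its position here
STAGES = (
    "simulate",
    "consensus",
    "counts",
    "normalize",
    "differential",
    "classify",
    "enrich",
    "gsr",
    "overlap",
)

__all__ = ["PipelineConfig", "ConfigError", "validate_config", "run_all", "stage_seed"]


class ConfigError(ValueError):
    """Aggregated configuration problems, one message line per violation."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n" + "\n".join(problems))


@dataclass
class PipelineConfig:
    """All paths, parameters and flags of one pipeline run."""

    output_dir: str = "results/pipeline"
    synthetic: bool = True
    # real-data inputs (ignored in synthetic mode)
    design_path: str | None = None
    counts_path: str | None = None
    library_sizes_path: str | None = None
    regions_path: str | None = None
    feature_dir: str | None = None
    gene_sets_path: str | None = None
    external_lists: dict[str, list[str]] = field(default_factory=dict)
    # parameters (study defaults)
    min_samples: int = 3
    sex_chroms: tuple[str, ...] = ("chrX", "chrY")
    alpha: float = 0.05
    pseudocount: float = 0.5
    moderation: bool = True
    n_perm: int = 10_000
    gsr_iterations: int = 10_000
    gsr_min_size: int = 2
    gsr_max_size: int = 2000
    gsr_multifunctionality_top_frac: float = 0.01
    direction_B: int = 2000
    seed: int = 0
    # synthetic generator knobs (forwarded to SimulationConfig)
    synthetic_params: dict = field(default_factory=dict)
    skip_stages: tuple[str, ...] = ()

    def simulation_config(self) -> simulate.SimulationConfig:
        return simulate.SimulationConfig(
            seed=stage_seed(self.seed, "simulate"), **self.synthetic_params
        )


_RANGES: dict[str, tuple] = {
    "min_samples": (1, None),
    "alpha": (0.0, 1.0),
    "pseudocount": (1e-12, None),
    "n_perm": (1, None),
    "gsr_iterations": (1, None),
    "gsr_min_size": (2, None),
    "gsr_max_size": (2, None),
    "gsr_multifunctionality_top_frac": (0.0, 1.0),
    "direction_B": (1, None),
}


def validate_config(raw: str | dict) -> PipelineConfig:
    """Parse + validate a config mapping (or YAML text).

    Unknown keys are rejected, defaults injected, types and ranges
    checked; all violations are reported together in a :class:`ConfigError`.
    """
    if isinstance(raw, str):
        data = yaml.safe_load(raw) or {}
    else:
        data = dict(raw)
    if not isinstance(data, dict):
        raise ConfigError(["config root must be a mapping"])
    problems: list[str] = []
    known = {f.name for f in fields(PipelineConfig)}
    for key in sorted(set(data) - known):
        problems.append(f"unknown key: {key}")
    data = {k: v for k, v in data.items() if k in known}
    for key in ("sex_chroms", "skip_stages"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    cfg = PipelineConfig(**{k: v for k, v in data.items()})
    for key, (lo, hi) in _RANGES.items():
        val = getattr(cfg, key)
        if not isinstance(val, (int, float)) or isinstance(val, bool):
            problems.append(f"{key}: expected a number, got {val!r}")
            continue
        if lo is not None and val < lo:
            problems.append(f"{key}: {val} below minimum {lo}")
        if hi is not None and val > hi:
            problems.append(f"{key}: {val} above maximum {hi}")
    if cfg.gsr_max_size < cfg.gsr_min_size:
        problems.append("gsr_max_size must be >= gsr_min_size")
    for st in cfg.skip_stages:
        if st not in STAGES:
            problems.append(f"skip_stages: unknown stage {st!r}")
    if not cfg.synthetic:
        if not cfg.design_path:
            problems.append("design_path required when synthetic=false")
        if not cfg.counts_path:
            problems.append("counts_path required when synthetic=false")
        for key in ("design_path", "counts_path", "library_sizes_path",
                    "regions_path", "gene_sets_path"):
            p = getattr(cfg, key)
            if p and not Path(p).exists():
                problems.append(f"{key}: file not found: {p}")
        if cfg.feature_dir and not Path(cfg.feature_dir).is_dir():
            problems.append(f"feature_dir: not a directory: {cfg.feature_dir}")
    if problems:
        raise ConfigError(sorted(problems))
    return cfg


def stage_seed(master_seed: int, stage: str) -> int:
    """Per-stage seed via a counter-based spawn of the master seed."""
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence(master_seed, spawn_key=(idx,))
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_features(feature_dir: Path) -> dict:
    feats = {}
    for stem in list(annotate.FEATURE_FILE_KEYS.values()) + ["genes"]:
        p = feature_dir / f"{stem}.bed"
        if p.exists():
            feats[stem] = read_bed(p, label=stem)
    return feats


def run_all(config: PipelineConfig) -> dict:
    """Run every stage in dependency order; returns the run manifest.

    Synthetic mode generates the cohort first; otherwise the design,
    count matrix and annotations are read from the configured paths.
    Outputs are plain TSVs under ``output_dir``; the manifest (written
    last as ``manifest.json``) maps each output file to a content hash.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": _config_snapshot(config), "stages": {}, "files": {}}

    def record(stage: str, paths: list[Path]) -> None:
        manifest["stages"][stage] = {
            "seed": stage_seed(config.seed, stage),
            "outputs": [str(p) for p in paths],
        }
        for p in paths:
            manifest["files"][str(p)] = _sha256(p)

    # ---- inputs -----------------------------------------------------------
    annotation_features = None
    gene_bodies = None
    gene_sets = None
    truth = None
    if config.synthetic:
        study = simulate.simulate_study(config.simulation_config())
        design = study.design
        regions = study.regions
        counts = study.counts
        library_sizes = study.library_sizes
        annotation_features = study.annotation.features
        gene_sets = study.gene_sets
        truth = study.truth
        paths = simulate.write_study(study, out / "synthetic")
        record("simulate", sorted(paths.values()))
    else:
        design = pd.read_csv(config.design_path, sep="\t")
        counts = pd.read_csv(config.counts_path, sep="\t", index_col=0)
        if config.library_sizes_path:
            library_sizes = pd.read_csv(
                config.library_sizes_path, sep="\t", index_col=0
            ).iloc[:, 0]
        else:
            library_sizes = counts.sum(axis=0)
        if config.regions_path:
            regions = pd.read_csv(
                config.regions_path, sep="\t", header=None,
                names=["chrom", "start", "end", "region_id"],
            )
            regions["length"] = regions["end"] - regions["start"]
        else:
            regions = None
        if config.feature_dir:
            annotation_features = _load_features(Path(config.feature_dir))
        if config.gene_sets_path:
            gene_sets = pd.read_csv(config.gene_sets_path, sep="\t")

    # ---- sex-chromosome removal ------------------------------------------
    if regions is not None:
        regions = consensus.remove_sex_chromosomes(regions, config.sex_chroms)
        counts = counts.loc[counts.index.intersection(regions["region_id"])]
        counts = counts.reindex(regions["region_id"])

    # ---- normalize --------------------------------------------------------
    lengths = (
        regions.set_index("region_id")["length"]
        if regions is not None
        else pd.Series(1000, index=counts.index)
    )
    mat = normalize.rpkm(counts, lengths, library_sizes)
    mat = normalize.log_transform(mat, config.pseudocount)
    batch = pd.Series(design["batch"].to_numpy(), index=design["sample_id"])
    protected = normalize.build_protected_design(design)
    if batch.nunique() > 1:
        mat, batch_model = normalize.combat_adjust(mat, batch, protected)
        batch_model.to_frame().to_csv(out / "batch_model.tsv", sep="\t", index=False)
    mat.to_csv(out / "normalized.tsv", sep="\t", index_label="region_id")
    record("normalize", [out / "normalized.tsv"])

    # ---- differential + classification ------------------------------------
    tables = {}
    calls = {}
    for tier in differential.TIERS:
        tab = differential.run_tier(mat, design, tier, moderate=config.moderation)
        tab.to_csv(out / f"contrasts_{tier}.tsv", sep="\t", index=False)
        tables[tier] = tab
        calls[tier] = classify.classify_table(tab, regions, alpha=config.alpha)
    conc, fem, mal = classify.reassign_sex_tiers(
        calls["concordant"], calls["female"], calls["male"]
    )
    final_calls = pd.concat([conc, fem, mal], ignore_index=True)
    final_calls.to_csv(out / "dmr_calls.tsv", sep="\t", index=False)
    record("differential",
           [out / f"contrasts_{t}.tsv" for t in differential.TIERS])

    dir_rows = []
    dseed = stage_seed(config.seed, "classify")
    for (tier, cat), sub in final_calls.groupby(["tier", "category"], observed=True):
        n_up = int((sub["direction"] == "up").sum())
        n_down = int((sub["direction"] == "down").sum())
        if n_up + n_down == 0:
            continue
        r = classify.direction_chisq_mc(n_up, n_down, B=config.direction_B, seed=dseed)
        dir_rows.append(
            {"tier": tier, "category": cat, "n_up": r.n_up, "n_down": r.n_down,
             "chi2": r.chi2, "p_sim": r.p_sim, "B": r.B}
        )
    pd.DataFrame(dir_rows).to_csv(out / "direction_tests.tsv", sep="\t", index=False)
    record("classify", [out / "dmr_calls.tsv", out / "direction_tests.tsv"])

    # ---- annotation + enrichment ------------------------------------------
    annotation = None
    if annotation_features is not None and regions is not None:
        annotation = annotate.annotate_regions(regions, annotation_features,
                                               gene_bodies)
        annotation.to_csv(out / "region_annotation.tsv", sep="\t", index=False)
        eseed = stage_seed(config.seed, "enrich")
        enr_frames = []
        bg = list(regions["region_id"])
        for (tier, cat), sub in final_calls.groupby(["tier", "category"],
                                                    observed=True):
            if sub.empty:
                continue
            res = annotate.permutation_enrichment(
                list(sub["region_id"]), bg, annotation,
                n_perm=config.n_perm, seed=eseed,
            )
            res.insert(0, "tier", tier)
            res.insert(1, "category", cat)
            enr_frames.append(res)
        enrich = (
            pd.concat(enr_frames, ignore_index=True)
            if enr_frames
            else pd.DataFrame()
        )
        enrich.to_csv(out / "feature_enrichment.tsv", sep="\t", index=False)
        record("enrich", [out / "region_annotation.tsv",
                          out / "feature_enrichment.tsv"])

    # ---- gene-score resampling --------------------------------------------
    gsr_results: dict[str, pd.DataFrame] = {}
    if annotation is not None and gene_sets is not None:
        gseed = stage_seed(config.seed, "gsr")
        for contrast in differential.CONTRASTS:
            scores = gsr.gene_scores(tables["concordant"], annotation, contrast)
            if len(scores) < config.gsr_min_size:
                continue
            res = gsr.gsr_test(
                scores, gene_sets, iterations=config.gsr_iterations,
                min_size=config.gsr_min_size, max_size=config.gsr_max_size,
                seed=gseed,
            )
            k_top = int(round(config.gsr_multifunctionality_top_frac * len(scores)))
            res = gsr.multifunctionality_check(
                gene_sets, res, scores, k_top, alpha=config.alpha,
                iterations=config.gsr_iterations, min_size=config.gsr_min_size,
                max_size=config.gsr_max_size, seed=gseed,
            )
            res.insert(0, "contrast", contrast)
            gsr_results[contrast] = res
        if gsr_results:
            pd.concat(gsr_results.values(), ignore_index=True).to_csv(
                out / "gsr_results.tsv", sep="\t", index=False
            )
            pathways = gsr.final_pathway_sets(gsr_results, alpha=config.alpha)
            with open(out / "pathways.json", "w") as fh:
                json.dump(pathways, fh, indent=1, sort_keys=True)
            record("gsr", [out / "gsr_results.tsv", out / "pathways.json"])

    # ---- external gene-list overlap ---------------------------------------
    if config.external_lists and annotation is not None:
        gene_of_region = dict(zip(annotation["region_id"], annotation["gene_ids"]))
        dmr_genes: dict[tuple[str, str], set[str]] = {}
        for row in final_calls.itertuples(index=False):
            gs = gene_of_region.get(row.region_id, "")
            genes = {g for g in str(gs).split(";") if g}
            dmr_genes.setdefault((row.tier, row.category), set()).update(genes)
        overlap = gsr.gene_list_overlap(dmr_genes, config.external_lists)
        overlap.to_csv(out / "gene_list_overlap.tsv", sep="\t", index=False)
        record("overlap", [out / "gene_list_overlap.tsv"])

    if truth is not None:
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _config_snapshot(config: PipelineConfig) -> dict:
    snap = asdict(config)
    snap["sex_chroms"] = list(config.sex_chroms)
    snap["skip_stages"] = list(config.skip_stages)
    return snap
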