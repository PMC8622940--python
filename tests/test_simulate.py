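"""Synthetic cohort generator: design, genome, counts, peaks, gene sets."""

import numpy as np
import pandas as pd
import pytest

from medipdmr.consensus import count_fragments
from medipdmr.simulate import (
    SimulationConfig,
    generate_design,
    generate_gene_sets,
    generate_genome_annotation,
    generate_peaksets_fragments,
    generate_regions_counts,
    simulate_study,
)


class TestDesign:
    def test_default_design_is_thirty_animals_five_per_cell(self):
        d = generate_design(5)
        assert len(d) == 30
        assert (d.groupby(["group", "sex"]).size() == 5).all()

    def test_minimal_design_has_one_per_cell(self):
        assert len(generate_design(1)) == 6

    def test_no_litter_contributes_two_animals_of_one_sex(self):
        d = generate_design(5)
        assert (d.groupby(["litter", "sex"]).size() <= 1).all()

    def test_batches_balanced_within_one(self):
        d = generate_design(5, n_batches=2)
        counts = d["batch"].value_counts()
        assert counts.max() - counts.min() <= 2

    def test_rejects_empty_cells(self):
        with pytest.raises(ValueError):
            generate_design(0)


@pytest.fixture(scope="module")
def annotation():
    return generate_genome_annotation(SimulationConfig(seed=3, n_genes=60))


class TestGenomeAnnotation:

    def test_exons_and_introns_partition_each_gene_body(self, annotation):
        exons = annotation.features["exons"]
        introns = annotation.features["introns"]
        by_gene = {}
        for iv, g in zip(exons, exons.names):
            by_gene.setdefault(g, []).append((iv.start, iv.end))
        for iv, g in zip(introns, introns.names):
            by_gene.setdefault(g, []).append((iv.start, iv.end))
        for row in annotation.genes.itertuples():
            segs = sorted(by_gene[row.gene_id])
            assert segs[0][0] == row.start and segs[-1][1] == row.end
            for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
                assert e1 == s2  # contiguous, no overlap, no gap

    def test_promoters_follow_tss_arithmetic_on_coding_strand(self, annotation):
        p200 = {g: iv for iv, g in zip(annotation.features["promoter200"],
                                       annotation.features["promoter200"].names)}
        for row in annotation.genes.itertuples():
            iv = p200[row.gene_id]
            if row.strand == "+":
                assert (iv.start, iv.end) == (row.tss - 200, row.tss)
            else:
                assert (iv.start, iv.end) == (row.tss, row.tss + 200)

    def test_features_stay_within_chromosome_bounds(self, annotation):
        cfg = SimulationConfig()
        for iset in annotation.features.values():
            for iv in iset:
                assert 0 <= iv.start < iv.end <= cfg.chrom_length


class TestRegionsCounts:
    def test_zero_effect_size_plants_nothing(self):
        cfg = SimulationConfig(seed=2, n_regions=200, effect_size=0.0,
                               dmr_fraction=0.0, n_genes=50)
        design = generate_design(2)
        _, _, truth, _ = generate_regions_counts(design, cfg)
        assert (truth["category"] == "none").all()

    def test_same_seed_reproduces_counts_exactly(self):
        cfg = SimulationConfig(seed=9, n_regions=150, n_genes=50)
        design = generate_design(3)
        _, c1, _, l1 = generate_regions_counts(design, cfg)
        _, c2, _, l2 = generate_regions_counts(design, cfg)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_series_equal(l1, l2)

    def test_planted_shift_recovered_at_large_n(self):
        # a -1 log2 PAE-specific effect should appear as a group-mean ratio
        # close to -1 once the per-cell sample size is large
        cfg = SimulationConfig(seed=4, n_regions=120, n_genes=30,
                               effect_size=1.0, dmr_fraction=0.3,
                               batch_effect=0.0, libsize_log2_sd=0.0)
        design = generate_design(50)
        regions, counts, truth, _ = generate_regions_counts(design, cfg)
        sel = truth[(truth["category"] == "PAE_specific")
                    & (truth["tier"] == "concordant")
                    & (truth["direction"] == "down")]
        assert len(sel) >= 2
        pae = design.loc[design["group"] == "PAE", "sample_id"]
        con = design.loc[design["group"] == "CON", "sample_id"]
        for rid in sel["region_id"]:
            ratio = np.log2(counts.loc[rid, pae].mean()) - np.log2(
                counts.loc[rid, con].mean()
            )
            assert ratio == pytest.approx(-1.0, abs=0.2)

    def test_sex_chromosome_regions_exist_and_are_never_planted(self):
        cfg = SimulationConfig(seed=2, n_regions=300, n_genes=50)
        design = generate_design(2)
        regions, _, truth, _ = generate_regions_counts(design, cfg)
        on_x = regions["chrom"] == cfg.sex_chrom
        assert on_x.any()
        assert (truth.loc[on_x.to_numpy(), "category"] == "none").all()


@pytest.fixture(scope="module")
def tiny():
    cfg = SimulationConfig(seed=6, n_regions=40, n_genes=20,
                           baseline_rate=0.05, dropout_prob=0.0)
    design = generate_design(1)
    regions, counts, truth, libs = generate_regions_counts(design, cfg)
    return cfg, design, regions, counts, libs


class TestPeaksetsFragments:

    def test_no_dropout_covers_every_region(self, tiny):
        cfg, design, regions, counts, libs = tiny
        peaks, _ = generate_peaksets_fragments(regions, design, cfg, counts, libs)
        for s, ps in peaks.items():
            assert len(ps) == len(regions)

    def test_total_dropout_empties_all_peaksets(self, tiny):
        cfg, design, regions, counts, libs = tiny
        cfg1 = SimulationConfig(**{**cfg.__dict__, "dropout_prob": 1.0})
        peaks, _ = generate_peaksets_fragments(regions, design, cfg1, counts, libs)
        assert all(len(ps) == 0 for ps in peaks.values())

    def test_fragment_counting_reproduces_count_matrix_and_library_sizes(self, tiny):
        cfg, design, regions, counts, libs = tiny
        _, frags = generate_peaksets_fragments(regions, design, cfg, counts, libs)
        got, got_libs = count_fragments(frags, regions)
        pd.testing.assert_frame_equal(
            got[counts.columns], counts, check_names=False
        )
        assert (got_libs[libs.index] == libs).all()


class TestGeneSets:
    def test_sizes_respect_bounds_and_seed_determinism(self):
        cfg = SimulationConfig(seed=8, n_gene_sets=10)
        genes = [f"G{i:03d}" for i in range(10)]
        s1, _ = generate_gene_sets(genes, cfg)
        s2, _ = generate_gene_sets(genes, cfg)
        pd.testing.assert_frame_equal(s1, s2)
        sizes = s1.groupby("set_id").size()
        assert sizes.between(2, 10).all()

    def test_planted_set_is_mostly_dmr_hosting_genes(self):
        cfg = SimulationConfig(seed=8, n_gene_sets=5)
        genes = [f"G{i:03d}" for i in range(200)]
        planted = set(genes[:30])
        sets, pid = generate_gene_sets(genes, cfg, planted_genes=planted)
        members = set(sets.loc[sets["set_id"] == pid, "gene_id"])
        assert len(members & planted) / len(members) >= 0.8


class TestEndToEndDeterminism:
    def test_one_seed_fixes_everything(self):
        cfg = SimulationConfig(seed=12, n_regions=120, n_genes=40)
        a, b = simulate_study(cfg), simulate_study(cfg)
        pd.testing.assert_frame_equal(a.design, b.design)
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        pd.testing.assert_frame_equal(a.gene_sets, b.gene_sets)
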