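"""Gene-score resampling, multifunctionality check, pathway intersections."""

import numpy as np
import pandas as pd
import pytest

from _oracles import exhaustive_mean_tail
from medipdmr.gsr import (
    final_pathway_sets,
    gene_list_overlap,
    gene_scores,
    gsr_test,
    multifunctionality_check,
)


def scores_frame(pairs):
    return pd.DataFrame(
        {"gene_id": [g for g, _ in pairs], "score": [s for _, s in pairs],
         "n_regions": 1}
    )


def sets_frame(mapping):
    rows = [(sid, g) for sid, genes in mapping.items() for g in genes]
    return pd.DataFrame(rows, columns=["set_id", "gene_id"])


class TestGeneScores:
    def contrast_table(self, pvals):
        return pd.DataFrame(
            {
                "region_id": list(pvals),
                "contrast": "PAEvCON",
                "logFC": 0.0,
                "p": list(pvals.values()),
                "q": list(pvals.values()),
            }
        )

    def annotation(self, gene_map):
        return pd.DataFrame(
            {
                "region_id": list(gene_map),
                "features": "exon",
                "gene_ids": list(gene_map.values()),
            }
        )

    def test_single_region_score_is_minus_log10_p(self):
        tab = self.contrast_table({"R1": 0.01})
        out = gene_scores(tab, self.annotation({"R1": "G1"}), "PAEvCON")
        assert out.loc[0, "score"] == pytest.approx(2.0)

    def test_best_p_wins_across_regions(self):
        tab = self.contrast_table({"R1": 0.1, "R2": 0.01})
        out = gene_scores(tab, self.annotation({"R1": "G1", "R2": "G1"}), "PAEvCON")
        assert out.loc[0, "score"] == pytest.approx(2.0)
        assert out.loc[0, "n_regions"] == 2

    def test_null_p_scores_zero_and_unannotated_regions_ignored(self):
        tab = self.contrast_table({"R1": 1.0, "R2": 0.5})
        out = gene_scores(tab, self.annotation({"R1": "G1", "R2": ""}), "PAEvCON")
        assert list(out["gene_id"]) == ["G1"]
        assert out.loc[0, "score"] == pytest.approx(0.0)


class TestGsrTest:
    def test_full_universe_set_has_p_one(self):
        genes = [(f"G{i}", float(i)) for i in range(10)]
        res = gsr_test(scores_frame(genes), sets_frame({"S": [g for g, _ in genes]}),
                       iterations=200, seed=0)
        assert res.loc[0, "p_emp"] == 1.0

    def test_top_pair_matches_exhaustive_enumeration(self):
        vals = [(f"G{i}", float(i)) for i in range(10)]
        top2 = ["G9", "G8"]
        iters = 4000
        res = gsr_test(scores_frame(vals), sets_frame({"S": top2}),
                       iterations=iters, seed=3)
        exact = exhaustive_mean_tail(np.arange(10.0), 2, 8.5)
        assert exact == pytest.approx(1 / 45)
        expected = (1 + iters * exact) / (iters + 1)
        se = np.sqrt(exact * (1 - exact) / iters)
        assert abs(res.loc[0, "p_emp"] - expected) <= 3 * se

    def test_tied_scores_make_every_set_null(self):
        genes = [(f"G{i}", 1.5) for i in range(8)]
        res = gsr_test(scores_frame(genes),
                       sets_frame({"A": ["G0", "G1"], "B": ["G2", "G3", "G4"]}),
                       iterations=100, seed=0)
        assert (res["p_emp"] == 1.0).all()

    def test_size_bound_exclusion_leaves_other_sets_unchanged(self):
        genes = [(f"G{i}", float(i % 4)) for i in range(12)]
        small = sets_frame({"keep": ["G1", "G2", "G3"]})
        with_oversize = pd.concat(
            [small, sets_frame({"big": [f"G{i}" for i in range(12)]})],
            ignore_index=True,
        )
        a = gsr_test(scores_frame(genes), small, iterations=300, seed=2)
        b = gsr_test(scores_frame(genes), with_oversize, iterations=300, seed=2,
                     max_size=5)
        a_keep = a.set_index("set_id").loc["keep"]
        b_keep = b.set_index("set_id").loc["keep"]
        assert a_keep["p_emp"] == b_keep["p_emp"]
        assert "big" not in set(b["set_id"])

    def test_single_scored_member_set_excluded(self):
        genes = [(f"G{i}", float(i)) for i in range(6)]
        sets = sets_frame({"lonely": ["G1", "ZZZ"], "ok": ["G1", "G2"]})
        res = gsr_test(scores_frame(genes), sets, iterations=50, seed=0)
        assert set(res["set_id"]) == {"ok"}


class TestMultifunctionality:
    def test_k_top_zero_is_identity(self):
        genes = [(f"G{i}", float(i)) for i in range(8)]
        sets = sets_frame({"A": ["G6", "G7"], "B": ["G0", "G1"]})
        res = gsr_test(scores_frame(genes), sets, iterations=200, seed=1)
        out = multifunctionality_check(sets, res, scores_frame(genes), 0,
                                       iterations=200, seed=1)
        assert not out["multifunctionality_flagged"].any()
        pd.testing.assert_frame_equal(
            out.drop(columns="multifunctionality_flagged"),
            res.drop(columns="multifunctionality_flagged"),
        )

    def test_single_driver_gene_set_gets_flagged(self):
        # G49 carries a huge score and sits in three sets; pair set A is
        # significant only through it (null pairs hit the driver w.p. 2/50)
        genes = [(f"G{i}", 0.1) for i in range(49)] + [("G49", 50.0)]
        sets = sets_frame({
            "A": ["G49", "G0"],
            "B": ["G49", "G1", "G2", "G3", "G4", "G5"],
            "C": ["G49", "G6", "G7", "G8", "G9", "G10"],
            "D": ["G11", "G12"],
        })
        res = gsr_test(scores_frame(genes), sets, iterations=2000, seed=4)
        assert res.set_index("set_id").loc["A", "p_emp"] <= 0.05
        out = multifunctionality_check(sets, res, scores_frame(genes), 1,
                                       alpha=0.05, iterations=2000, seed=4)
        assert bool(out.set_index("set_id").loc["A", "multifunctionality_flagged"])

    def test_k_top_beyond_gene_count_refused(self):
        genes = [(f"G{i}", 1.0) for i in range(4)]
        sets = sets_frame({"A": ["G0", "G1"]})
        res = gsr_test(scores_frame(genes), sets, iterations=10, seed=0)
        with pytest.raises(ValueError):
            multifunctionality_check(sets, res, scores_frame(genes), 99)


class TestPlantedSetRecovery:
    def test_planted_enriched_set_reaches_significance(self):
        """The generator's planted gene set (members host planted DMRs)
        attains q < 0.05 when scored from the pipeline's own p-values."""
        from medipdmr import annotate, benchmark
        from medipdmr.simulate import SimulationConfig, simulate_study

        cfg = SimulationConfig(seed=71, n_regions=1500, n_genes=300)
        study = simulate_study(cfg)
        result = benchmark.analyze_study(study)
        ann = annotate.annotate_regions(result["regions"],
                                        study.annotation.features)
        scores = gene_scores(result["tables"]["concordant"], ann, "PAEvCON")
        res = gsr_test(scores, study.gene_sets, iterations=2000, seed=7)
        by = res.set_index("set_id")
        assert study.planted_set_id in by.index
        assert by.loc[study.planted_set_id, "q"] < 0.05


class TestFinalPathways:
    def result(self, sig):
        return pd.DataFrame(
            {
                "set_id": list(sig),
                "size": 5,
                "observed_score": 1.0,
                "p_emp": [0.001 if s else 0.9 for s in sig.values()],
                "q": [0.01 if s else 0.9 for s in sig.values()],
                "multifunctionality_flagged": False,
            }
        )

    def test_contrast_intersection_rules(self):
        res = {
            "PAEvCON": self.result({"S1": True, "S2": True, "S3": False}),
            "PAEvPF": self.result({"S1": True, "S2": False, "S3": False}),
            "PFvCON": self.result({"S1": False, "S2": True, "S3": False}),
        }
        out = final_pathway_sets(res)
        assert out["PAE_specific"] == ["S1"]
        assert out["shared"] == ["S2"]
        assert all("S3" not in v for v in out.values())

    def test_flagged_sets_do_not_count_as_significant(self):
        res = {
            "PAEvCON": self.result({"S1": True}),
            "PAEvPF": self.result({"S1": True}),
            "PFvCON": self.result({"S1": False}),
        }
        res["PAEvCON"]["multifunctionality_flagged"] = True
        assert final_pathway_sets(res)["PAE_specific"] == []


class TestGeneListOverlap:
    def test_case_insensitive_match(self):
        out = gene_list_overlap(
            {("concordant", "PAE_specific"): {"Negr1", "Kcnn1"}},
            {"asd_gwas": ["NEGR1", "MMS22L"]},
        )
        assert out.loc[0, "overlap_genes"] == "NEGR1"

    def test_empty_list_and_duplicates(self):
        out = gene_list_overlap(
            {("female", "shared"): ["Nrg2", "NRG2", "nrg2"]},
            {"empty": [], "buccal": ["NRG2", "NRG2"]},
        )
        by = out.set_index("list")
        assert by.loc["empty", "n_overlap"] == 0
        assert by.loc["buccal", "overlap_genes"] == "NRG2"
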