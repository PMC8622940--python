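"""RPKM, log transform, and empirical-Bayes batch adjustment."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from medipdmr.normalize import (
    build_protected_design,
    combat_adjust,
    log_transform,
    rpkm,
)


def toy_counts(values, lengths, libs):
    counts = pd.DataFrame(values, dtype=float)
    counts.index = [f"R{i}" for i in range(counts.shape[0])]
    counts.columns = [f"s{i}" for i in range(counts.shape[1])]
    return (
        counts,
        pd.Series(lengths, index=counts.index),
        pd.Series(libs, index=counts.columns),
    )


class TestRpkm:
    def test_unit_and_zero_cases(self):
        counts, lengths, libs = toy_counts([[0], [10], [1]], [500, 500, 1000],
                                           [1_000_000])
        out = rpkm(counts, lengths, libs)
        assert out.loc["R0", "s0"] == 0.0
        assert out.loc["R1", "s0"] == pytest.approx(20.0)
        assert out.loc["R2", "s0"] == pytest.approx(1.0)

    def test_zero_library_size_error_names_sample(self):
        counts, lengths, libs = toy_counts([[1, 1]], [100], [10, 0])
        with pytest.raises(ValueError, match="s1"):
            rpkm(counts, lengths, libs)

    def test_linear_in_counts(self, rng):
        vals = rng.integers(0, 50, size=(10, 4))
        counts, lengths, libs = toy_counts(vals, rng.integers(100, 900, 10),
                                           rng.integers(10**5, 10**6, 4))
        a = rpkm(counts, lengths, libs)
        b = rpkm(3 * counts, lengths, libs)
        pd.testing.assert_frame_equal(3 * a, b)


class TestLogTransform:
    def test_pseudocount_anchors(self):
        m = pd.DataFrame({"s": [0.0, 1.5]})
        out = log_transform(m, pseudocount=0.5)
        assert out["s"].tolist() == [-1.0, 1.0]

    def test_monotone(self, rng):
        m = pd.DataFrame({"s": np.sort(rng.random(20))})
        out = log_transform(m)
        assert (np.diff(out["s"]) >= 0).all()

    def test_rejects_nonpositive_pseudocount(self):
        with pytest.raises(ValueError):
            log_transform(pd.DataFrame({"s": [1.0]}), pseudocount=0.0)


def _toy_design(n, groups=None, sexes=None):
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "group": groups or ["CON"] * n,
            "sex": sexes or ["F"] * n,
        }
    )


class TestCombat:
    def test_single_batch_is_identity(self, rng):
        Y = pd.DataFrame(rng.normal(0, 1, (30, 8)),
                         columns=[f"s{i}" for i in range(8)])
        design = _toy_design(8)
        prot = build_protected_design(design)
        prot.index = Y.columns
        batch = pd.Series(["B1"] * 8, index=Y.columns)
        out, model = combat_adjust(Y, batch, prot)
        assert np.abs(out.to_numpy() - Y.to_numpy()).max() < 1e-10
        assert float(model.gamma_star.to_numpy().max()) == 0.0

    def test_pure_location_shift_removed_like_mean_centering(self, rng):
        # no biological covariates, batch 2 shifted +0.7: after adjustment
        # per-batch means agree; oracle is direct per-batch mean-centering
        n_r, n_s = 200, 40
        batch = pd.Series(["B1"] * 20 + ["B2"] * 20,
                          index=[f"s{i}" for i in range(n_s)])
        Y = pd.DataFrame(rng.normal(5, 1, (n_r, n_s)), columns=batch.index)
        Y.loc[:, batch == "B2"] += 0.7
        design = _toy_design(n_s)
        prot = build_protected_design(design)
        prot.index = Y.columns
        out, _ = combat_adjust(Y, batch, prot)
        m1 = out.loc[:, (batch == "B1").to_numpy()].mean(axis=1)
        m2 = out.loc[:, (batch == "B2").to_numpy()].mean(axis=1)
        assert abs(m1.mean() - m2.mean()) < 0.05
        centered = Y.copy()
        for b in ("B1", "B2"):
            cols = (batch == b).to_numpy()
            sub = centered.loc[:, cols]
            centered.loc[:, cols] = sub.sub(sub.mean(axis=1), axis=0)
        centered += Y.mean(axis=1).to_numpy()[:, None]
        assert np.abs(out.to_numpy() - centered.to_numpy()).mean() < 0.15

    def test_protected_group_effect_survives_adjustment(self, rng):
        n_r, n_s = 200, 40
        ids = [f"s{i}" for i in range(n_s)]
        design = pd.DataFrame(
            {
                "sample_id": ids,
                "group": (["CON"] * 10 + ["PAE"] * 10) * 2,
                "sex": ["F", "M"] * 20,
            }
        )
        batch = pd.Series(["B1"] * 20 + ["B2"] * 20, index=ids)
        Y = pd.DataFrame(rng.normal(0, 0.5, (n_r, n_s)), columns=ids)
        Y.loc[:, (batch == "B2").to_numpy()] += 0.5
        pae = (design["group"] == "PAE").to_numpy()
        Y.loc[:, pae] += 1.0
        prot = build_protected_design(design)
        prot.index = ids
        out, _ = combat_adjust(Y, batch, prot)
        diff = (
            out.loc[:, pae].mean(axis=1) - out.loc[:, ~pae].mean(axis=1)
        ).mean()
        assert diff == pytest.approx(1.0, abs=0.1)
        b_diff = (
            out.loc[:, (batch == "B2").to_numpy()].mean(axis=1)
            - out.loc[:, (batch == "B1").to_numpy()].mean(axis=1)
        ).mean()
        assert abs(b_diff) < 0.05

    def test_confounded_batch_refused(self, rng):
        ids = [f"s{i}" for i in range(8)]
        design = pd.DataFrame(
            {"sample_id": ids, "group": ["CON"] * 4 + ["PAE"] * 4,
             "sex": ["F"] * 8}
        )
        batch = pd.Series(["B1"] * 4 + ["B2"] * 4, index=ids)
        Y = pd.DataFrame(rng.normal(0, 1, (20, 8)), columns=ids)
        prot = build_protected_design(design)
        prot.index = ids
        with pytest.raises(ValueError, match="confounded"):
            combat_adjust(Y, batch, prot)

    def test_batch_with_single_sample_refused(self, rng):
        ids = [f"s{i}" for i in range(5)]
        batch = pd.Series(["B1"] * 4 + ["B2"], index=ids)
        Y = pd.DataFrame(rng.normal(0, 1, (10, 5)), columns=ids)
        design = _toy_design(5)
        prot = build_protected_design(design)
        prot.index = ids
        with pytest.raises(ValueError, match="fewer than 2"):
            combat_adjust(Y, batch, prot)

    def test_rerunning_on_adjusted_data_estimates_null_batch_model(self, rng):
        # batch sizes of 30 keep the ddof-1 bias of the scale estimate
        # (n/(n-1)) inside the tolerance
        n_r, n_s = 300, 90
        ids = [f"s{i}" for i in range(n_s)]
        batch = pd.Series(["B1", "B2", "B3"] * 30, index=ids)
        Y = pd.DataFrame(rng.normal(2, 1, (n_r, n_s)), columns=ids)
        Y.loc[:, (batch == "B2").to_numpy()] += 0.6
        design = _toy_design(n_s)
        prot = build_protected_design(design)
        prot.index = ids
        once, _ = combat_adjust(Y, batch, prot)
        _, model = combat_adjust(once, batch, prot)
        assert np.abs(model.gamma_star.to_numpy()).mean() < 0.05
        assert np.abs(model.delta_star.to_numpy().mean() - 1.0) < 0.05

    def test_matches_reference_sva_implementation(self, rng, tmp_path):
        # independent oracle: Bioconductor sva::ComBat via Rscript
        n_r, n_s = 40, 12
        ids = [f"s{i}" for i in range(n_s)]
        design = pd.DataFrame(
            {"sample_id": ids,
             "group": ["CON", "PF", "PAE"] * 4,
             "sex": ["F", "M"] * 6}
        )
        # balanced against group and sex so nothing is confounded
        batch = pd.Series(["B1", "B1", "B2", "B2", "B1", "B2",
                           "B2", "B2", "B1", "B1", "B2", "B1"], index=ids)
        Y = pd.DataFrame(rng.normal(3, 1, (n_r, n_s)), columns=ids)
        Y.loc[:, (batch == "B2").to_numpy()] += 0.4
        Y.to_csv(tmp_path / "Y.csv", index=False)
        pd.DataFrame({"batch": batch.to_numpy(),
                      "group": design["group"],
                      "sex": design["sex"]}).to_csv(tmp_path / "meta.csv",
                                                    index=False)
        script = textwrap.dedent(
            """
            suppressMessages(library(sva))
            Y <- as.matrix(read.csv('Y.csv'))
            meta <- read.csv('meta.csv')
            mod <- model.matrix(~group+sex, data=meta)
            out <- ComBat(dat=Y, batch=meta$batch, mod=mod, par.prior=TRUE)
            write.csv(out, 'Y_R.csv', row.names=FALSE)
            """
        )
        (tmp_path / "oracle.R").write_text(script)
        subprocess.run(["Rscript", "oracle.R"], cwd=tmp_path, check=True,
                       capture_output=True)
        ref = pd.read_csv(tmp_path / "Y_R.csv").to_numpy()
        prot = build_protected_design(design)
        prot.index = ids
        out, _ = combat_adjust(Y, batch, prot)
        assert np.abs(out.to_numpy() - ref).max() < 1e-8
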