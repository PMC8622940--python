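"""Count normalization and empirical-Bayes batch adjustment.

Counts are converted to RPKM (reads per kilobase of region per million
library fragments), log2-transformed with a pseudocount, and adjusted for
batch with the parametric empirical-Bayes location/scale method
(ComBat): per-region batch deviations are standardized after removing
protected biological covariates (treatment group and sex), per-batch
normal/inverse-gamma priors are estimated by moments, posterior batch
effects are iterated to convergence, and the data are rescaled with the
protected fit restored.  Group and sex effects therefore survive the
adjustment intact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "rpkm",
    "log_transform",
    "combat_adjust",
    "BatchModel",
    "build_protected_design",
]


def rpkm(
    counts: pd.DataFrame, lengths: pd.Series, library_sizes: pd.Series
) -> pd.DataFrame:
    """count / (length/1e3) / (library_size/1e6), element-wise.

    ``lengths`` is indexed by region, ``library_sizes`` by sample.
    """
    lengths = lengths.reindex(counts.index)
    library_sizes = library_sizes.reindex(counts.columns)
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][0]
        raise ValueError(f"non-positive region length for {bad}")
    zero = library_sizes[library_sizes <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample {zero.index[0]}")
    vals = (
        counts.to_numpy(dtype=float)
        / (lengths.to_numpy()[:, None] / 1e3)
        / (library_sizes.to_numpy()[None, :] / 1e6)
    )
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


def log_transform(rpkm_matrix: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """log2(rpkm + pseudocount); the pseudocount keeps zeros finite."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return np.log2(rpkm_matrix + pseudocount)


@dataclass
class BatchModel:
    """Fitted batch-adjustment parameters, for inspection and testing."""

    batches: list[str]
    gamma_star: pd.DataFrame   # batches x regions, posterior location
    delta_star: pd.DataFrame   # batches x regions, posterior scale (>0)
    gamma_bar: pd.Series       # per-batch location prior mean
    tau2: pd.Series            # per-batch location prior variance
    a_prior: pd.Series         # per-batch inverse-gamma shape
    b_prior: pd.Series         # per-batch inverse-gamma scale
    n_iter: pd.Series          # EB iterations per batch
    tolerance: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b in self.batches:
            rows.append(
                {
                    "batch": b,
                    "gamma_bar": self.gamma_bar[b],
                    "tau2": self.tau2[b],
                    "a_prior": self.a_prior[b],
                    "b_prior": self.b_prior[b],
                    "n_iter": self.n_iter[b],
                    "gamma_star_mean": self.gamma_star.loc[b].mean(),
                    "delta_star_mean": self.delta_star.loc[b].mean(),
                }
            )
        return pd.DataFrame(rows)


def build_protected_design(design: pd.DataFrame) -> pd.DataFrame:
    """Model matrix of the protected covariates: intercept + group + sex.

    Treatment coding with CON and F as references; column order is fixed
    (intercept, group_PF, group_PAE, sex_M) so downstream contrasts are
    stable.  Single-sex designs drop the sex column.
    """
    X = pd.DataFrame(index=design.index)
    X["intercept"] = 1.0
    X["group_PF"] = (design["group"] == "PF").astype(float)
    X["group_PAE"] = (design["group"] == "PAE").astype(float)
    if design["sex"].nunique() > 1:
        X["sex_M"] = (design["sex"] == "M").astype(float)
    return X


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2.0 * s2 + m**2) / s2 if s2 > 0 else np.inf


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2 if s2 > 0 else np.inf


def combat_adjust(
    matrix: pd.DataFrame,
    batch: pd.Series,
    design: pd.DataFrame,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> tuple[pd.DataFrame, BatchModel]:
    """Parametric empirical-Bayes batch adjustment protecting covariates.

    ``matrix`` is regions x samples (log scale), ``batch`` maps sample to
    batch label, and ``design`` holds the protected covariates (intercept
    plus group/sex indicators; see :func:`build_protected_design`).
    With a single batch the data are returned unchanged.

    Raises if any batch has < 2 samples or if batch is confounded with a
    protected covariate (joint model matrix loses rank).
    """
    batch = batch.reindex(matrix.columns)
    if batch.isna().any():
        raise ValueError("batch labels missing for some samples")
    levels = sorted(batch.unique())
    if len(levels) == 1:
        model = _identity_model(levels, matrix.index, tol)
        return matrix.copy(), model
    sizes = batch.value_counts()
    if (sizes < 2).any():
        small = sizes.index[sizes < 2][0]
        raise ValueError(f"batch {small!r} has fewer than 2 samples")

    Y = matrix.to_numpy(dtype=float)  # regions x samples
    n_r, n_s = Y.shape
    B = np.stack([(batch == lv).to_numpy(float) for lv in levels], axis=1)
    covars = design.drop(columns=[c for c in design.columns
                                  if design[c].nunique() == 1], errors="ignore")
    X = np.hstack([B, covars.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "batch is confounded with a protected covariate: the joint "
            "batch+covariate design is rank-deficient; adjustment refused"
        )

    # per-region OLS of samples on [batch indicators, protected covariates]
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # (p, regions)
    n_batch = len(levels)
    frac = sizes.reindex(levels).to_numpy() / n_s
    grand_mean = frac @ beta[:n_batch]  # weighted batch intercepts, per region
    stand_mean = grand_mean[None, :].T @ np.ones((1, n_s))
    stand_mean += (covars.to_numpy(dtype=float) @ beta[n_batch:]).T
    var_pooled = ((Y - (X @ beta).T) ** 2).mean(axis=1)
    var_pooled = np.maximum(var_pooled, 1e-12)
    Z = (Y - stand_mean) / np.sqrt(var_pooled)[:, None]

    gamma_star = np.zeros((n_batch, n_r))
    delta_star = np.ones((n_batch, n_r))
    gamma_bar = np.zeros(n_batch)
    tau2 = np.zeros(n_batch)
    a_pr = np.zeros(n_batch)
    b_pr = np.zeros(n_batch)
    iters = np.zeros(n_batch, dtype=int)
    for bi, lv in enumerate(levels):
        cols = (batch == lv).to_numpy()
        Zb = Z[:, cols]
        nb = Zb.shape[1]
        g_hat = Zb.mean(axis=1)
        d_hat = Zb.var(axis=1, ddof=1)
        gamma_bar[bi] = g_hat.mean()
        tau2[bi] = g_hat.var(ddof=1)
        a_pr[bi] = _aprior(d_hat)
        b_pr[bi] = _bprior(d_hat)
        g_new, d_new = g_hat.copy(), d_hat.copy()
        for it in range(1, max_iter + 1):
            g_old, d_old = g_new, d_new
            g_new = (tau2[bi] * nb * g_hat + d_old * gamma_bar[bi]) / (
                tau2[bi] * nb + d_old
            )
            sum2 = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (0.5 * sum2 + b_pr[bi]) / (nb / 2.0 + a_pr[bi] - 1.0)
            # element-wise relative change, as in the canonical EB iteration
            with np.errstate(divide="ignore", invalid="ignore"):
                change = max(
                    np.nanmax(np.abs(g_new - g_old) / np.abs(g_old)),
                    np.nanmax(np.abs(d_new - d_old) / np.abs(d_old)),
                )
            if change < tol:
                break
        iters[bi] = it
        gamma_star[bi] = g_new
        delta_star[bi] = np.maximum(d_new, 1e-12)

    adjusted = Z.copy()
    for bi, lv in enumerate(levels):
        cols = (batch == lv).to_numpy()
        adjusted[:, cols] = (
            (Z[:, cols] - gamma_star[bi][:, None])
            / np.sqrt(delta_star[bi])[:, None]
        )
    adjusted = adjusted * np.sqrt(var_pooled)[:, None] + stand_mean
    out = pd.DataFrame(adjusted, index=matrix.index, columns=matrix.columns)
    model = BatchModel(
        batches=list(map(str, levels)),
        gamma_star=pd.DataFrame(gamma_star, index=levels, columns=matrix.index),
        delta_star=pd.DataFrame(delta_star, index=levels, columns=matrix.index),
        gamma_bar=pd.Series(gamma_bar, index=levels),
        tau2=pd.Series(tau2, index=levels),
        a_prior=pd.Series(a_pr, index=levels),
        b_prior=pd.Series(b_pr, index=levels),
        n_iter=pd.Series(iters, index=levels),
        tolerance=tol,
    )
    return out, model


def _identity_model(levels, regions, tol) -> BatchModel:
    lv = list(map(str, levels))
    zero = pd.DataFrame(np.zeros((1, len(regions))), index=levels, columns=regions)
    one = pd.DataFrame(np.ones((1, len(regions))), index=levels, columns=regions)
    return BatchModel(
        batches=lv,
        gamma_star=zero,
        delta_star=one,
        gamma_bar=pd.Series([0.0], index=levels),
        tau2=pd.Series([0.0], index=levels),
        a_prior=pd.Series([np.inf], index=levels),
        b_prior=pd.Series([np.inf], index=levels),
        n_iter=pd.Series([0], index=levels),
        tolerance=tol,
    )
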