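"""Per-region linear models, moderated contrasts and FDR control.

Three analysis tiers are fit on the normalized (log2-RPKM,
batch-adjusted) matrix:

* ``concordant`` — all samples, model ``~ group + sex``;
* ``female`` / ``male`` — single-sex subsets, model ``~ group``.

Ordinary least squares with treatment coding (CON reference) gives, for
each region, coefficients for PF and PAE; the three contrasts of interest
are PAEvCON (= beta_PAE), PFvCON (= beta_PF) and PAEvPF
(= beta_PAE - beta_PF).  Residual variances are shrunk toward a common
prior by empirical Bayes: the prior degrees of freedom d0 and prior
variance s0^2 are estimated by matching the first two moments of the log
sample variances to the scaled-F prior predictive (trigamma-inverse
method), and the moderated t statistic uses the posterior variance
s~^2 = (d0 s0^2 + d s^2) / (d0 + d) with d0 + d degrees of freedom.
Benjamini-Hochberg correction is applied within each contrast x tier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

TIERS = ("concordant", "female", "male")
CONTRASTS = ("PAEvCON", "PAEvPF", "PFvCON")

__all__ = [
    "ModelSpec",
    "FitResult",
    "ModerationParams",
    "fit_models",
    "estimate_moderation",
    "contrast_tests",
    "bh_fdr",
    "run_tier",
]


@dataclass(frozen=True)
class ModelSpec:
    """Which samples and which formula a tier uses."""

    tier: str  # concordant | female | male

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise ValueError(f"unknown tier {self.tier!r}")

    def subset(self, design: pd.DataFrame) -> pd.DataFrame:
        if self.tier == "female":
            return design[design["sex"] == "F"]
        if self.tier == "male":
            return design[design["sex"] == "M"]
        return design

    @property
    def with_sex_term(self) -> bool:
        return self.tier == "concordant"


@dataclass
class FitResult:
    """Per-region OLS output for one tier."""

    tier: str
    coef: pd.DataFrame        # regions x coefficient names
    sigma2: pd.Series         # residual variance per region
    df_resid: int
    xtx_inv: pd.DataFrame     # (X'X)^-1, coefficient basis
    n_samples: int


@dataclass(frozen=True)
class ModerationParams:
    """Empirical-Bayes variance prior: d0 (prior df) and s0^2."""

    d0: float
    s0sq: float

    def posterior_variance(self, s2: np.ndarray, d: float) -> np.ndarray:
        if self.d0 == 0:
            return np.asarray(s2, dtype=float)
        if np.isinf(self.d0):
            return np.full_like(np.asarray(s2, dtype=float), self.s0sq)
        return (self.d0 * self.s0sq + d * s2) / (self.d0 + d)


def _model_matrix(design: pd.DataFrame, with_sex: bool) -> pd.DataFrame:
    X = pd.DataFrame(index=design.index)
    X["intercept"] = 1.0
    # treatment coding, CON reference; only groups actually present get a
    # column so reduced designs (e.g. two-group toys) stay full rank
    present = set(design["group"])
    for g in ("PF", "PAE"):
        if g in present:
            X[f"group_{g}"] = (design["group"] == g).astype(float)
    if with_sex:
        X["sex_M"] = (design["sex"] == "M").astype(float)
    return X


def fit_models(
    matrix: pd.DataFrame, design: pd.DataFrame, spec: ModelSpec
) -> FitResult:
    """Vectorized per-region OLS for one tier.

    ``matrix`` is regions x samples; the design is subset to the tier's
    samples.  Raises on an empty subset or a rank-deficient model matrix
    (e.g. a missing group), naming the offending columns.
    """
    sub = spec.subset(design)
    if sub.empty:
        raise ValueError(f"tier {spec.tier!r}: no samples after subsetting")
    X = _model_matrix(sub, spec.with_sex_term)
    Xv = X.to_numpy()
    rank = np.linalg.matrix_rank(Xv)
    if rank < Xv.shape[1]:
        raise ValueError(
            f"tier {spec.tier!r}: rank-deficient design over columns "
            f"{list(X.columns)}; check that every group (and sex) is present"
        )
    Y = matrix[sub["sample_id"]].to_numpy(dtype=float)  # regions x n
    xtx = Xv.T @ Xv
    xtx_inv = np.linalg.inv(xtx)
    beta = (xtx_inv @ Xv.T @ Y.T).T  # regions x p
    resid = Y - beta @ Xv.T
    df_resid = Xv.shape[0] - Xv.shape[1]
    if df_resid <= 0:
        raise ValueError(f"tier {spec.tier!r}: no residual degrees of freedom")
    sigma2 = (resid**2).sum(axis=1) / df_resid
    return FitResult(
        tier=spec.tier,
        coef=pd.DataFrame(beta, index=matrix.index, columns=X.columns),
        sigma2=pd.Series(sigma2, index=matrix.index),
        df_resid=df_resid,
        xtx_inv=pd.DataFrame(xtx_inv, index=X.columns, columns=X.columns),
        n_samples=Xv.shape[0],
    )


def _trigamma_inverse(y: float, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_moderation(sigma2: pd.Series, df_resid: int) -> ModerationParams:
    """Fit the scaled-F variance prior by moment matching on log variances.

    Writes z = log(s^2); under the hierarchical model
    E[z] = log(s0^2) + digamma(d/2) - log(d/2) - digamma(d0/2) + log(d0/2)
    and Var[z] = trigamma(d/2) + trigamma(d0/2).  d0 is recovered by
    trigamma inversion of the excess spread; when the observed spread does
    not exceed the chi-square sampling spread, d0 is infinite and s0^2 is
    the (geometric-mean) common variance.
    """
    s2 = sigma2.to_numpy(dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need >= 2 regions with positive residual variance")
    z = np.log(s2[ok])
    d = float(df_resid)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    evar = z.var(ddof=1) - special.polygamma(1, d / 2.0)
    if evar <= 0:
        # no excess spread: variances are exchangeable around one value
        return ModerationParams(d0=np.inf, s0sq=float(np.exp(z.mean())))
    d0 = 2.0 * _trigamma_inverse(float(evar))
    if np.isinf(d0):
        return ModerationParams(d0=np.inf, s0sq=float(np.exp(z.mean())))
    s0sq = float(np.exp(e.mean() + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return ModerationParams(d0=d0, s0sq=s0sq)


_CONTRAST_VECTORS = {
    "PAEvCON": {"group_PAE": 1.0},
    "PFvCON": {"group_PF": 1.0},
    "PAEvPF": {"group_PAE": 1.0, "group_PF": -1.0},
}


def contrast_tests(
    fit: FitResult,
    moderation: ModerationParams | None = None,
    contrasts: tuple[str, ...] = CONTRASTS,
    apply_fdr: bool = True,
) -> pd.DataFrame:
    """Moderated t tests for the requested contrasts.

    Returns long-format rows (region_id, contrast, logFC, t, p, q) with
    BH-adjusted q computed within each contrast.  ``moderation=None`` or
    d0 = 0 gives the ordinary (unmoderated) t test.
    """
    if moderation is None:
        moderation = ModerationParams(d0=0.0, s0sq=1.0)
    d = fit.df_resid
    s2_post = moderation.posterior_variance(fit.sigma2.to_numpy(), d)
    df_total = np.inf if np.isinf(moderation.d0) else moderation.d0 + d
    frames = []
    for name in contrasts:
        cvec = np.zeros(len(fit.coef.columns))
        for col, w in _CONTRAST_VECTORS[name].items():
            if col not in fit.coef.columns:
                raise ValueError(
                    f"contrast {name!r} needs coefficient {col!r}, absent "
                    f"from the fitted design (group missing from the data?)"
                )
            cvec[fit.coef.columns.get_loc(col)] = w
        est = fit.coef.to_numpy() @ cvec
        v = float(cvec @ fit.xtx_inv.to_numpy() @ cvec)
        se = np.sqrt(s2_post * v)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, est / se, 0.0)
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df_total)
        p = np.clip(p, 0.0, 1.0)
        frames.append(
            pd.DataFrame(
                {
                    "region_id": fit.coef.index,
                    "contrast": name,
                    "logFC": est,
                    "t": t,
                    "p": p,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    if apply_fdr:
        out["q"] = np.nan
        for name in contrasts:
            mask = out["contrast"] == name
            out.loc[mask, "q"] = bh_fdr(out.loc[mask, "p"].to_numpy())
    return out


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_tier(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    tier: str,
    moderate: bool = True,
) -> pd.DataFrame:
    """Fit one tier end to end: OLS, moderation, contrasts, BH."""
    spec = ModelSpec(tier)
    fit = fit_models(matrix, design, spec)
    mod = estimate_moderation(fit.sigma2, fit.df_resid) if moderate else None
    table = contrast_tests(fit, mod)
    table.insert(1, "tier", tier)
    return table
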