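"""Moderated linear-model differential analysis of circuit activities.

Per feature (circuit or gene) an ordinary least-squares linear model is fit
with the sample condition and an optional batch covariate (tissue source
site); the contrast of interest is case minus control.  Residual variances
are then shrunk toward a common prior with an empirical-Bayes scheme: the
prior (d0, s0^2) of a scaled inverse-chi-square distribution is estimated by
method of moments on log s^2 (using the digamma/trigamma moments of log
chi-square variables), and the moderated t-statistic uses the posterior
variance (d0*s0^2 + d*s^2) / (d0 + d) on d0 + d degrees of freedom.

Multiple testing is controlled with Benjamini-Hochberg step-up FDR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DesignSpec",
    "LinearFit",
    "ModeratedStats",
    "fit_linear_model",
    "ebayes_moderate",
    "bh_adjust",
    "differential_table",
    "cross_contrast_intersection",
]


@dataclass
class DesignSpec:
    """Per-sample condition labels, an optional batch label, and the contrast
    (case label, control label)."""

    condition: pd.Series
    contrast: tuple[str, str]
    batch: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.condition.isna().any():
            raise ValueError("every sample must carry a condition label")
        case, control = self.contrast
        levels = set(self.condition)
        for lab in (case, control):
            if lab not in levels:
                raise ValueError(f"contrast label {lab!r} absent from condition")
        if self.batch is not None:
            self.batch = self.batch.reindex(self.condition.index)
            if self.batch.isna().any():
                raise ValueError("every sample must carry a batch label")


class LinearFit(NamedTuple):
    coef: pd.Series  # contrast coefficient (case - control) per feature
    s2: pd.Series  # residual variance per feature
    df_resid: int
    stdev_unscaled: float  # sqrt of the contrast element of (X'X)^-1


class ModeratedStats(NamedTuple):
    d0: float
    s0_2: float
    s2_post: pd.Series
    t: pd.Series
    p: pd.Series


def build_design_matrix(design: DesignSpec) -> pd.DataFrame:
    """Intercept + condition dummies (control as reference) + batch dummies
    (first level dropped).  Raises naming aliased columns when rank deficient."""
    _, control = design.contrast
    samples = design.condition.index
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(samples))}
    for level in sorted(set(design.condition)):
        if level == control:
            continue
        cols[f"cond[{level}]"] = (design.condition == level).to_numpy(dtype=float)
    if design.batch is not None:
        blevels = sorted(set(design.batch))
        for level in blevels[1:]:
            cols[f"batch[{level}]"] = (design.batch == level).to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=samples)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify aliased columns via QR with column pivoting
        from scipy.linalg import qr

        _, rmat, piv = qr(X.to_numpy(), mode="economic", pivoting=True)
        diag = np.abs(np.diag(rmat))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        aliased = [X.columns[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        aliased += [X.columns[j] for j in piv[len(diag):]]
        raise ValueError(f"rank-deficient design; aliased columns: {sorted(set(map(str, aliased)))}")
    return X


def fit_linear_model(matrix: pd.DataFrame, design: DesignSpec) -> LinearFit:
    """Row-wise OLS of features x samples data on the encoded design."""
    X = build_design_matrix(design)
    Y = matrix.loc[:, X.index].to_numpy(dtype=float)
    Xn = X.to_numpy()
    n, p = Xn.shape
    if n <= p:
        raise ValueError(f"not enough residual degrees of freedom (n={n}, p={p})")
    xtx_inv = np.linalg.inv(Xn.T @ Xn)
    beta = Y @ (xtx_inv @ Xn.T).T  # features x p
    resid = Y - beta @ Xn.T
    s2 = (resid ** 2).sum(axis=1) / (n - p)
    case, _ = design.contrast
    j = X.columns.get_loc(f"cond[{case}]")
    return LinearFit(
        coef=pd.Series(beta[:, j], index=matrix.index, name="coef"),
        s2=pd.Series(s2, index=matrix.index, name="s2"),
        df_resid=n - p,
        stdev_unscaled=float(np.sqrt(xtx_inv[j, j])),
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if -dif / x < 1e-8:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square prior (d0, s0^2)
    from observed residual variances with d residual df each.

    Uses E/Var of log chi-square: if s^2 ~ s0^2 * F(d, d0) then
    var(log s^2) = trigamma(d/2) + trigamma(d0/2).
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2 > 0
    if pos.sum() < 10:
        raise ValueError("need >= 10 features with positive residual variance")
    z = np.log(s2[pos])
    e = z - digamma(d / 2.0) + np.log(d / 2.0)
    evar = np.var(e, ddof=1) - polygamma(1, d / 2.0)
    if evar <= 0:
        d0 = np.inf
        s0_2 = float(np.exp(np.mean(e)))
    else:
        d0 = 2.0 * _trigamma_inverse(float(evar))
        s0_2 = float(np.exp(np.mean(e) + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s0_2


def ebayes_moderate(
    fit: LinearFit,
    d0: float | None = None,
    s0_2: float | None = None,
) -> ModeratedStats:
    """Moderated t-statistics from an OLS fit.

    d0/s0_2 are estimated by :func:`fit_variance_prior` unless given
    explicitly (d0=0 reproduces the classical t; d0=inf uses the prior
    variance for every feature).
    """
    s2 = fit.s2.to_numpy(dtype=float)
    d = fit.df_resid
    if d0 is None:
        try:
            d0, s0_fit = fit_variance_prior(s2, d)
        except ValueError:
            # too few features to estimate a prior: classical t
            d0, s0_fit = 0.0, float("nan")
        if s0_2 is None:
            s0_2 = s0_fit
    elif s0_2 is None and d0 > 0:
        _, s0_2 = fit_variance_prior(s2, d)
    if d0 == 0:
        s2_post = s2.copy()
        df_total = float(d)
    elif np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + d * s2) / (d0 + d)
        df_total = d0 + d
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fit.coef.to_numpy() / (np.sqrt(s2_post) * fit.stdev_unscaled)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isnan(t), 1.0, p)
    idx = fit.coef.index
    return ModeratedStats(
        d0=float(d0),
        s0_2=float(s0_2) if s0_2 is not None else float("nan"),
        s2_post=pd.Series(s2_post, index=idx),
        t=pd.Series(t, index=idx),
        p=pd.Series(p, index=idx),
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_table(
    matrix: pd.DataFrame,
    design: DesignSpec,
    alpha: float = 0.05,
    d0: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full differential table (sorted by FDR) and its significant subset.

    Columns: feature_id, log2FC (contrast coefficient), t_mod, p, fdr,
    direction.  ``d0`` overrides the estimated prior df (0 = classical t).
    """
    fit = fit_linear_model(matrix, design)
    mod = ebayes_moderate(fit, d0=d0)
    table = pd.DataFrame(
        {
            "feature_id": matrix.index,
            "log2FC": fit.coef.to_numpy(),
            "t_mod": mod.t.to_numpy(),
            "p": mod.p.to_numpy(),
            "fdr": bh_adjust(mod.p.to_numpy()),
        }
    )
    table["direction"] = np.where(table["log2FC"] >= 0, "up", "down")
    table = table.sort_values(["fdr", "p", "feature_id"], kind="stable").reset_index(drop=True)
    significant = table[table["fdr"] < alpha].reset_index(drop=True)
    return table, significant


def cross_contrast_intersection(
    tables: dict[str, pd.DataFrame],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Features significant with the same direction in *all* contrasts, with
    effect sizes and FDRs averaged across contrasts."""
    if not tables:
        return pd.DataFrame(columns=["feature_id", "direction", "n_contrasts", "log2FC", "fdr"])
    sig_sets = []
    for name, tab in tables.items():
        sig = tab[tab["fdr"] < alpha][["feature_id", "log2FC", "fdr", "direction"]].copy()
        sig["contrast"] = name
        sig_sets.append(sig)
    allsig = pd.concat(sig_sets, ignore_index=True)
    rows = []
    for fid, grp in allsig.groupby("feature_id", sort=True):
        if len(grp) == len(tables) and grp["direction"].nunique() == 1:
            rows.append(
                {
                    "feature_id": fid,
                    "direction": grp["direction"].iloc[0],
                    "n_contrasts": len(grp),
                    "log2FC": grp["log2FC"].mean(),
                    "fdr": grp["fdr"].mean(),
                }
            )
    return pd.DataFrame(rows, columns=["feature_id", "direction", "n_contrasts", "log2FC", "fdr"])
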