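"""Count normalization and rescaling ahead of activity propagation.

Pipeline: raw gene counts -> TMM scaling factors -> log2-CPM -> per-gene
rescaling to [0, 1] -> imputation of pathway genes absent from the assay.

TMM (trimmed mean of M-values) computes per-sample scaling factors under the
assumption that most genes are not differentially expressed: for each sample
vs. a reference, log-ratios (M) are doubly trimmed (on M and on average
abundance A) and averaged with inverse approximate binomial variance weights.
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "NormalizedMatrix",
    "tmm_factors",
    "log_cpm",
    "rescale_unit",
    "impute_missing",
]


class NormalizedMatrix(NamedTuple):
    """log2-scale normalized expression values with the TMM factors used."""

    values: pd.DataFrame  # genes x samples, log2 scale
    lib_factors: pd.Series  # per-sample TMM factor, geometric mean 1


def _check_counts(counts: pd.DataFrame) -> np.ndarray:
    x = counts.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("count matrix contains negative entries")
    if counts.index.duplicated().any() or counts.columns.duplicated().any():
        raise ValueError("count matrix labels must be unique")
    return x


def _tmm_pair(
    obs: np.ndarray,
    lib_obs: float,
    ref: np.ndarray,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """log2 TMM factor of one sample against the reference sample.

    Genes with zero count in either sample are excluded from the pair.
    """
    pos = (obs > 0) & (ref > 0)
    o, r = obs[pos], ref[pos]
    po, pr = o / lib_obs, r / lib_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    # inverse of the weight: delta-method variance of M under binomial sampling
    v = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    fin = np.isfinite(m) & np.isfinite(a) & (v > 0)
    m, a, v = m[fin], a[fin], v[fin]
    n = m.size
    if n == 0:
        return 0.0
    if np.max(np.abs(m)) < 1e-6:  # pure library scaling / identical columns
        return 0.0
    lo_m = math.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(m)
    rank_a = rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 0.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f) or abs(f) < 1e-6:
        return 0.0
    return float(f)


def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ref_sample: str | None = None,
) -> pd.Series:
    """Per-sample TMM scaling factors, rescaled to geometric mean 1.

    The reference sample is the one whose upper-quartile/library-size ratio is
    closest to the mean of that ratio across samples (override with
    ``ref_sample``).  Raises if any sample has an all-zero library.
    """
    x = _check_counts(counts)
    if x.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = x.sum(axis=0)
    for j, size in enumerate(lib):
        if size <= 0:
            raise ValueError(f"sample {counts.columns[j]!r} has zero library size")
    if ref_sample is None:
        f75 = np.array([np.quantile(x[:, j] / lib[j], 0.75) for j in range(x.shape[1])])
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = counts.columns.get_loc(ref_sample)
    log_factors = np.array(
        [
            _tmm_pair(x[:, j], lib[j], x[:, ref_idx], lib[ref_idx], trim_m, trim_a)
            for j in range(x.shape[1])
        ]
    )
    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def log_cpm(
    counts: pd.DataFrame,
    factors: pd.Series,
    prior: float = 0.5,
) -> NormalizedMatrix:
    """log2 counts-per-million on TMM-adjusted library sizes.

    entry = log2((count + prior) / (lib_size * factor + 2*prior) * 1e6);
    strictly monotone in the count and monotone decreasing in the factor.
    """
    x = _check_counts(counts)
    f = factors.reindex(counts.columns)
    if f.isna().any():
        raise ValueError("factors do not cover all samples")
    eff = x.sum(axis=0) * f.to_numpy(dtype=float)
    if (eff <= 0).any():
        raise ValueError("non-positive effective library size")
    vals = np.log2((x + prior) / (eff + 2 * prior) * 1e6)
    out = pd.DataFrame(vals, index=counts.index, columns=counts.columns)
    return NormalizedMatrix(values=out, lib_factors=f)


def rescale_unit(norm: NormalizedMatrix | pd.DataFrame, trunc_quantile: float = 0.99) -> pd.DataFrame:
    """Per-gene rescaling to [0, 1]: clip above the per-gene ``trunc_quantile``
    (tempers single-sample outliers), then min-max map.  Constant genes map
    to 0.5."""
    values = norm.values if isinstance(norm, NormalizedMatrix) else norm
    x = values.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("rescaling needs at least 2 samples")
    q = np.quantile(x, trunc_quantile, axis=1, keepdims=True)
    clipped = np.minimum(x, q)
    mn = clipped.min(axis=1, keepdims=True)
    mx = clipped.max(axis=1, keepdims=True)
    span = mx - mn
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = (clipped - mn) / span
    scaled = np.where(span > 0, scaled, 0.5)
    return pd.DataFrame(scaled, index=values.index, columns=values.columns)


def impute_missing(
    scaled: pd.DataFrame,
    required_genes: set[str],
    impute_value: float | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Append constant rows for pathway genes absent from the matrix.

    The fill value is the grand mean of all scaled entries unless
    ``impute_value`` overrides it.  Returns (matrix, imputed gene ids).
    Raises if *no* required gene was measured at all.
    """
    present = set(scaled.index)
    required = set(required_genes)
    if required and not (required & present):
        raise ValueError("no measured pathway genes: cannot impute the full catalog")
    missing = sorted(required - present)
    if not missing:
        return scaled, []
    fill = float(scaled.to_numpy().mean()) if impute_value is None else float(impute_value)
    extra = pd.DataFrame(fill, index=missing, columns=scaled.columns)
    return pd.concat([scaled, extra]), missing
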