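"""Negative-binomial differential expression, cold vs control per time point.

The engine mirrors the count-based testing workflow standard for RNA-seq:
median-of-ratios size factors, method-of-moments dispersion estimates
shrunk toward a fitted mean-dispersion trend, a per-feature NB GLM with
log link fitted by iteratively reweighted least squares, a two-sided Wald
test on the cold coefficient, Benjamini-Hochberg correction within the
analysis batch, and a 4-state status call:

* ``up`` / ``down``: |log2FC| >= 1 (fold change >= 2 or <= -2) and
  adjusted p <= 0.05, at detectable expression;
* ``undetected``: base mean below 5 normalized counts (the very-low
  expression bin);
* ``unchanged``: everything else.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

LN2 = np.log(2.0)

FC_THRESHOLD = 2.0  # |fold change| for a DE call
ALPHA = 0.05  # BH-adjusted significance level
DETECTION_THRESHOLD = 5.0  # normalized counts; below this a feature is undetected

_MAX_ITER = 100
_TOL = 1e-8
_BETA_CLAMP = 15.0  # natural-log scale; bounds the cold coefficient


def bh_adjust(p: np.ndarray | pd.Series | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (order-preserving, monotone)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    finite = np.isfinite(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    idx = np.where(finite)[0]
    if len(idx) == 0:
        return out
    m = len(idx)
    order = np.argsort(p[idx], kind="mergesort")
    ranked = p[idx][order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out[idx[order]] = np.minimum(adjusted, 1.0)
    return out


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Falls back to total-count scaling (with a warning) when no feature is
    nonzero in every sample.
    """
    mat = counts.to_numpy(dtype=float)
    nonzero = (mat > 0).all(axis=1)
    if nonzero.any():
        sub = mat[nonzero]
        geo = np.exp(np.log(sub).mean(axis=1))
        log_factors = np.log(np.median(sub / geo[:, None], axis=0))
    else:
        logger.warning("no all-nonzero feature; falling back to total-count scaling")
        depth = mat.sum(axis=0)
        if (depth <= 0).any():
            raise ValueError("zero-depth sample in count matrix")
        log_factors = np.log(depth)
    log_factors = log_factors - log_factors.mean()  # geometric mean 1
    return pd.Series(np.exp(log_factors), index=counts.columns, name="size_factor")


def estimate_dispersion(normalized: pd.DataFrame, groups: pd.Series) -> pd.Series:
    """Per-feature NB dispersion alpha (Var = mu + alpha mu^2).

    Method-of-moments estimate pooled across the condition groups, then
    shrunk 50/50 toward a fitted a + b/mu mean-dispersion trend.
    """
    labels = groups.loc[normalized.columns]
    sizes = labels.value_counts()
    if (sizes < 2).any():
        raise ValueError(
            "dispersion estimation needs >= 2 replicates per group; "
            "supply dispersions explicitly for single-replicate designs"
        )
    mat = normalized.to_numpy(dtype=float)
    group_vars = []
    for g in sizes.index:
        cols = np.where((labels == g).to_numpy())[0]
        group_vars.append(mat[:, cols].var(axis=1, ddof=1))
    pooled_var = np.mean(group_vars, axis=0)
    mu = mat.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(mu > 0, np.maximum(0.0, (pooled_var - mu) / mu**2), 0.0)

    trend = _fit_trend(mu, raw)
    final = 0.5 * raw + 0.5 * trend
    return pd.Series(np.maximum(final, 1e-8), index=normalized.index, name="dispersion")


def _fit_trend(mu: np.ndarray, raw: np.ndarray) -> np.ndarray:
    """Least-squares fit of alpha(mu) = a + b/mu on informative features."""
    use = mu >= 1
    if use.sum() < 10:
        level = float(np.median(raw[use])) if use.any() else 0.0
        return np.full(mu.shape, max(level, 0.0))
    x = np.column_stack([np.ones(use.sum()), 1.0 / mu[use]])
    coef, *_ = np.linalg.lstsq(x, raw[use], rcond=None)
    a, b = max(float(coef[0]), 0.0), max(float(coef[1]), 0.0)
    with np.errstate(divide="ignore"):
        trend = a + b / np.where(mu > 0, mu, np.inf)
    return trend


def _irls_nb(y: np.ndarray, x: np.ndarray, offset: np.ndarray,
             alpha: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized IRLS for the 2-parameter NB GLM with log link.

    y: (features, samples) counts; x: (samples,) cold indicator;
    offset: (samples,) log size factors; alpha: (features,) dispersions.
    Returns (beta0, beta1, se1) on the natural-log scale; non-converged
    features get NaN in se1.
    """
    n_feat, n_samp = y.shape
    mean_ctrl = np.maximum((y / np.exp(offset))[:, x == 0].mean(axis=1), 0.1)
    mean_cold = np.maximum((y / np.exp(offset))[:, x == 1].mean(axis=1), 0.1)
    beta0 = np.log(mean_ctrl)
    beta1 = np.clip(np.log(mean_cold) - beta0, -_BETA_CLAMP, _BETA_CLAMP)
    converged = np.zeros(n_feat, dtype=bool)
    se1 = np.full(n_feat, np.nan)
    alpha = alpha[:, None]

    for _ in range(_MAX_ITER):
        active = ~converged
        if not active.any():
            break
        eta = offset[None, :] + beta0[:, None] + beta1[:, None] * x[None, :]
        mu = np.clip(np.exp(eta), 1e-10, 1e12)
        w = mu / (1.0 + alpha * mu)
        z = (eta - offset[None, :]) + (y - mu) / mu
        sw = w.sum(axis=1)
        swx = (w * x[None, :]).sum(axis=1)
        swxx = (w * (x**2)[None, :]).sum(axis=1)
        swz = (w * z).sum(axis=1)
        swxz = (w * x[None, :] * z).sum(axis=1)
        det = sw * swxx - swx**2
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        new0 = (swxx * swz - swx * swxz) / det
        new1 = np.clip((sw * swxz - swx * swz) / det, -_BETA_CLAMP, _BETA_CLAMP)
        step = np.maximum(np.abs(new0 - beta0), np.abs(new1 - beta1))
        beta0 = np.where(active, new0, beta0)
        beta1 = np.where(active, new1, beta1)
        converged |= (step < _TOL) | ~np.isfinite(step)

    # final weights for the Wald standard error
    eta = offset[None, :] + beta0[:, None] + beta1[:, None] * x[None, :]
    mu = np.clip(np.exp(eta), 1e-10, 1e12)
    w = mu / (1.0 + alpha * mu)
    sw = w.sum(axis=1)
    swx = (w * x[None, :]).sum(axis=1)
    swxx = (w * (x**2)[None, :]).sum(axis=1)
    det = sw * swxx - swx**2
    good = converged & np.isfinite(det) & (det > 0)
    se1[good] = np.sqrt(sw[good] / det[good])
    return beta0, beta1, se1


def nb_wald_test(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    time_point: str,
    alpha: float = ALPHA,
    lfc_threshold: float = 1.0,
    detection_threshold: float = DETECTION_THRESHOLD,
    dispersions: pd.Series | None = None,
    batch: pd.Series | None = None,
) -> pd.DataFrame:
    """Cold-vs-control NB Wald test at one time point.

    Returns one row per feature with columns (feature, time, base_mean,
    log2fc, p, p_adj, status).  BH is applied within each ``batch`` group
    (one batch covering all features when not given).
    """
    sub = design[design["time"] == time_point]
    conditions = set(sub["condition"])
    if not {"control", "cold"} <= conditions:
        raise ValueError(
            f"time point {time_point!r} needs both control and cold samples"
        )
    samples = list(sub["sample"])
    y = counts[samples].to_numpy(dtype=float)
    x = (sub["condition"] == "cold").to_numpy(dtype=float)

    sf = size_factors(counts[samples])
    offset = np.log(sf.to_numpy())
    normalized = counts[samples] / sf
    base_mean = normalized.mean(axis=1).to_numpy()

    if dispersions is None:
        disp = estimate_dispersion(normalized, sub.set_index("sample")["condition"])
    else:
        disp = dispersions.reindex(counts.index)
        if disp.isna().any():
            raise ValueError("supplied dispersions missing some features")
    beta0, beta1, se1 = _irls_nb(y, x, offset, disp.to_numpy())

    all_zero = (y.sum(axis=1) == 0)
    zero_group = ((normalized.to_numpy()[:, x == 0].sum(axis=1) == 0)
                  | (normalized.to_numpy()[:, x == 1].sum(axis=1) == 0))

    log2fc = beta1 / LN2
    # raw estimate with a +0.5 pseudo-mean floor when one group is all zero
    if zero_group.any():
        m_ctrl = normalized.to_numpy()[:, x == 0].mean(axis=1)
        m_cold = normalized.to_numpy()[:, x == 1].mean(axis=1)
        pseudo = np.log2(m_cold + 0.5) - np.log2(m_ctrl + 0.5)
        log2fc = np.where(zero_group, pseudo, log2fc)

    with np.errstate(invalid="ignore", divide="ignore"):
        z = beta1 / se1
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[all_zero] = 1.0
    log2fc = np.where(all_zero, 0.0, log2fc)
    failed = ~np.isfinite(p)
    if failed.any():
        logger.warning("%d feature(s) failed to converge; p set to NA", failed.sum())

    result = pd.DataFrame(
        {
            "feature": counts.index,
            "time": time_point,
            "base_mean": base_mean,
            "log2fc": log2fc,
            "p": p,
        }
    )
    if batch is None:
        result["p_adj"] = bh_adjust(result["p"].to_numpy())
    else:
        result["p_adj"] = np.nan
        batches = batch.reindex(counts.index).fillna("__default__")
        for _name, group_idx in result.groupby(batches.to_numpy()).groups.items():
            result.loc[group_idx, "p_adj"] = bh_adjust(
                result.loc[group_idx, "p"].to_numpy())

    status = np.full(len(result), "unchanged", dtype=object)
    sig = (result["p_adj"] <= alpha).fillna(False).to_numpy()
    detected = base_mean >= detection_threshold
    status[detected & sig & (result["log2fc"].to_numpy() >= lfc_threshold)] = "up"
    status[detected & sig & (result["log2fc"].to_numpy() <= -lfc_threshold)] = "down"
    status[~detected] = "undetected"
    result["status"] = status
    return result


def run_de(counts: pd.DataFrame, design: pd.DataFrame,
           batch: pd.Series | None = None, **kwargs) -> pd.DataFrame:
    """Convenience wrapper: NB Wald test at every time point in the design."""
    frames = [
        nb_wald_test(counts, design, tp, batch=batch, **kwargs)
        for tp in design["time"].unique()
    ]
    return pd.concat(frames, ignore_index=True)
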