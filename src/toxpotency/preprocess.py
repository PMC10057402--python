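"""Normalization and per-gene differential-expression statistics.

Two-channel intensities are normalized by subtracting a LOWESS trend of
M = log2(R/G) against A = (log2 R + log2 G)/2 per array. Treatment
effects are tested per gene with an F statistic, or the variance-
shrunken Fs variant, with p-values from residual-shuffling permutations;
BH-FDR adjustment and least-square-mean fold changes complete the DEG
table (|FC| >= 1.5 and q <= 0.05 by default, both thresholds inclusive).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import polygamma
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix


def lowess_normalize(
    red: pd.DataFrame, green: pd.DataFrame, span: float = 0.4
) -> pd.DataFrame:
    """Per-array LOWESS normalization of two-channel intensities.

    Returns the matrix of normalized log ratios M = log2(R/G) with the
    fitted trend against A = (log2 R + log2 G)/2 removed.
    """
    if red.shape != green.shape:
        raise ValueError("red and green channels must have the same shape")
    bad = (np.asarray(red) <= 0) | (np.asarray(green) <= 0)
    if bad.any():
        rows, cols = np.nonzero(bad)
        cells = [(red.index[r], red.columns[c]) for r, c in zip(rows[:10], cols[:10])]
        raise ValueError(f"non-positive intensities at cells {cells}")
    r = np.log2(np.asarray(red, float))
    g = np.log2(np.asarray(green, float))
    m = r - g
    a = (r + g) / 2.0
    out = np.empty_like(m)
    for j in range(m.shape[1]):
        fit = sm_lowess(m[:, j], a[:, j], frac=span, return_sorted=False)
        out[:, j] = m[:, j] - fit
    return pd.DataFrame(out, index=red.index, columns=red.columns)


def _group_stats(values: np.ndarray, codes: np.ndarray, k: int):
    """Per-gene between/within sums of squares for a one-way layout.

    values: genes x samples; codes: group index per sample.
    """
    n = values.shape[1]
    counts = np.bincount(codes, minlength=k).astype(float)
    gsum = np.zeros((values.shape[0], k))
    for j in range(k):
        gsum[:, j] = values[:, codes == j].sum(axis=1)
    gmean = gsum / counts
    grand = values.mean(axis=1)
    ss_between = ((gmean - grand[:, None]) ** 2 * counts).sum(axis=1)
    ss_total = ((values - grand[:, None]) ** 2).sum(axis=1)
    ss_within = np.maximum(ss_total - ss_between, 0.0)
    return ss_between / (k - 1), ss_within / (n - k), gmean


def _shrink_mse(ms_within: np.ndarray, df: int) -> np.ndarray:
    """James-Stein shrinkage of per-gene log variances toward their
    across-gene mean, with the weight set by the method of moments:
    the sampling variance of log(s^2) is trigamma(df/2), so the excess
    spread estimates the true between-gene variance."""
    logv = np.log(np.where(ms_within > 0, ms_within, np.nan))
    center = np.nanmean(logv)
    samp_var = float(polygamma(1, df / 2.0))
    obs_var = np.nanvar(logv)
    between = max(obs_var - samp_var, 0.0)
    w = samp_var / (samp_var + between) if (samp_var + between) > 0 else 1.0
    shrunk = np.exp(center + (1.0 - w) * (np.nan_to_num(logv, nan=center) - center))
    return shrunk


def _f_stats(
    values: np.ndarray, codes: np.ndarray, k: int, statistic: str
) -> tuple[np.ndarray, np.ndarray]:
    ms_between, ms_within, _ = _group_stats(values, codes, k)
    degenerate = ms_within <= 0
    if statistic == "F":
        denom = np.where(degenerate, np.nan, ms_within)
    elif statistic == "Fs":
        denom = _shrink_mse(ms_within, values.shape[1] - k)
        degenerate = denom <= 0
    else:
        raise ValueError(f"unknown statistic: {statistic!r}")
    stat = np.where(degenerate, np.nan, ms_between / denom)
    return stat, degenerate


def gene_anova(
    em: ExpressionMatrix,
    groups: Sequence,
    statistic: str = "Fs",
    nperm: int = 30000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene one-way treatment-effect test with permutation p-values.

    ``groups`` assigns each sample (column) to a group. Null statistics
    are generated by residual shuffling: residuals from the full
    (group-means) model are permuted across samples — the same
    permutation for every gene — and added back to the grand mean.
    p = (1 + #{null >= observed}) / (1 + nperm).

    Genes with zero within-group variance under ``statistic="F"`` are
    flagged degenerate and reported with p = 1.
    """
    values = em.values.to_numpy(float)
    labels, codes = np.unique(np.asarray(groups), return_inverse=True)
    k = len(labels)
    if k < 2:
        raise ValueError("need >= 2 groups")
    if np.bincount(codes).min() < 2:
        raise ValueError("need >= 2 samples per group")

    stat, degenerate = _f_stats(values, codes, k, statistic)

    gmean = np.zeros((values.shape[0], k))
    for j in range(k):
        gmean[:, j] = values[:, codes == j].mean(axis=1)
    residuals = values - gmean[:, codes]
    grand = values.mean(axis=1, keepdims=True)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(values.shape[0])
    obs = np.nan_to_num(stat, nan=np.inf)  # degenerate genes collect no exceedances
    for _ in range(nperm):
        perm = rng.permutation(values.shape[1])
        null_stat, _ = _f_stats(grand + residuals[:, perm], codes, k, statistic)
        exceed += np.nan_to_num(null_stat, nan=0.0) >= obs
    p = (1.0 + exceed) / (1.0 + nperm)
    p[degenerate] = 1.0
    return pd.DataFrame(
        {"stat": stat, "p": p, "degenerate": degenerate}, index=em.values.index
    )


def adjust_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, clipped to [0, 1]."""
    p = np.asarray(pvals, float)
    if np.isnan(p).any():
        raise ValueError("NaN p-values")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def signed_fold_change(log2_diff: np.ndarray) -> np.ndarray:
    """Linear fold change with the symmetric +/- convention: 2^d for
    d >= 0, -2^(-d) for d < 0 (so a halving is reported as -2.0)."""
    d = np.asarray(log2_diff, float)
    with np.errstate(over="ignore"):  # huge planted effects overflow to inf
        mag = np.power(2.0, np.abs(d))
    return np.where(d >= 0, mag, -mag)


def lsmeans_fold_change(
    em: ExpressionMatrix, groups: Sequence, control_label
) -> pd.DataFrame:
    """Per-gene signed linear fold change of each group vs control,
    based on least-square means (= unweighted cell means in the one-way
    layout, so unbalanced replication does not bias the contrast)."""
    garr = np.asarray(groups)
    labels = [g for g in pd.unique(garr) if g != control_label]
    if control_label not in garr:
        raise ValueError(f"control group {control_label!r} not present")
    values = em.values.to_numpy(float)
    cmean = values[:, garr == control_label].mean(axis=1)
    out = {}
    for g in labels:
        diff = values[:, garr == g].mean(axis=1) - cmean
        out[g] = signed_fold_change(diff)
    return pd.DataFrame(out, index=em.values.index)


def call_degs(
    stats: pd.DataFrame,
    fold_change: pd.Series,
    fc_thresh: float = 1.5,
    fdr_thresh: float = 0.05,
) -> pd.DataFrame:
    """Assemble the DEG table for one contrast.

    ``stats`` carries per-gene ``stat`` and ``p`` (plus optional ``q``;
    computed here if absent); ``fold_change`` is the signed linear FC of
    the contrast. A gene is a DEG iff q <= fdr_thresh and
    |FC| >= fc_thresh — both thresholds inclusive.
    """
    if not stats.index.equals(fold_change.index):
        if set(stats.index) != set(fold_change.index):
            raise ValueError("stats and fold-change tables cover different gene universes")
        fold_change = fold_change.loc[stats.index]
    q = stats["q"].to_numpy() if "q" in stats else adjust_fdr(stats["p"].to_numpy())
    fc = fold_change.to_numpy(float)
    is_deg = (q <= fdr_thresh) & (np.abs(fc) >= fc_thresh)
    return pd.DataFrame(
        {
            "stat": stats["stat"],
            "p": stats["p"],
            "q": q,
            "fold_change": fc,
            "direction": np.sign(fc).astype(int),
            "is_deg": is_deg,
        },
        index=stats.index,
    )


def differential_expression(
    em: ExpressionMatrix,
    exposure: str,
    statistic: str = "Fs",
    nperm: int = 30000,
    seed: int = 0,
    fc_thresh: float = 1.5,
    fdr_thresh: float = 0.05,
) -> dict[float, pd.DataFrame]:
    """DEG tables for one exposure: omnibus dose-effect test (q shared
    across doses) combined with per-dose fold changes vs the vehicle
    control. Returns {dose: DEG table}."""
    sub = em.subset_exposure(exposure)
    doses = sub.doses()
    if (doses == 0).sum() == 0:
        raise ValueError(f"exposure {exposure!r} has no vehicle control samples")
    anova = gene_anova(sub, doses, statistic=statistic, nperm=nperm, seed=seed)
    anova = anova.assign(q=adjust_fdr(anova["p"].to_numpy()))
    fc = lsmeans_fold_change(sub, doses, 0.0)
    return {
        dose: call_degs(anova, fc[dose], fc_thresh=fc_thresh, fdr_thresh=fdr_thresh)
        for dose in fc.columns
    }
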