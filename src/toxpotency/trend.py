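"""Williams-type trend test and dose-responsive gene prefilter.

The statistic compares the isotonic (pooled-adjacent-violators)
estimate of the highest-dose group mean against the observed control
mean, standardized by the pooled within-group variance:

    t = (mu_iso_k - ybar_0) / sqrt(s^2 (1/n_k + 1/n_0))

Significance comes from permuting sample-to-dose labels rather than
Williams' tabulated critical values. Genes pass the prefilter when the
permutation p-value and the largest |fold change vs control| across
doses clear their cutoffs (defaults p <= 0.05, |FC| >= 1.5; the
permissive p <= 0.5 used by some benchmark-dose workflows is available
via the cutoff argument).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix
from .preprocess import signed_fold_change


def pava(
    values: Sequence[float],
    weights: Sequence[float] | None = None,
    increasing: bool = True,
) -> np.ndarray:
    """Weighted least-squares monotone fit by pooled adjacent violators.

    Returns the non-decreasing (or non-increasing) vector minimizing the
    weighted SSE to ``values``; preserves the weighted mean.
    """
    y = np.asarray(values, float)
    if y.ndim != 1 or y.size == 0:
        raise ValueError("values must be a non-empty 1-D sequence")
    w = np.ones_like(y) if weights is None else np.asarray(weights, float)
    if w.shape != y.shape or (w <= 0).any():
        raise ValueError("weights must be positive and match values")
    if not increasing:
        return -pava(-y, w, increasing=True)
    # blocks of (mean, weight, count), pooled while order is violated
    means, wts, counts = [], [], []
    for yi, wi in zip(y, w):
        means.append(yi)
        wts.append(wi)
        counts.append(1)
        while len(means) > 1 and means[-2] > means[-1]:
            m2, w2, c2 = means.pop(), wts.pop(), counts.pop()
            m1, w1, c1 = means.pop(), wts.pop(), counts.pop()
            wt = w1 + w2
            means.append((m1 * w1 + m2 * w2) / wt)
            wts.append(wt)
            counts.append(c1 + c2)
    return np.repeat(means, counts)


@lru_cache(maxsize=32)
def _partitions(k: int) -> list[tuple[tuple[int, int], ...]]:
    """All contiguous partitions of positions 0..k-1 into blocks."""
    if k > 12:
        raise ValueError("partition enumeration limited to <= 12 dose groups")
    out = []
    for mask in range(1 << (k - 1)):
        blocks, start = [], 0
        for i in range(k - 1):
            if mask >> i & 1:
                blocks.append((start, i + 1))
                start = i + 1
        blocks.append((start, k))
        out.append(tuple(blocks))
    return out


def _iso_last(means: np.ndarray, weights: np.ndarray, increasing: bool) -> np.ndarray:
    """Isotonic fitted value at the last (highest-dose) position, for
    many rows at once.

    The isotonic solution is piecewise constant on a contiguous
    partition with pooled block means; enumerating the 2^(k-1)
    partitions and keeping the monotone-feasible one with least
    weighted SSE is exact for the small k of a dose design.
    """
    if not increasing:
        return -_iso_last(-means, weights, True)
    k = means.shape[1]
    best_sse = np.full(means.shape[0], np.inf)
    best_last = np.empty(means.shape[0])
    for blocks in _partitions(k):
        fitted = np.empty_like(means)
        prev = None
        feasible = np.ones(means.shape[0], bool)
        for lo, hi in blocks:
            wblock = weights[lo:hi]
            bm = means[:, lo:hi] @ wblock / wblock.sum()
            fitted[:, lo:hi] = bm[:, None]
            if prev is not None:
                feasible &= bm >= prev - 1e-12
            prev = bm
        sse = ((fitted - means) ** 2 * weights).sum(axis=1)
        better = feasible & (sse < best_sse)
        best_sse[better] = sse[better]
        best_last[better] = fitted[better, -1]
    return best_last


def _williams_stats(
    values: np.ndarray, codes: np.ndarray, counts: np.ndarray, direction: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-row Williams statistic and the winning direction (+1 up/-1 down).

    values: rows x samples, codes: dose-group index per sample (0 =
    control, ascending dose), counts: samples per group.
    """
    k = len(counts)
    n = values.shape[1]
    gmean = np.empty((values.shape[0], k))
    for j in range(k):
        gmean[:, j] = values[:, codes == j].mean(axis=1)
    ss_within = ((values - gmean[:, codes]) ** 2).sum(axis=1)
    s2 = ss_within / (n - k)
    se = np.sqrt(s2 * (1.0 / counts[-1] + 1.0 / counts[0]))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_up = (_iso_last(gmean, counts.astype(float), True) - gmean[:, 0]) / se
        t_dn = (gmean[:, 0] - _iso_last(gmean, counts.astype(float), False)) / se
    if direction == "up":
        return t_up, np.ones(values.shape[0], int)
    if direction == "down":
        return t_dn, -np.ones(values.shape[0], int)
    if direction != "auto":
        raise ValueError(f"unknown direction: {direction!r}")
    up_wins = t_up >= t_dn
    return np.where(up_wins, t_up, t_dn), np.where(up_wins, 1, -1)


@dataclass
class TrendResult:
    statistic: float
    direction: int  # +1 up, -1 down
    p: float
    max_fc: float  # signed linear fold change, largest |.| across doses
    degenerate: bool


def williams_test(
    groups: Sequence[Sequence[float]],
    direction: str = "auto",
    nperm: int = 1000,
    seed: int = 0,
) -> TrendResult:
    """Trend test for one gene; ``groups`` ordered by dose, control first.

    ``direction="auto"`` evaluates both orientations and keeps the
    larger statistic; the permutation null applies the same rule. Zero
    pooled variance yields a degenerate flag with p = 1.
    """
    if len(groups) < 3:
        raise ValueError("need a control plus >= 2 dose groups")
    arrs = [np.asarray(g, float) for g in groups]
    values = np.concatenate(arrs)[None, :]
    codes = np.concatenate([np.full(len(a), j) for j, a in enumerate(arrs)])
    counts = np.array([len(a) for a in arrs])
    stat, sgn = _williams_stats(values, codes, counts, direction)
    means = np.array([a.mean() for a in arrs])
    deltas = means[1:] - means[0]
    max_fc = float(signed_fold_change(deltas[np.argmax(np.abs(deltas))]))
    if not np.isfinite(stat[0]):
        return TrendResult(0.0, int(sgn[0]), 1.0, max_fc, True)
    rng = np.random.default_rng(seed)
    exceed = 0
    flat = values[0]
    for _ in range(nperm):
        null, _ = _williams_stats(flat[rng.permutation(flat.size)][None, :], codes, counts, direction)
        exceed += bool(np.nan_to_num(null[0]) >= stat[0])
    p = (1.0 + exceed) / (1.0 + nperm)
    return TrendResult(float(stat[0]), int(sgn[0]), p, max_fc, False)


def williams_scan(
    em: ExpressionMatrix,
    direction: str = "auto",
    nperm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Vectorized Williams trend scan over all genes of one exposure's
    matrix (columns spanning the control and dose groups).

    Permutations reshuffle the sample-to-dose assignment, identically
    for every gene. Returns per-gene statistic, direction, p, max_fc
    and degenerate flag.
    """
    doses = em.doses()
    levels = np.unique(doses)
    if levels[0] != 0:
        raise ValueError("control group (dose 0) required")
    if len(levels) < 3:
        raise ValueError("need >= 2 non-zero dose groups")
    codes = np.searchsorted(levels, doses)
    counts = np.bincount(codes)
    values = em.values.to_numpy(float)

    stat, sgn = _williams_stats(values, codes, counts, direction)
    degenerate = ~np.isfinite(stat)
    obs = np.where(degenerate, np.inf, stat)

    gmean = np.empty((values.shape[0], len(levels)))
    for j in range(len(levels)):
        gmean[:, j] = values[:, codes == j].mean(axis=1)
    deltas = gmean[:, 1:] - gmean[:, [0]]
    pick = np.argmax(np.abs(deltas), axis=1)
    max_fc = signed_fold_change(deltas[np.arange(len(deltas)), pick])

    rng = np.random.default_rng(seed)
    exceed = np.zeros(values.shape[0])
    for _ in range(nperm):
        perm = rng.permutation(values.shape[1])
        null, _ = _williams_stats(values[:, perm], codes, counts, direction)
        exceed += np.nan_to_num(null, nan=0.0) >= obs
    p = (1.0 + exceed) / (1.0 + nperm)
    p[degenerate] = 1.0
    return pd.DataFrame(
        {
            "statistic": np.where(degenerate, 0.0, stat),
            "direction": sgn,
            "p": p,
            "max_fc": max_fc,
            "degenerate": degenerate,
        },
        index=em.values.index,
    )


def prefilter(
    trend: pd.DataFrame, p_cutoff: float = 0.05, fc_cutoff: float = 1.5
) -> pd.DataFrame:
    """Apply the trend-test and fold-change cutoffs; adds a ``pass``
    column and returns the table (passing genes = table[table['pass']])."""
    out = trend.copy()
    out["pass"] = (out["p"] <= p_cutoff) & (out["max_fc"].abs() >= fc_cutoff)
    return out


def passing_genes(trend: pd.DataFrame, p_cutoff: float = 0.05, fc_cutoff: float = 1.5) -> list:
    table = prefilter(trend, p_cutoff, fc_cutoff)
    return table.index[table["pass"]].tolist()
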