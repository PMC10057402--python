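"""Group-comparison statistics for the bioassay endpoints (BALF
neutrophil counts, comet % tail DNA).

Nonparametric route: tie-corrected Kruskal-Wallis followed by Dunn's
many-to-one post hoc (Bonferroni family adjustment). Parametric route:
one-way ANOVA with Dunnett's many-to-one comparisons (multivariate-t
family-wise p-values). A Shapiro-Wilk normality screen picks the route
when none is forced; both are always computable explicitly.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


def _rank_all(groups: list[np.ndarray]) -> tuple[np.ndarray, list[np.ndarray], float]:
    """Pooled midranks per group plus the tie-correction term
    sum(t^3 - t) over tied value multiplicities."""
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    out, i = [], 0
    for g in groups:
        out.append(ranks[i : i + len(g)])
        i += len(g)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    return ranks, out, tie_term


def kruskal_wallis(groups: Sequence[Sequence[float]], exact: bool = False) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its p-value.

    p from chi-square(k-1) by default; ``exact=True`` enumerates every
    assignment of the pooled observations to the group sizes (small n
    only). All-identical data yields H = 0, p = 1.
    """
    arrs = [np.asarray(g, float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need >= 2 groups")
    pooled = np.concatenate(arrs)
    if len(pooled) < 2:
        raise ValueError("need >= 2 observations")
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*arrs)
    if not exact:
        return float(h), float(p)
    sizes = [len(a) for a in arrs]
    n = len(pooled)
    if n > 10:
        raise ValueError("exact enumeration limited to n <= 10")
    count = 0
    total = 0
    idx_all = set(range(n))

    def recurse(remaining: set, gi: int, chosen: list):
        nonlocal count, total
        if gi == len(sizes) - 1:
            groups_now = chosen + [sorted(remaining)]
            hh = _h_from_index_groups(pooled, groups_now)
            total += 1
            count += hh >= h - 1e-12
            return
        for comb in combinations(sorted(remaining), sizes[gi]):
            recurse(remaining - set(comb), gi + 1, chosen + [list(comb)])

    recurse(idx_all, 0, [])
    return float(h), count / total


def _h_from_index_groups(pooled: np.ndarray, index_groups: list[list[int]]) -> float:
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    h = 0.0
    for idx in index_groups:
        r = ranks[idx]
        h += len(idx) * (r.mean() - (n + 1) / 2.0) ** 2
    h *= 12.0 / (n * (n + 1))
    return h / tie if tie > 0 else 0.0


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    control_index: int = 0,
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """Dunn's many-to-one comparisons against the control group.

    z uses pooled midrank means with the tie-corrected standard error
    sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_0)); two-sided p,
    Bonferroni-adjusted over the k-1 comparisons by default.
    """
    arrs = [np.asarray(g, float) for g in groups]
    if any(len(a) == 0 for a in arrs):
        raise ValueError("empty group")
    n = sum(len(a) for a in arrs)
    _, rank_groups, tie_term = _rank_all(arrs)
    var_base = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))
    r0 = rank_groups[control_index].mean()
    n0 = len(arrs[control_index])
    rows = []
    m = len(arrs) - 1
    for i, rg in enumerate(rank_groups):
        if i == control_index:
            continue
        se = np.sqrt(var_base * (1.0 / len(arrs[i]) + 1.0 / n0))
        z = (rg.mean() - r0) / se if se > 0 else 0.0
        p_raw = 2.0 * stats.norm.sf(abs(z))
        if adjust == "bonferroni":
            p_adj = min(1.0, p_raw * m)
        elif adjust == "none":
            p_adj = p_raw
        else:
            raise ValueError(f"unknown adjustment: {adjust!r}")
        rows.append({"group": i, "z": float(z), "p_raw": float(p_raw), "p_adj": float(p_adj)})
    return pd.DataFrame(rows).set_index("group")


def anova_dunnett(
    groups: Sequence[Sequence[float]], control_index: int = 0, seed: int = 0
) -> pd.DataFrame:
    """One-way ANOVA followed by Dunnett's many-to-one t comparisons.

    Family-wise p-values integrate the multivariate t distribution
    (Monte-Carlo quadrature, seeded). Zero residual variance is an
    error.
    """
    arrs = [np.asarray(g, float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need >= 2 groups")
    resid = np.concatenate([a - a.mean() for a in arrs])
    if np.allclose(resid, 0):
        raise ValueError("zero residual variance")
    control = arrs[control_index]
    treats = [a for i, a in enumerate(arrs) if i != control_index]
    res = stats.dunnett(*treats, control=control, random_state=np.random.default_rng(seed))
    rows = []
    for i, (t, p) in enumerate(zip(np.atleast_1d(res.statistic), np.atleast_1d(res.pvalue))):
        rows.append({"comparison": i, "t": float(t), "p_adj": float(p)})
    return pd.DataFrame(rows).set_index("comparison")


def significance_stars(p: float) -> str:
    """Figure-legend convention: * 0.05, ** 0.01, *** 0.001, **** 0.0001."""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 5e-2)):
        if p <= cut:
            return stars
    return ""


def normality_screen(groups: Sequence[Sequence[float]], alpha: float = 0.05) -> str:
    """Shapiro-Wilk on pooled residuals: returns ``anova_dunnett`` when
    normality is not rejected, else ``kruskal_dunn``."""
    resid = np.concatenate([np.asarray(g, float) - np.mean(g) for g in groups])
    if np.ptp(resid) == 0 or len(resid) < 3:
        return "kruskal_dunn"
    _, p = stats.shapiro(resid)
    return "anova_dunnett" if p >= alpha else "kruskal_dunn"


def bioassay_summary(table: pd.DataFrame, endpoint: str) -> pd.DataFrame:
    """Median and interquartile range per exposure and dose, mirroring
    the figure layout of the bioassay panels."""
    g = table.groupby(["exposure", "dose"])[endpoint]
    out = g.agg(
        median="median",
        q1=lambda x: float(np.percentile(x, 25)),
        q3=lambda x: float(np.percentile(x, 75)),
        n="count",
    )
    return out.reset_index()


def bioassay_tests(
    table: pd.DataFrame,
    endpoint: str,
    method: str = "auto",
    seed: int = 0,
) -> pd.DataFrame:
    """Per-exposure many-to-one comparisons of each dose vs control.

    ``method``: ``kruskal_dunn``, ``anova_dunnett`` or ``auto``
    (normality screen). Output rows carry the omnibus p, per-dose
    adjusted p and significance stars.
    """
    rows = []
    for exposure, sub in table.groupby("exposure"):
        doses = sorted(sub["dose"].unique())
        groups = [sub.loc[sub["dose"] == d, endpoint].to_numpy(float) for d in doses]
        chosen = normality_screen(groups) if method == "auto" else method
        if chosen == "kruskal_dunn":
            h, omnibus = kruskal_wallis(groups)
            post = dunn_posthoc(groups, control_index=0)
            padj = post["p_adj"].to_numpy()
            stat = post["z"].to_numpy()
        elif chosen == "anova_dunnett":
            omnibus = float(stats.f_oneway(*groups).pvalue)
            post = anova_dunnett(groups, control_index=0, seed=seed)
            padj = post["p_adj"].to_numpy()
            stat = post["t"].to_numpy()
        else:
            raise ValueError(f"unknown method: {chosen!r}")
        for dose, s, p in zip(doses[1:], stat, padj):
            rows.append(
                {
                    "exposure": exposure,
                    "dose": dose,
                    "endpoint": endpoint,
                    "method": chosen,
                    "omnibus_p": omnibus,
                    "statistic": s,
                    "p_adj": p,
                    "stars": significance_stars(p),
                }
            )
    return pd.DataFrame(rows)
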