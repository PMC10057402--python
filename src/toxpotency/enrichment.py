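"""Gene-set level analysis: GSEA ES/NES, hypergeometric
over-representation, activation z-scores and the deposited-surface-area
correlation.

The enrichment score is the signed extremum of the weighted
Kolmogorov-Smirnov running sum over a ranked gene list (hit increments
proportional to |score|, miss decrements 1/(N - Nh)). NES divides the
ES by the mean |ES| of sign-matched gene-label permutations; set-level
p-values come from the matching-sign null tail with +1 smoothing and
are BH-adjusted across sets.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GeneSetCollection
from .preprocess import adjust_fdr


def rank_genes(degstats: pd.DataFrame, metric: str = "signed_stat") -> pd.Series:
    """Ranked gene scores (descending) for GSEA.

    Metrics: ``signed_stat`` = direction x |statistic| (default),
    ``signed_logp`` = direction x -log10 p, ``log2_fc`` = signed log2
    fold change. Ties break deterministically by gene ID.
    """
    needed = {"signed_stat": ("stat", "direction"), "signed_logp": ("p", "direction"), "log2_fc": ("fold_change",)}
    if metric not in needed:
        raise ValueError(f"unknown metric: {metric!r}")
    missing = [c for c in needed[metric] if c not in degstats.columns]
    if missing:
        raise ValueError(f"DEG table missing columns: {missing}")
    if metric == "signed_stat":
        score = np.sign(degstats["direction"]) * degstats["stat"].abs()
    elif metric == "signed_logp":
        p = degstats["p"].clip(lower=1e-300)
        score = np.sign(degstats["direction"]) * (-np.log10(p))
    else:
        fc = degstats["fold_change"].to_numpy(float)
        score = pd.Series(np.where(fc >= 0, np.log2(np.abs(fc)), -np.log2(np.abs(fc))), index=degstats.index)
    if score.isna().any():
        raise ValueError("missing statistics for some genes")
    # mergesort is stable; pre-sorting by gene ID makes ties deterministic
    return score.loc[sorted(score.index)].sort_values(ascending=False, kind="mergesort")


def _hit_mask(ranked_genes: pd.Index, gene_set: Sequence[str]) -> np.ndarray:
    members = set(gene_set)
    return np.fromiter((g in members for g in ranked_genes), bool, len(ranked_genes))


def _running_sum(scores: np.ndarray, hits: np.ndarray, weight: float = 1.0) -> np.ndarray:
    nh = int(hits.sum())
    n = len(scores)
    if nh == 0 or nh == n:
        raise ValueError("gene set must be a proper non-empty subset of the universe")
    w = np.abs(scores) ** weight
    inc = np.where(hits, w, 0.0)
    tot = inc.sum()
    if tot <= 0:  # all member scores zero: fall back to equal hit weights
        inc = hits.astype(float)
        tot = inc.sum()
    steps = inc / tot - (~hits) / (n - nh)
    return np.cumsum(steps)


def gsea_es(
    ranked: pd.Series, gene_set: Sequence[str], weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Enrichment score of one set against a ranked score Series
    (descending). Returns (ES, running sum)."""
    scores = ranked.to_numpy(float)
    hits = _hit_mask(ranked.index, gene_set)
    rs = _running_sum(scores, hits, weight)
    i = int(np.argmax(np.abs(rs)))
    return float(rs[i]), rs


def _es_batch(scores: np.ndarray, idx: np.ndarray, weight: float = 1.0) -> np.ndarray:
    """ES for many same-size gene sets given by row index matrices.

    The running sum only changes slope at hit positions, so its
    extremum is attained immediately at or just before a hit; both
    candidate values are evaluated per hit, vectorized across sets.
    """
    m = idx.shape[1]
    n = len(scores)
    pos = np.sort(idx, axis=1)
    w = np.abs(scores) ** weight
    hit_w = w[pos]
    tot = hit_w.sum(axis=1, keepdims=True)
    zero = (tot[:, 0] <= 0)
    if zero.any():
        hit_w[zero] = 1.0
        tot[zero] = m
    cum_hit = np.cumsum(hit_w, axis=1) / tot
    j = np.arange(1, m + 1)
    miss_after = (pos + 1 - j) / (n - m)  # misses seen once the j-th hit is included
    miss_before = (pos - (j - 1)) / (n - m)
    after = cum_hit - miss_after
    before = np.concatenate([np.zeros((len(pos), 1)), cum_hit[:, :-1]], axis=1) - miss_before
    cand = np.concatenate([after, before], axis=1)
    i = np.argmax(np.abs(cand), axis=1)
    return cand[np.arange(len(cand)), i]


def gsea_nes(
    ranked: pd.Series,
    sets: GeneSetCollection | Mapping[str, Sequence[str]],
    nperm: int = 1000,
    seed: int = 0,
    min_size: int = 3,
    weight: float = 1.0,
) -> pd.DataFrame:
    """GSEA with gene-label permutation null, per set.

    NES = ES / mean(|null ES| of matching sign); p is the matching-sign
    tail with +1 smoothing, BH-adjusted across sets. Sets smaller than
    ``min_size`` (after intersection with the universe) are skipped.
    """
    if nperm < 100:
        raise ValueError("nperm must be >= 100")
    items = sets.items() if hasattr(sets, "items") else sets
    scores = ranked.to_numpy(float)
    universe = ranked.index
    rng = np.random.default_rng(seed)
    rows = []
    null_cache: dict[int, np.ndarray] = {}
    for name, genes in items:
        present = [g for g in genes if g in universe]
        m = len(present)
        if m < min_size or m >= len(universe):
            continue
        es, rs = gsea_es(ranked, present, weight)
        if m not in null_cache:
            idx = np.argsort(rng.random((nperm, len(universe))), axis=1)[:, :m]
            null_cache[m] = _es_batch(scores, idx, weight)
        null = null_cache[m]
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        denom = np.abs(same).mean() if len(same) else np.nan
        nes = es / denom if denom and np.isfinite(denom) else 0.0
        p = (1.0 + (np.abs(same) >= abs(es)).sum()) / (1.0 + len(same))
        # leading edge: members at or before (after, for negative ES) the extremum
        hits = _hit_mask(universe, present)
        i = int(np.argmax(np.abs(rs)))
        lead = universe[: i + 1][hits[: i + 1]] if es >= 0 else universe[i:][hits[i:]]
        rows.append(
            {
                "set": name,
                "size": m,
                "es": es,
                "nes": float(nes),
                "p": float(p),
                "leading_edge": ",".join(lead),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["padj"] = adjust_fdr(out["p"].to_numpy())
        out["significant"] = out["padj"] <= 0.05
    return out.set_index("set") if len(out) else out


def ora_fisher(
    degs: Sequence[str],
    universe: Sequence[str],
    gene_set: Sequence[str],
    neglogp_thresh: float = 1.3,
    min_overlap: int = 5,
) -> dict:
    """One-sided hypergeometric over-representation test.

    ``perturbed`` follows the printed convention: -log10 p >= 1.3
    (inclusive) AND overlap strictly greater than 5 DEGs.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    dset = set(degs)
    if not dset <= uni:
        raise ValueError("DEGs outside the universe")
    members = set(gene_set) & uni
    overlap = len(dset & members)
    p = float(stats.hypergeom.sf(overlap - 1, len(uni), len(members), len(dset)))
    p = min(p, 1.0)
    neglog = -np.log10(max(p, 1e-300))
    return {
        "overlap": overlap,
        "p": p,
        "neglog10p": float(neglog),
        "perturbed": bool(neglog >= neglogp_thresh and overlap > min_overlap),
    }


def activation_z(
    deg_directions: Mapping[str, int], set_directions: Mapping[str, int]
) -> dict:
    """IPA-style activation z-score over a set with expected directions.

    z = (concordant - discordant) / sqrt(overlap) over set genes present
    among the DEGs; z > 2 activated, z < -2 inhibited, no overlap ->
    no activity pattern (z undefined).
    """
    overlap = [g for g in set_directions if g in deg_directions]
    if not overlap:
        return {"z": None, "overlap": 0, "state": "no_activity_pattern"}
    conc = sum(1 for g in overlap if np.sign(deg_directions[g]) == np.sign(set_directions[g]))
    disc = len(overlap) - conc
    z = (conc - disc) / np.sqrt(len(overlap))
    state = "activated" if z > 2 else ("inhibited" if z < -2 else "no_call")
    return {"z": float(z), "overlap": len(overlap), "state": state}


def surface_area_correlation(
    values: pd.DataFrame,
    bet: Mapping[str, float],
    value_col: str = "value",
) -> tuple[float, float]:
    """Spearman correlation of a per-(exposure, dose) quantity with the
    total deposited surface area, BET (m^2/g) x instilled dose.

    ``values`` needs columns exposure, dose and ``value_col``; all
    exposure/dose combinations are pooled. Returns (rho, p) with
    midrank tie handling and the t-approximation p-value.
    """
    missing = sorted(set(values["exposure"]) - set(bet))
    if missing:
        raise ValueError(f"BET surface area missing for exposures: {missing}")
    x = values["exposure"].map(bet).to_numpy(float) * values["dose"].to_numpy(float)
    y = values[value_col].to_numpy(float)
    if len(x) < 3:
        raise ValueError("need >= 3 (exposure, dose) pairs")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
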