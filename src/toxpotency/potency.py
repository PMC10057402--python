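"""Exposure-level transcriptional potency estimators.

Three roll-ups of the per-gene BMDs of one exposure:

* NTP pathway approach — among gene sets with at least ``min_genes``
  BMD genes covering at least ``min_fraction`` of the set, the lowest
  median BMD;
* 25th ranked gene — the 25th smallest gene BMD;
* LCRD (lowest consistent response dose) — the smallest BMD not
  isolated from the body of ranked BMDs, by two published readings of
  the rule: (A) the lowest BMD after which every consecutive ratio
  BMD_(n+1)/BMD_(n) stays below 1.66, and (B) the lowest BMD of the
  earliest run of BMDs mutually within a quarter-log (10^0.25) of a
  neighbour. Both candidates are reported; the estimate is their
  minimum.

Lower potency values mean a more potent exposure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import GeneSetCollection


@dataclass
class PotencyEstimate:
    exposure_id: str
    method: str  # ntp_pathway | gene25 | lcrd
    potency: Optional[float]
    defined: bool
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.defined and not (self.potency and self.potency > 0):
            raise ValueError("defined potency must be positive")
        if self.defined and not self.evidence:
            raise ValueError("defined potency requires evidence")


def _sorted_bmds(bmds: Mapping[str, float]) -> list[tuple[str, float]]:
    return sorted(bmds.items(), key=lambda kv: (kv[1], kv[0]))


def ntp_pathway_potency(
    bmds: Mapping[str, float],
    sets: GeneSetCollection,
    exposure_id: str = "",
    min_genes: int = 3,
    min_fraction: float = 0.05,
) -> PotencyEstimate:
    """Lowest median BMD among qualifying gene sets.

    A set qualifies when it holds >= min_genes genes with a BMD and
    those genes make up >= min_fraction of the set (set size as given
    in the collection).
    """
    best_name, best_median, qualifying = None, np.inf, {}
    for name, genes in sets.items():
        hit = [bmds[g] for g in genes if g in bmds]
        if len(hit) >= min_genes and len(hit) / len(genes) >= min_fraction:
            med = float(np.median(hit))
            qualifying[name] = med
            if med < best_median or (med == best_median and (best_name is None or name < best_name)):
                best_name, best_median = name, med
    if best_name is None:
        return PotencyEstimate(exposure_id, "ntp_pathway", None, False)
    return PotencyEstimate(
        exposure_id,
        "ntp_pathway",
        best_median,
        True,
        evidence={"pathway": best_name, "median_bmd": best_median, "qualifying": qualifying},
    )


def gene25_potency(
    bmds: Mapping[str, float], exposure_id: str = "", rank: int = 25
) -> PotencyEstimate:
    """BMD of the 25th ranked (25th smallest) gene; undefined with
    fewer genes. Ties are broken by gene ID for determinism."""
    ranked = _sorted_bmds(bmds)
    if len(ranked) < rank:
        return PotencyEstimate(exposure_id, "gene25", None, False, {"n_genes": len(ranked)})
    gene, value = ranked[rank - 1]
    return PotencyEstimate(
        exposure_id, "gene25", float(value), True, evidence={"gene": gene, "rank": rank}
    )


def lcrd(
    bmds: Mapping[str, float],
    exposure_id: str = "",
    ratio_thresh: float = 1.66,
    quarter_log: float = 0.25,
    log_base: float = 10.0,
) -> PotencyEstimate:
    """Lowest consistent response dose.

    Candidate A: rank the BMDs ascending; the LCRD is the lowest BMD
    after which every consecutive ratio is < ratio_thresh (so a low
    outlier separated by a >= 1.66 jump is excluded).
    Candidate B: the lowest BMD of the earliest run of >= 2 consecutive
    BMDs in which each member lies within a factor
    ``log_base**quarter_log`` of a neighbouring member.
    The estimate is the minimum of the defined candidates.
    """
    ranked = _sorted_bmds(bmds)
    if not ranked:
        return PotencyEstimate(exposure_id, "lcrd", None, False)
    values = np.array([v for _, v in ranked], float)
    if (values <= 0).any():
        raise ValueError("BMDs must be positive")

    # candidate A: all subsequent consecutive ratios below the threshold
    ratios = values[1:] / values[:-1]
    start = 0
    big = np.nonzero(ratios >= ratio_thresh)[0]
    if len(big):
        start = int(big[-1]) + 1
    cand_a = float(values[start])

    # candidate B: earliest maximal consecutive run within a quarter log
    factor = log_base**quarter_log
    cand_b = None
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[j + 1] / values[j] <= factor:
            j += 1
        if j > i:  # run of >= 2 members
            cand_b = float(values[i])
            break
        i = j + 1
    if len(values) == 1:
        cand_a = float(values[0])

    candidates = {"ratio_rule": cand_a, "consistent_group": cand_b}
    defined = [v for v in candidates.values() if v is not None]
    est = min(defined)
    return PotencyEstimate(
        exposure_id, "lcrd", est, True, evidence={"candidates": candidates, "n_genes": len(values)}
    )


def rank_exposures(estimates: Sequence[PotencyEstimate]) -> pd.DataFrame:
    """Consolidated ranking table: ascending potency within each method
    (lower dose = more potent); undefined estimates rank last."""
    if not estimates:
        raise ValueError("no estimates supplied")
    df = pd.DataFrame(
        [
            {
                "exposure": e.exposure_id,
                "method": e.method,
                "potency": e.potency if e.defined else np.nan,
                "defined": e.defined,
            }
            for e in estimates
        ]
    )
    df["rank"] = (
        df.assign(_key=df["potency"].fillna(np.inf))
        .groupby("method")["_key"]
        .rank(method="min")
        .astype(int)
    )
    return df.sort_values(["method", "rank", "exposure"]).reset_index(drop=True)
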