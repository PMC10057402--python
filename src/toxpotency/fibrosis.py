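"""Pro-fibrotic signature classification.

Query conditions are described by their log2 fold changes over a fixed
signature gene panel (17 genes by default). The panel fold changes of a
labelled reference compendium and the queries are projected jointly
into a centered, unscaled PCA space; a Gaussian linear discriminant
(shared covariance, empirical class priors by default) fitted on the
reference scores yields a pro-fibrotic class probability per query.
Calls follow the strict thresholds: probability > 0.8 pro-fibrotic,
< 0.2 non-fibrotic, otherwise unknown.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PRO = "pro-fibrotic"
NON = "non-fibrotic"


def project_pca(
    compendium: pd.DataFrame, query: pd.DataFrame, n_components: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Joint PCA of reference and query fold-change rows.

    Centered, unscaled; component signs are fixed by making the loading
    of the first panel gene non-negative. Returns (reference scores,
    query scores).
    """
    missing = [g for g in compendium.columns if g not in query.columns]
    if missing:
        raise ValueError(f"query missing signature genes: {missing}")
    q = query[compendium.columns]
    x = np.vstack([compendium.to_numpy(float), q.to_numpy(float)])
    if n_components > min(x.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    centered = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    comps = vt[:n_components]
    flip = np.where(comps[:, 0] < 0, -1.0, 1.0)
    comps = comps * flip[:, None]
    scores = centered @ comps.T
    cols = [f"PC{i+1}" for i in range(n_components)]
    ref = pd.DataFrame(scores[: len(compendium)], index=compendium.index, columns=cols)
    qry = pd.DataFrame(scores[len(compendium):], index=q.index, columns=cols)
    return ref, qry


@dataclass
class DiscriminantModel:
    classes: tuple
    means: np.ndarray  # 2 x d
    cov: np.ndarray  # shared d x d
    priors: np.ndarray
    ridge: float = 0.0

    def posterior(self, scores: pd.DataFrame | np.ndarray) -> np.ndarray:
        """P(pro-fibrotic | score) per row."""
        x = np.asarray(scores, float)
        if x.ndim == 1:
            x = x[None, :]
        inv = np.linalg.inv(self.cov)
        logd = []
        for mu, prior in zip(self.means, self.priors):
            diff = x - mu
            logd.append(-0.5 * np.einsum("ij,jk,ik->i", diff, inv, diff) + np.log(prior))
        logd = np.column_stack(logd)
        logd -= logd.max(axis=1, keepdims=True)
        dens = np.exp(logd)
        post = dens / dens.sum(axis=1, keepdims=True)
        return post[:, list(self.classes).index(PRO)]


def fit_discriminant(
    scores: pd.DataFrame, labels: pd.Series, priors: str = "empirical"
) -> DiscriminantModel:
    """Gaussian linear discriminant on PC scores with pooled covariance.

    A singular pooled covariance is ridge-regularized (epsilon recorded
    on the model). ``priors`` is ``empirical`` or ``uniform``.
    """
    y = labels.loc[scores.index]
    classes = (PRO, NON)
    counts = np.array([(y == c).sum() for c in classes])
    if (counts < 2).any():
        raise ValueError("need >= 2 reference conditions per class")
    x = scores.to_numpy(float)
    means = np.vstack([x[(y == c).to_numpy()].mean(axis=0) for c in classes])
    d = x.shape[1]
    pooled = np.zeros((d, d))
    for c, mu in zip(classes, means):
        xc = x[(y == c).to_numpy()] - mu
        pooled += xc.T @ xc
    pooled /= len(x) - 2
    ridge = 0.0
    if not np.all(np.isfinite(pooled)) or np.linalg.cond(pooled) > 1e10:
        ridge = 1e-8 * max(np.trace(pooled) / d, 1.0)
        pooled = pooled + ridge * np.eye(d)
    if priors == "empirical":
        pr = counts / counts.sum()
    elif priors == "uniform":
        pr = np.full(2, 0.5)
    else:
        raise ValueError(f"unknown priors: {priors!r}")
    return DiscriminantModel(classes=classes, means=means, cov=pooled, priors=pr, ridge=ridge)


def classify(
    model: DiscriminantModel,
    query_scores: pd.DataFrame,
    hi: float = 0.8,
    lo: float = 0.2,
) -> pd.DataFrame:
    """Class calls per query condition.

    Strict thresholds as printed: probability > hi -> pro-fibrotic,
    < lo -> non-fibrotic, boundary values inclusive of neither ->
    unknown.
    """
    prob = model.posterior(query_scores)
    call = np.where(prob > hi, PRO, np.where(prob < lo, NON, "unknown"))
    return pd.DataFrame({"probability": prob, "call": call}, index=query_scores.index)


def classify_conditions(
    compendium: pd.DataFrame,
    labels: pd.Series,
    query_fc: pd.DataFrame,
    n_components: int = 2,
    priors: str = "empirical",
    hi: float = 0.8,
    lo: float = 0.2,
) -> pd.DataFrame:
    """End-to-end: joint PCA projection, discriminant fit on the
    reference scores, class calls (with PC scores) for the queries."""
    ref, qry = project_pca(compendium, query_fc, n_components=n_components)
    model = fit_discriminant(ref, labels, priors=priors)
    calls = classify(model, qry, hi=hi, lo=lo)
    return pd.concat([calls, qry], axis=1)
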