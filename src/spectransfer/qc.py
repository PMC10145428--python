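"""Multivariate outlier screening of the predictor matrix.

Plots whose NDRE1 statistics are jointly anomalous are flagged by the
local outlier factor (LOF) computed on PCA scores of the standardized
predictor matrix.  Distances are Mahalanobis in score space, which equals
Euclidean distance on variance-whitened scores.

The removal threshold on log LOF is the far-out Tukey fence (Q3 + 3 IQR)
with an absolute floor of log(2): log-LOF is right-skewed even on clean
Gaussian data (boundary points in the typically 1-3 effective score
dimensions have genuinely elevated density ratios), so the inner 1.5-IQR
fence flags several percent of perfectly clean plots, while a density
ratio below 2 is not outlying in any practical sense.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

DEFAULT_VARIANCE_TARGET = 0.95
MAX_COMPONENTS = 10
DEFAULT_MAX_REMOVAL_FRAC = 0.10
TUKEY_FENCE_MULTIPLIER = 3.0
LOF_FLOOR = 2.0


@dataclass
class OutlierReport:
    """Per-row LOF scores and keep/remove flags for one filtering pass."""

    lof: np.ndarray
    removed: np.ndarray  # boolean mask
    threshold: float     # on the log-LOF scale
    k_neighbors: int
    n_components: int

    @property
    def n_removed(self) -> int:
        return int(self.removed.sum())

    def to_frame(self, index=None) -> pd.DataFrame:
        return pd.DataFrame(
            {"lof": self.lof, "removed": self.removed}, index=index
        )


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"{int((~keep).sum())} constant column(s) dropped before PCA",
            stacklevel=3,
        )
    return (X[:, keep] - mu[keep]) / sd[keep]


def pca_scores(X, n_components: int | None = None) -> np.ndarray:
    """Scores of standardized ``X`` on its leading principal components.

    With ``n_components=None`` the smallest count explaining >= 95% of the
    variance is used, capped at 10.  Sign convention: within each component
    the loading of largest magnitude is positive.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    Z = _standardize(X)
    p = Z.shape[1]
    if n_components is not None and not 1 <= n_components < n:
        raise ValueError("need n rows > n_components >= 1")
    full = PCA(n_components=min(n - 1, p)).fit(Z)
    if n_components is None:
        cum = np.cumsum(full.explained_variance_ratio_)
        n_components = int(np.searchsorted(cum, DEFAULT_VARIANCE_TARGET) + 1)
        n_components = min(n_components, MAX_COMPONENTS, len(cum))
    comps = full.components_[:n_components].copy()
    # deterministic sign: largest-|loading| entry positive per component
    flip = comps[np.arange(n_components), np.abs(comps).argmax(axis=1)] < 0
    comps[flip] *= -1
    return Z @ comps.T


def lof_scores(scores, k_neighbors: int) -> np.ndarray:
    """Classic local outlier factor on a PCA score matrix.

    The reachability-distance formulation of Breunig et al.; neighborhoods
    include all points tied at the k-distance.  Distances are Euclidean on
    whitened scores (= Mahalanobis in score space); zero distances between
    duplicate points are floored at machine epsilon so the scores stay
    defined.
    """
    S = np.asarray(scores, dtype=float)
    if S.ndim == 1:
        S = S[:, None]
    n = S.shape[0]
    if not 2 <= k_neighbors < n:
        raise ValueError("need n rows > k_neighbors >= 2")
    sd = S.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    W = S / sd
    D = cdist(W, W)
    np.fill_diagonal(D, np.inf)
    D = np.maximum(D, np.finfo(float).eps)
    np.fill_diagonal(D, np.inf)

    k_dist = np.partition(D, k_neighbors - 1, axis=1)[:, k_neighbors - 1]
    # neighborhoods: everything within the k-distance (ties included)
    neigh = D <= k_dist[:, None]

    reach = np.maximum(D, k_dist[None, :])  # reach-dist_k(a, b) row a, col b
    with np.errstate(divide="ignore"):
        lrd = 1.0 / (np.sum(np.where(neigh, reach, 0.0), axis=1) / neigh.sum(axis=1))
    lof = np.array(
        [lrd[neigh[i]].mean() / lrd[i] for i in range(n)]
    )
    return lof


def default_k_neighbors(n: int) -> int:
    return max(2, min(20, n // 10))


def filter_outliers(
    X: pd.DataFrame,
    y: pd.Series | None = None,
    k_neighbors: int | None = None,
    n_components: int | None = None,
    max_removal_frac: float = DEFAULT_MAX_REMOVAL_FRAC,
) -> tuple[pd.DataFrame, pd.Series | None, OutlierReport]:
    """Remove LOF outliers from a predictor matrix (yield in lockstep).

    Rows whose log LOF exceeds the removal threshold (far-out Tukey fence
    with an absolute floor, see module docstring) are dropped.  Removing
    more than ``max_removal_frac`` of the rows aborts with an error, since
    that signals a parameterization problem rather than a few bad plots.
    """
    n = len(X)
    if k_neighbors is None:
        k_neighbors = default_k_neighbors(n)
    if n < k_neighbors + 1:
        raise ValueError(f"need at least k_neighbors + 1 = {k_neighbors + 1} rows, got {n}")
    scores = pca_scores(X.to_numpy(), n_components)
    lof = lof_scores(scores, k_neighbors)
    log_lof = np.log(lof)
    q1, q3 = np.quantile(log_lof, [0.25, 0.75])
    threshold = max(q3 + TUKEY_FENCE_MULTIPLIER * (q3 - q1), np.log(LOF_FLOOR))
    removed = log_lof > threshold
    frac = removed.mean()
    if frac > max_removal_frac:
        raise ValueError(
            f"LOF filter would remove {frac:.1%} of rows "
            f"(> {max_removal_frac:.0%}); review qc parameters"
        )
    report = OutlierReport(
        lof=lof,
        removed=removed,
        threshold=float(threshold),
        k_neighbors=k_neighbors,
        n_components=scores.shape[1],
    )
    logger.info("LOF filter removed %d/%d rows (threshold %.3f on log LOF)",
                report.n_removed, n, threshold)
    X_f = X.loc[~removed]
    y_f = y.loc[~removed] if y is not None else None
    return X_f, y_f, report
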