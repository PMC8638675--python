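"""Moving quantities between spatial supports.

* ordinary kriging of cluster-level covariates to the grid (logit scale for
  proportions, exponential covariance, range set to the first quartile of
  inter-cluster distances),
* population-weighted aggregation of grid covariates and posterior coverage
  surfaces to districts (weights q(s): the within-district population share
  of each cell whose centroid falls in the district), and
* exceedance probabilities of programmatic coverage thresholds
  (default 80% and 95%).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from scipy.special import expit, logit

__all__ = [
    "krige_covariate",
    "district_covariate",
    "aggregate_surface",
    "exceedance",
    "summarize_districts",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = (0.80, 0.95)


def krige_covariate(
    cluster_xy: np.ndarray,
    values: np.ndarray,
    grid_xy: np.ndarray,
    proportion: bool = True,
    range_km: float | None = None,
) -> np.ndarray:
    """Ordinary kriging of cluster values onto the grid.

    Uses an exponential covariance exp(-d / range); the range defaults to
    the first quartile of the pairwise inter-cluster distances.  Proportion
    inputs are logit-transformed before interpolation and back-transformed
    to (0, 1).  With no nugget the predictor interpolates: predictions at
    cluster locations reproduce the cluster values, and a constant input
    yields a constant surface.
    """
    cluster_xy = np.asarray(cluster_xy, dtype=float)
    values = np.asarray(values, dtype=float)
    grid_xy = np.asarray(grid_xy, dtype=float)
    if cluster_xy.shape[0] < 3:
        raise ValueError("kriging needs at least 3 clusters")
    if proportion:
        if np.any((values <= 0) | (values >= 1)):
            eps = 0.5 / 1000.0
            values = np.clip(values, eps, 1 - eps)
        z = logit(values)
    else:
        z = values
    if range_km is None:
        range_km = float(np.quantile(pdist(cluster_xy), 0.25))
        if range_km <= 0:
            raise ValueError("degenerate cluster configuration: zero range")

    n = cluster_xy.shape[0]
    K = np.exp(-cdist(cluster_xy, cluster_xy) / range_km)
    # ordinary-kriging system with a Lagrange multiplier for unbiasedness
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = K
    A[n, :n] = 1.0
    A[:n, n] = 1.0
    k0 = np.empty((n + 1, grid_xy.shape[0]))
    k0[:n] = np.exp(-cdist(cluster_xy, grid_xy) / range_km)
    k0[n] = 1.0
    lam = np.linalg.solve(A, k0)[:n]
    pred = lam.T @ z
    return expit(pred) if proportion else pred


def _check_q(q: np.ndarray, district: np.ndarray) -> None:
    for d in np.unique(district):
        s = q[district == d].sum()
        if not np.isclose(s, 1.0, atol=1e-8):
            raise ValueError(f"q(s) must sum to 1 within district {d}; got {s:.6f}")


def district_covariate(
    grid_values: np.ndarray, q: np.ndarray, district: np.ndarray
) -> pd.Series:
    """Population-weighted district average of a grid covariate surface.

    x(A_i) = sum_j x(s_j) q(s_j) over cells with centroids in district i.
    """
    grid_values = np.asarray(grid_values, dtype=float)
    q = np.asarray(q, dtype=float)
    district = np.asarray(district)
    _check_q(q, district)
    out = {}
    for d in np.unique(district):
        m = district == d
        if not m.any():
            raise ValueError(f"district {d} contains no grid centroids")
        out[d] = float(np.dot(grid_values[m], q[m]))
    return pd.Series(out).sort_index()


def aggregate_surface(
    surface: np.ndarray, q: np.ndarray, district: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Population-weighted district aggregates of posterior coverage draws.

    Applies p_r(A_i) = sum_j p_r(s_j) q(s_j) to every posterior draw r,
    preserving the joint posterior structure. Returns (draws, district_ids)
    with draws of shape (n_draws, n_districts).
    """
    surface = np.atleast_2d(np.asarray(surface, dtype=float))
    q = np.asarray(q, dtype=float)
    district = np.asarray(district)
    _check_q(q, district)
    ids = np.unique(district)
    out = np.empty((surface.shape[0], ids.size))
    for j, d in enumerate(ids):
        m = district == d
        out[:, j] = surface[:, m] @ q[m]
    return out, ids


def exceedance(draws: np.ndarray, thresholds=DEFAULT_THRESHOLDS) -> np.ndarray:
    """P(coverage >= t) per district and threshold: (n_districts, n_thr).

    The fraction of posterior draws at or above each threshold; necessarily
    non-increasing in the threshold.
    """
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    thr = np.asarray(thresholds, dtype=float)
    return np.stack([(draws >= t).mean(axis=0) for t in thr], axis=1)


def summarize_districts(
    draws: np.ndarray,
    district_ids,
    thresholds=DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Posterior summary table per district: mean, sd, quantiles, exceedance."""
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    exc = exceedance(draws, thresholds)
    qs = np.quantile(draws, [0.025, 0.5, 0.975], axis=0)
    df = pd.DataFrame(
        {
            "district_id": list(district_ids),
            "mean": draws.mean(axis=0),
            "sd": draws.std(axis=0, ddof=1),
            "q2.5": qs[0],
            "q50": qs[1],
            "q97.5": qs[2],
        }
    )
    for j, t in enumerate(thresholds):
        df[f"p_ge_{int(round(100 * t))}"] = exc[:, j]
    return df
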