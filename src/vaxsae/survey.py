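"""Design-based (pre-model) survey computations.

Implements the direct weighted layer feeding the district-level models:

* weight normalization — within each district the per-child weights are
  rescaled so they sum to the number of children surveyed there,
* the Horvitz-Thompson ratio estimate p_dir of district coverage with a
  Taylor-linearized, stratified, with-replacement between-cluster variance
  (clusters are the PSUs; single-PSU strata are collapsed with the other
  stratum in the same district),
* the empirical logit transform Y_L = logit(p_dir) with design variance
  var_Y = var_p / (p (1-p))^2, and
* the effective sample size N_E = p (1-p) / var_p and effective cases
  Y_E = N_E * p.

Districts with boundary estimates (p_dir in {0, 1}) or zero/undefined
design variance are flagged and their transformed quantities left missing;
the models impute them from their posterior predictive distributions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "normalize_weights",
    "direct_estimate",
    "direct_estimates",
    "empirical_logit",
    "effective_sample_size",
]

_REQUIRED = ["cluster_id", "district_id", "stratum", "n_children", "n_vaccinated", "weight"]


def _check(clusters: pd.DataFrame) -> None:
    missing = [c for c in _REQUIRED if c not in clusters.columns]
    if missing:
        raise ValueError(f"cluster table lacks required columns: {missing}")
    if (clusters["weight"] <= 0).any():
        raise ValueError("weights must be strictly positive")
    if (clusters["n_vaccinated"] > clusters["n_children"]).any():
        raise ValueError("n_vaccinated cannot exceed n_children")


def normalize_weights(clusters: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with per-child normalized weights ``w_norm``.

    Within district i, the per-child weight w_k of every child in cluster k
    is rescaled by a single constant so that sum_k N_k w_norm_k equals the
    district's surveyed child count N_Ai. Relative weights are preserved and
    the result is invariant to a uniform rescaling of the raw weights.
    Districts with zero surveyed children are dropped with a warning.
    """
    _check(clusters)
    out = clusters.copy()
    out["w_norm"] = np.nan
    drop = []
    for d, g in out.groupby("district_id"):
        n_children = g["n_children"].sum()
        if n_children == 0:
            drop.append(d)
            continue
        total_w = float((g["weight"] * g["n_children"]).sum())
        out.loc[g.index, "w_norm"] = g["weight"] * n_children / total_w
    if drop:
        warnings.warn(f"districts with zero surveyed children excluded: {drop}", stacklevel=2)
        out = out[~out["district_id"].isin(drop)]
    return out


def _collapse_strata(g: pd.DataFrame) -> pd.Series:
    """Variance strata within one district, single-PSU strata collapsed.

    A stratum holding a single cluster cannot contribute a between-PSU
    variance term, so it is merged with the other stratum of the district
    (mirroring the collapse behaviour of standard survey software). If the
    district has only one cluster in total the variance is undefined.
    """
    counts = g.groupby("stratum")["cluster_id"].count()
    lone = counts[counts < 2].index.tolist()
    strata = g["stratum"].copy()
    if len(counts) > 1 and lone:
        strata[:] = "collapsed"
    return strata


def direct_estimate(district_clusters: pd.DataFrame) -> tuple[float, float]:
    """Horvitz-Thompson coverage estimate and linearized design variance.

    The estimate is the weighted ratio
    p = sum_k w_k Y_k / sum_k w_k N_k over the district's clusters
    (equivalently over individuals, weights being constant within cluster).
    The variance treats clusters as with-replacement PSUs within strata and
    linearizes the ratio: with cluster residual totals
    e_k = w_k (Y_k - p N_k) / W, W = sum w_k N_k,

        var = sum_h n_h / (n_h - 1) * sum_{k in h} (e_k - mean_h(e))^2.

    Returns (p, var); var is NaN when the district has a single cluster.
    """
    g = district_clusters
    if len(g) == 0:
        raise ValueError("no clusters supplied")
    w = g["w_norm"].to_numpy() if "w_norm" in g else g["weight"].to_numpy()
    y = g["n_vaccinated"].to_numpy(dtype=float)
    n = g["n_children"].to_numpy(dtype=float)
    W = float(np.sum(w * n))
    p = float(np.sum(w * y) / W)
    if len(g) == 1:
        return p, float("nan")
    strata = _collapse_strata(g)
    e = w * (y - p * n) / W
    var = 0.0
    for _, idx in strata.groupby(strata).groups.items():
        eh = e[g.index.get_indexer(idx)]
        nh = eh.size
        if nh < 2:
            return p, float("nan")
        var += nh / (nh - 1) * float(np.sum((eh - eh.mean()) ** 2))
    return p, max(var, 0.0)


def empirical_logit(est: pd.DataFrame) -> pd.DataFrame:
    """Attach Y_L = logit(p_dir) and var_Y = var_p / (p(1-p))^2.

    Boundary districts (p in {0,1}) have undefined transforms and are left
    missing with ``boundary_flag`` set; zero design variance also yields a
    missing var_Y (a degenerate known-variance likelihood).
    """
    out = est.copy()
    p = out["p_hat_dir"].to_numpy()
    v = out["var_p_dir"].to_numpy()
    ok = (p > 0) & (p < 1) & np.isfinite(v) & (v > 0)
    y_logit = np.full(p.shape, np.nan)
    var_logit = np.full(p.shape, np.nan)
    y_logit[ok] = np.log(p[ok] / (1 - p[ok]))
    var_logit[ok] = v[ok] / (p[ok] * (1 - p[ok])) ** 2
    out["y_logit"] = y_logit
    out["var_logit"] = var_logit
    return out


def effective_sample_size(est: pd.DataFrame) -> pd.DataFrame:
    """Attach N_E = p(1-p)/var_p and Y_E = N_E * p.

    The effective sample size equates the complex-design variance with that
    of a simple random sample. Undefined for boundary estimates or zero
    variance; such districts stay missing.
    """
    out = est.copy()
    p = out["p_hat_dir"].to_numpy()
    v = out["var_p_dir"].to_numpy()
    ok = (p > 0) & (p < 1) & np.isfinite(v) & (v > 0)
    n_eff = np.full(p.shape, np.nan)
    n_eff[ok] = p[ok] * (1 - p[ok]) / v[ok]
    out["n_eff"] = n_eff
    out["y_eff"] = n_eff * p
    return out


def direct_estimates(clusters: pd.DataFrame) -> pd.DataFrame:
    """Full district-level direct-estimate table.

    Normalizes weights, computes the Horvitz-Thompson estimate and its
    linearized variance per district, and attaches the empirical logit and
    effective-sample-size transforms with boundary/missing flags.
    """
    cl = normalize_weights(clusters)
    rows = []
    for d, g in cl.groupby("district_id"):
        p, v = direct_estimate(g)
        rows.append(
            {
                "district_id": d,
                "n_clusters": len(g),
                "n_raw": int(g["n_children"].sum()),
                "y_raw": int(g["n_vaccinated"].sum()),
                "p_hat_dir": p,
                "var_p_dir": v,
                "boundary_flag": bool(p in (0.0, 1.0)),
            }
        )
    est = pd.DataFrame(rows).sort_values("district_id").reset_index(drop=True)
    est = empirical_logit(est)
    est = effective_sample_size(est)
    return est
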