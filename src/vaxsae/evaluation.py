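"""Leave-one-district-out cross-validation and comparison metrics.

Each district in turn is withheld: discrete models lose the district's
response (covariates stay, so the fit imputes it from the CAR structure);
continuous models lose every cluster inside the district and predict its
grid cells from the surrounding data.  Held-out predictive draws of
district coverage are scored against the direct weighted survey estimates
with four metrics:

    RBias = (1/n) sum (p_hat_i - p_i) / p_i
    RMSE  = sqrt( sum (p_hat_i - p_i)^2 / n )
    MAE   = (1/n) sum |p_hat_i - p_i|
    CRPS  = mean_i [ (1/m) sum_j |X_ij - p_i| - (1/2m^2) sum_jk |X_ij - X_ik| ]

where p_hat_i is the posterior mean of the held-out coverage and the CRPS
uses the full held-out predictive distribution.  Districts whose direct
estimate sits on the boundary (p in {0,1}, undefined design variance) are
excluded from the metric averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aggregation import aggregate_surface

from .continuous import GP_MODELS, fit_gp, predict_surface
from .discrete import DISCRETE_MODELS, fit_discrete
from .matern import PCPriorSpec
from .mcmc import MCMCConfig
from .survey import direct_estimates
from .synthetic import SyntheticCountry

__all__ = [
    "lodo_split_discrete",
    "lodo_split_continuous",
    "metric_rbias",
    "metric_rmse_mae",
    "metric_crps",
    "crps_sample",
    "CVResult",
    "run_comparison",
    "district_design",
    "ALL_MODELS",
]

ALL_MODELS = DISCRETE_MODELS + GP_MODELS

_RESPONSE_COLS = ["y_raw", "n_raw", "y_logit", "var_logit", "y_eff", "n_eff"]


def lodo_split_discrete(direct_est: pd.DataFrame, district_id) -> pd.DataFrame:
    """Copy of the direct-estimate table with one district's responses masked.

    Only the response columns are set missing; covariates and the adjacency
    are untouched, so the model's draw for that district is its posterior
    predictive given the remaining data.
    """
    out = direct_est.copy()
    m = out["district_id"] == district_id
    if not m.any():
        raise KeyError(f"district {district_id} not in table")
    out.loc[m, _RESPONSE_COLS] = np.nan
    return out


def lodo_split_continuous(clusters: pd.DataFrame, district_id) -> pd.DataFrame:
    """Clusters with every cluster inside the held-out district removed."""
    return clusters[clusters["district_id"] != district_id].reset_index(drop=True)


def metric_rbias(p_hat: np.ndarray, p: np.ndarray) -> float:
    """Signed mean relative error (1/n) sum (p_hat - p)/p; needs p > 0."""
    p_hat, p = np.asarray(p_hat, float), np.asarray(p, float)
    if np.any(p <= 0):
        raise ValueError("relative bias requires reference values > 0")
    return float(np.mean((p_hat - p) / p))


def metric_rmse_mae(p_hat: np.ndarray, p: np.ndarray) -> tuple[float, float]:
    """(RMSE, MAE) of the point predictions against the reference."""
    p_hat, p = np.asarray(p_hat, float), np.asarray(p, float)
    if p_hat.shape != p.shape:
        raise ValueError("length mismatch")
    e = p_hat - p
    return float(np.sqrt(np.mean(e**2))), float(np.mean(np.abs(e)))


def crps_sample(draws: np.ndarray, obs: float, exact: bool = False) -> float:
    """Sample CRPS of one predictive distribution against one observation.

    Estimates E|X - obs| - 0.5 E|X - X'| from m posterior draws.  By
    default the second term uses the O(m log m) sorted identity
    sum_jk |x_j - x_k| = 2 sum_i (2i - 1 - m) x_(i); ``exact=True`` forces
    the literal O(m^2) double sum (both agree to ~1e-12, used as an
    internal cross-check).
    """
    x = np.asarray(draws, dtype=float).ravel()
    m = x.size
    if m < 2:
        raise ValueError("CRPS needs at least 2 draws")
    term1 = float(np.mean(np.abs(x - obs)))
    if exact:
        gini = float(np.sum(np.abs(x[:, None] - x[None, :])))
    else:
        xs = np.sort(x)
        i = np.arange(1, m + 1)
        gini = 2.0 * float(np.sum((2 * i - m - 1) * xs))
    return term1 - gini / (2.0 * m * m)


def metric_crps(heldout_draws: np.ndarray, p: np.ndarray) -> float:
    """Mean CRPS across districts; draws shaped (m, n_districts)."""
    draws = np.atleast_2d(np.asarray(heldout_draws, float))
    p = np.asarray(p, float)
    return float(np.mean([crps_sample(draws[:, i], p[i]) for i in range(p.size)]))


@dataclass
class CVResult:
    """Comparison table plus the per-model held-out draws behind it."""

    table: pd.DataFrame
    heldout: dict[tuple[str, bool], np.ndarray] = field(default_factory=dict)
    reference: np.ndarray | None = None
    included: np.ndarray | None = None
    n_excluded_boundary: int = 0


def _national_direct(clusters: pd.DataFrame) -> float:
    w = clusters["weight"].to_numpy()
    return float(
        np.sum(w * clusters["n_vaccinated"]) / np.sum(w * clusters["n_children"])
    )


def district_design(country: SyntheticCountry, names: list[str]) -> np.ndarray:
    """Intercept + population-weighted district aggregates of grid covariates."""
    from .aggregation import district_covariate

    grid = country.grid
    cols = [np.ones(country.districts.n)]
    for c in names:
        s = district_covariate(grid.covariates[c].to_numpy(), grid.q, grid.district)
        cols.append(s.to_numpy())
    return np.column_stack(cols)


def _heldout_discrete(model_id, direct, X, graph, seed, mcmc):
    n_A = graph.n
    out = None
    for i, d in enumerate(graph.ids):
        masked = lodo_split_discrete(direct, d)
        fit = fit_discrete(model_id, masked, X, graph, seed=seed + i, mcmc=mcmc)
        if out is None:
            out = np.empty((fit.p_district.shape[0], n_A))
        out[:, i] = fit.p_district[:, i]
    return out


def _heldout_continuous(model_id, country, clusters, names, seed, mcmc, n_surface_draws):
    grid = country.grid
    n_A = country.districts.n
    out = None
    for i in range(n_A):
        train = lodo_split_continuous(clusters, i)
        coords = train[["x_km", "y_km"]].to_numpy()
        X = np.column_stack(
            [np.ones(len(train))] + [train[c].to_numpy() for c in names]
        )
        pc = PCPriorSpec(r0=0.05 * country.config.extent_km[1])
        fit = fit_gp(
            coords,
            train["n_vaccinated"].to_numpy(float),
            train["n_children"].to_numpy(float),
            X,
            model_id=model_id,
            pc=pc,
            seed=seed + i,
            mcmc=mcmc,
        )
        sel = grid.district == i
        Xg = np.column_stack(
            [np.ones(int(sel.sum()))]
            + [grid.covariates[c].to_numpy()[sel] for c in names]
        )
        surf = predict_surface(
            fit, grid.xy[sel], Xg, seed=seed + i, n_draws=n_surface_draws
        )
        agg, _ = aggregate_surface(surf.p, grid.q[sel], np.zeros(int(sel.sum()), int))
        if out is None:
            out = np.empty((agg.shape[0], n_A))
        out[:, i] = agg[:, 0]
    return out


def run_comparison(
    country: SyntheticCountry,
    models=ALL_MODELS,
    covariates: str = "with",
    seed: int = 0,
    mcmc_discrete: MCMCConfig | None = None,
    mcmc_gp: MCMCConfig | None = None,
    n_surface_draws: int = 100,
    include_baseline: bool = True,
) -> CVResult:
    """Leave-one-district-out comparison of the requested models.

    ``covariates`` is one of "with", "without" or "both" (both arms, as in
    a model-comparison table with and without covariates).  The reference
    values are the direct weighted survey estimates from the *full* data;
    boundary districts are excluded from the metric averages.  The
    ``national-mean`` baseline row scores the constant pooled direct
    estimate (RMSE/RBias/MAE only — it has no predictive distribution).

    Deterministic given ``seed``; every fit receives a distinct derived
    seed below 2^31.
    """
    if covariates not in ("with", "without", "both"):
        raise ValueError("covariates must be 'with', 'without' or 'both'")
    clusters = country.clusters
    graph = country.districts.graph
    direct = direct_estimates(clusters)
    direct = direct.set_index("district_id").reindex(graph.ids).reset_index()
    ref = direct["p_hat_dir"].to_numpy()
    included = (~direct["boundary_flag"].to_numpy()) & np.isfinite(
        direct["var_p_dir"].to_numpy()
    )
    mcmc_discrete = mcmc_discrete or MCMCConfig(n_chains=2, n_warmup=400, n_keep=400)
    mcmc_gp = mcmc_gp or MCMCConfig(n_chains=2, n_warmup=250, n_keep=250, n_leapfrog=10)

    arms = {"with": [True], "without": [False], "both": [True, False]}[covariates]
    all_names = list(country.grid.covariates.columns)

    rows = []
    heldout: dict[tuple[str, bool], np.ndarray] = {}
    for with_cov in arms:
        names = all_names if with_cov else []
        X_dist = district_design(country, names)
        for k, model_id in enumerate(models):
            fit_seed = (seed * 1009 + k * 101 + (1 if with_cov else 0) * 50021) % (2**31)
            if model_id in DISCRETE_MODELS:
                draws = _heldout_discrete(
                    model_id, direct, X_dist, graph, fit_seed, mcmc_discrete
                )
            else:
                draws = _heldout_continuous(
                    model_id, country, clusters, names, fit_seed, mcmc_gp,
                    n_surface_draws,
                )
            heldout[(model_id, with_cov)] = draws
            p_hat = draws.mean(axis=0)
            rmse, mae = metric_rmse_mae(p_hat[included], ref[included])
            rows.append(
                {
                    "model": model_id,
                    "covariates": with_cov,
                    "RMSE": rmse,
                    "RBias": metric_rbias(p_hat[included], ref[included]),
                    "MAE": mae,
                    "CRPS": metric_crps(draws[:, included], ref[included]),
                }
            )
        if include_baseline:
            p_nat = _national_direct(clusters)
            const = np.full(int(included.sum()), p_nat)
            rmse, mae = metric_rmse_mae(const, ref[included])
            rows.append(
                {
                    "model": "national-mean",
                    "covariates": with_cov,
                    "RMSE": rmse,
                    "RBias": metric_rbias(const, ref[included]),
                    "MAE": mae,
                    "CRPS": np.nan,
                }
            )
    table = pd.DataFrame(rows)
    return CVResult(
        table=table,
        heldout=heldout,
        reference=ref,
        included=included,
        n_excluded_boundary=int((~included).sum()),
    )
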