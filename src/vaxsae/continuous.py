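"""Continuous (geostatistical) binomial coverage models and grid prediction.

Cluster counts follow Y(s_i) ~ Binomial(N(s_i), p(s_i)) with

    C-GPIID:  logit p(s_i) = x(s_i)' beta + omega(s_i) + eps(s_i)
    C-GP:     logit p(s_i) = x(s_i)' beta + omega(s_i)

where omega is a zero-mean Gaussian process with Matérn (nu = 1)
covariance (marginal variance sigma_omega^2, practical range r) and eps is
an iid Gaussian nugget (variance sigma_eps^2) capturing between-cluster /
excess-binomial variation.  Hyperpriors are penalized-complexity: the
joint PC prior on (r, sigma_omega) and an exponential PC prior on
sigma_eps (see :mod:`vaxsae.matern`), with vague N(0, 1e6) coefficients.

Inference is exact dense-covariance MCMC (no SPDE mesh): omega is whitened
through the Cholesky factor of the Matérn correlation, the latent block
(beta, z_omega[, z_eps]) moves by HMC and the hyperparameters by adaptive
Metropolis.  Grid prediction draws omega at cell centroids from the exact
conditional GP given omega at the data locations, per posterior draw,
blocked by district; the nugget is not added to grid predictions (it is a
property of clusters, not locations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular
from scipy.spatial.distance import cdist
from scipy.special import expit

from .matern import MaternKernel, PCPriorSpec, pc_nugget_logdensity, pc_prior_logdensity
from .mcmc import GibbsModel, MCMCConfig, run_gibbs
from .synthetic import safe_cholesky

__all__ = ["GPFit", "PosteriorSurface", "fit_gp", "predict_surface"]

GP_MODELS = ("C-GPIID", "C-GP")


@dataclass
class GPFit:
    """Posterior draws of a continuous model, plus what prediction needs."""

    model_id: str
    coords: np.ndarray  # (n, 2) cluster coordinates, km
    draws: dict[str, np.ndarray]
    x_mean: np.ndarray
    x_scale: np.ndarray
    rhat: dict[str, float]
    ess: dict[str, float]
    converged: bool

    @property
    def n_draws(self) -> int:
        return self.draws["omega"].shape[0]


@dataclass
class PosteriorSurface:
    """Coverage draws p_r(s_j) on the grid: (n_draws, n_grid) in (0, 1)."""

    p: np.ndarray
    xy: np.ndarray
    model_id: str


class _GPCore(GibbsModel):
    def __init__(self, coords, y, n, X, model_id, pc: PCPriorSpec):
        self.model_id = model_id
        self.nugget = model_id == "C-GPIID"
        self.coords = np.asarray(coords, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.n_vec = np.asarray(n, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.pc = pc
        self.n_c = self.coords.shape[0]
        self.p_cov = self.X.shape[1]
        if np.any(self.y > self.n_vec):
            raise ValueError("Y cannot exceed N")
        self.dists = cdist(self.coords, self.coords)
        self.kernel = MaternKernel()

        self.n_latent = self.p_cov + self.n_c * (2 if self.nugget else 1)
        self.latent_prior_sd = np.concatenate(
            [np.full(self.p_cov, 1e3), np.ones(self.n_latent - self.p_cov)]
        )
        self.hyper_names = ["log_range", "log_sigma_omega"] + (
            ["log_sigma_eps"] if self.nugget else []
        )

    def init_hyper(self, rng):
        h = [
            np.log(self.pc.r0 * 4.0) + 0.2 * rng.standard_normal(),
            np.log(0.5) + 0.2 * rng.standard_normal(),
        ]
        if self.nugget:
            h.append(np.log(0.3) + 0.2 * rng.standard_normal())
        return np.array(h)

    def make_cache(self, h, prev=None):
        r = float(np.exp(h[0]))
        if prev is not None and prev[0][0] == h[0]:
            L = prev[1]["L"]
            logdetL = prev[1]["logdetL"]
        else:
            R = self.kernel.corr(self.dists, r)
            L = safe_cholesky(R, 1.0)
            logdetL = float(np.sum(np.log(np.diag(L))))
        cache = {
            "L": L,
            "logdetL": logdetL,
            "range_r": r,
            "sigma_omega": float(np.exp(h[1])),
            "sigma_eps": float(np.exp(h[2])) if self.nugget else 0.0,
        }
        return cache

    def hyper_logprior(self, h):
        r, s_om = float(np.exp(h[0])), float(np.exp(h[1]))
        lp = pc_prior_logdensity(r, s_om, self.pc) + h[0] + h[1]  # + Jacobians
        if self.nugget:
            s_eps = float(np.exp(h[2]))
            lp += pc_nugget_logdensity(s_eps, self.pc) + h[2]
        return float(lp)

    def _split(self, u):
        beta = u[: self.p_cov]
        z_om = u[self.p_cov : self.p_cov + self.n_c]
        z_eps = u[self.p_cov + self.n_c :] if self.nugget else None
        return beta, z_om, z_eps

    def _eta(self, u, cache):
        beta, z_om, z_eps = self._split(u)
        eta = self.X @ beta + cache["sigma_omega"] * (cache["L"] @ z_om)
        if self.nugget:
            eta = eta + cache["sigma_eps"] * z_eps
        return eta

    def loglik(self, u, cache):
        eta = self._eta(u, cache)
        return float(np.sum(self.y * eta - self.n_vec * np.logaddexp(0.0, eta)))

    def grad_loglik(self, u, cache):
        eta = self._eta(u, cache)
        g_eta = self.y - self.n_vec * expit(eta)
        parts = [self.X.T @ g_eta, cache["sigma_omega"] * (cache["L"].T @ g_eta)]
        if self.nugget:
            parts.append(cache["sigma_eps"] * g_eta)
        return np.concatenate(parts)

    def centered_transform(self, u, cache, cache_new):
        """Re-whiten (z_omega[, z_eps]) so omega (and eps) are preserved."""
        beta, z_om, z_eps = self._split(u)
        omega = cache["sigma_omega"] * (cache["L"] @ z_om)
        z_om_new = (
            solve_triangular(cache_new["L"], omega, lower=True)
            / cache_new["sigma_omega"]
        )
        n = self.n_c
        dlp = (
            -0.5 * float(z_om_new @ z_om_new - z_om @ z_om)
            - n * (np.log(cache_new["sigma_omega"]) - np.log(cache["sigma_omega"]))
            - (cache_new["logdetL"] - cache["logdetL"])
        )
        parts = [beta, z_om_new]
        if self.nugget:
            eps = cache["sigma_eps"] * z_eps
            z_eps_new = eps / cache_new["sigma_eps"]
            dlp += -0.5 * float(z_eps_new @ z_eps_new - z_eps @ z_eps) - n * (
                np.log(cache_new["sigma_eps"]) - np.log(cache["sigma_eps"])
            )
            parts.append(z_eps_new)
        return np.concatenate(parts), float(dlp)

    def draw_record(self, u, h, cache):
        beta, z_om, z_eps = self._split(u)
        omega = cache["sigma_omega"] * (cache["L"] @ z_om)
        eta = self.X @ beta + omega
        if self.nugget:
            eta = eta + cache["sigma_eps"] * z_eps
        rec = {
            "beta": beta.copy(),
            "omega": omega,
            "p_cluster": expit(eta),
            "sigma_omega": cache["sigma_omega"],
            "sigma2_omega": cache["sigma_omega"] ** 2,
            "range_r": cache["range_r"],
            "beta0": float(beta[0]),
            "sigma_eps": cache["sigma_eps"],
            "sigma2_eps": cache["sigma_eps"] ** 2,
        }
        return rec

    def diag_names(self):
        names = ["beta0", "sigma_omega", "range_r"]
        if self.nugget:
            names.append("sigma_eps")
        return names


def _standardize(X):
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    mean[0], scale[0] = 0.0, 1.0
    scale[scale == 0] = 1.0
    return (X - mean) / scale, mean, scale


def fit_gp(
    coords: np.ndarray,
    y: np.ndarray,
    n: np.ndarray,
    X: np.ndarray,
    model_id: str = "C-GPIID",
    pc: PCPriorSpec | None = None,
    seed: int = 0,
    mcmc: MCMCConfig | None = None,
) -> GPFit:
    """Fit C-GPIID or C-GP to cluster-level counts.

    Parameters
    ----------
    coords : (n, 2) planar-km cluster coordinates.
    y, n : vaccinated and surveyed counts per cluster.
    X : (n, p) design matrix including the intercept column.
    pc : PC-prior calibration; default sets r0 to 5% of the north-south
        (y-coordinate) extent of the data.
    """
    if model_id not in GP_MODELS:
        raise ValueError(f"unknown continuous model {model_id!r}")
    coords = np.asarray(coords, dtype=float)
    if pc is None:
        ns_extent = float(np.ptp(coords[:, 1]))
        pc = PCPriorSpec(r0=max(0.05 * ns_extent, 1e-6))
    Xs, mean, scale = _standardize(X)
    core = _GPCore(coords, y, n, Xs, model_id, pc)
    res = run_gibbs(core, mcmc or MCMCConfig(), seed)
    beta_std = res.draws["beta"]
    beta_orig = beta_std / scale
    beta_orig[:, 0] = beta_std[:, 0] - beta_std[:, 1:] @ (mean[1:] / scale[1:])
    draws = dict(res.draws)
    draws["beta_std"] = beta_std
    draws["beta"] = beta_orig
    return GPFit(
        model_id=model_id,
        coords=coords,
        draws=draws,
        x_mean=mean,
        x_scale=scale,
        rhat=res.rhat,
        ess=res.ess,
        converged=res.converged,
    )


def predict_surface(
    fit: GPFit,
    grid_xy: np.ndarray,
    X_grid: np.ndarray,
    seed: int = 0,
    n_draws: int | None = None,
    blocks: np.ndarray | None = None,
) -> PosteriorSurface:
    """Draw the coverage surface p_r(s) at grid centroids per posterior draw.

    For each (thinned) posterior draw r, omega at the grid is drawn from
    the exact Gaussian conditional given omega at the data locations under
    that draw's (sigma_omega, range); then
    p_r(s) = expit(x(s)' beta_r + omega_r(s)).  When ``blocks`` labels the
    grid cells (eg by district), the conditional simulation runs per block
    — each block conditions on all data; cross-block posterior correlation
    of the *simulated noise* is dropped, which leaves within-block
    aggregates exact.  The nugget is never added to grid predictions.
    """
    grid_xy = np.asarray(grid_xy, dtype=float)
    X_grid = np.asarray(X_grid, dtype=float)
    if X_grid.shape[1] != fit.x_mean.size:
        raise ValueError(
            f"grid design has {X_grid.shape[1]} columns, fit used {fit.x_mean.size}"
        )
    Xg = (X_grid - fit.x_mean) / fit.x_scale
    m_total = fit.n_draws
    if n_draws is None or n_draws >= m_total:
        take = np.arange(m_total)
    else:  # deterministic thinning
        take = np.linspace(0, m_total - 1, n_draws).round().astype(int)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 7]))

    kernel = MaternKernel()
    d_dd = cdist(fit.coords, fit.coords)
    d_gd = cdist(grid_xy, fit.coords)
    if blocks is None:
        blocks = np.zeros(grid_xy.shape[0], dtype=int)
    blocks = np.asarray(blocks)
    labels = np.unique(blocks)
    d_gg = {b: cdist(grid_xy[blocks == b], grid_xy[blocks == b]) for b in labels}

    n_g = grid_xy.shape[0]
    P = np.empty((take.size, n_g))
    for out_i, r_i in enumerate(take):
        s2 = float(fit.draws["sigma2_omega"][r_i])
        rr = float(fit.draws["range_r"][r_i])
        omega_d = fit.draws["omega"][r_i]
        beta = fit.draws["beta_std"][r_i]
        R_dd = kernel.corr(d_dd, rr)
        L_dd = safe_cholesky(R_dd, 1.0)
        # alpha = R_dd^-1 omega_d ... work on correlation scale
        w = solve_triangular(
            L_dd.T, solve_triangular(L_dd, omega_d, lower=True), lower=False
        )
        R_gd = kernel.corr(d_gd, rr)
        cond_mean = R_gd @ w  # = Sigma_gd Sigma_dd^-1 omega_d
        omega_g = np.empty(n_g)
        for b in labels:
            sel = blocks == b
            V = solve_triangular(L_dd, R_gd[sel].T, lower=True)  # (n_d, n_b)
            # conditional *correlation*-scale matrix: keeps jitter meaningful
            # even when the sigma2_omega draw is tiny
            Cc = kernel.corr(d_gg[b], rr) - V.T @ V
            Lb = np.sqrt(s2) * safe_cholesky(Cc, 1.0, clip_eigs=True)
            omega_g[sel] = cond_mean[sel] + Lb @ rng.standard_normal(sel.sum())
        P[out_i] = expit(Xg @ beta + omega_g)
    return PosteriorSurface(p=P, xy=grid_xy, model_id=fit.model_id)
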