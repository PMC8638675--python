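"""The three discrete (district-level) Bayesian spatial models.

All three share the linear predictor eta_i = x_i' beta + phi_i with a
Leroux CAR prior on phi and differ only in the likelihood:

* D-UNWB — unweighted binomial: Y_i ~ Binomial(N_i, expit(eta_i)) on the
  raw district counts (ignores the survey design),
* D-LN — logit-normal: the empirical logit of the direct weighted estimate
  is Gaussian with *known* design-based variance, Y_L,i ~ N(eta_i, var_Y,i),
* D-ESS — effective sample size: Y_E,i ~ Binomial(N_E,i, expit(eta_i)) with
  the (non-integer) effective counts, via the gamma-normalized continuous
  binomial log-likelihood.

Priors: beta ~ N(0, 1e6) per coefficient, logit(rho) ~ N(0, 0.45),
precision sigma_phi^-2 ~ Gamma(0.1, 0.1).  Districts with missing
responses (boundary direct estimates) are dropped from the likelihood;
their eta and coverage draws come from the joint posterior, which is
exactly their posterior predictive under the model.

Sampling: the shared Gibbs engine in :mod:`vaxsae.mcmc`, with phi whitened
through the eigendecomposition of the graph Laplacian so hyperparameter
moves are cheap and exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, gammaln

from .car import AdjacencyGraph, LerouxEigen
from .mcmc import GibbsModel, MCMCConfig, MCMCResult, run_gibbs

__all__ = [
    "DiscreteModelSpec",
    "PosteriorFit",
    "fit_dunwb",
    "fit_dln",
    "fit_dess",
    "fit_discrete",
]

DISCRETE_MODELS = ("D-UNWB", "D-LN", "D-ESS")


@dataclass(frozen=True)
class DiscreteModelSpec:
    """Model id, covariates and prior hyperparameters.

    ``var_logit_rho`` is the variance of the Gaussian prior on logit(rho);
    ``prec_shape``/``prec_rate`` parameterize the Gamma prior on the
    precision sigma_phi^-2; ``var_beta`` the (vague) coefficient prior.
    """

    model_id: str = "D-UNWB"
    covariates: tuple[str, ...] = ()
    var_beta: float = 1.0e6
    var_logit_rho: float = 0.45
    prec_shape: float = 0.1
    prec_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.model_id not in DISCRETE_MODELS:
            raise ValueError(f"unknown model id {self.model_id!r}")
        for name in ("var_beta", "var_logit_rho", "prec_shape", "prec_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PosteriorFit:
    """Joint posterior draws of a discrete model.

    ``p_district`` holds district coverage draws (n_draws, n_districts) —
    expit(eta) for every district including imputed (missing-response) ones.
    """

    model_id: str
    district_ids: list
    draws: dict[str, np.ndarray]
    p_district: np.ndarray
    rhat: dict[str, float]
    ess: dict[str, float]
    converged: bool
    missing: np.ndarray  # bool mask of districts without a likelihood term

    def summary(self) -> "np.ndarray":
        return self.p_district.mean(axis=0)


class _DiscreteCore(GibbsModel):
    """Shared machinery; subclass-by-likelihood via the `kind` switch."""

    def __init__(
        self,
        kind: str,
        y: np.ndarray,
        n: np.ndarray,
        X: np.ndarray,
        graph: AdjacencyGraph,
        spec: DiscreteModelSpec,
        var_y: np.ndarray | None = None,
    ):
        self.kind = kind
        self.graph = graph
        self.spec = spec
        self.eig = LerouxEigen(graph)
        self.n_A = graph.n
        self.X = np.asarray(X, dtype=float)
        self.p_cov = self.X.shape[1]
        self.y = np.asarray(y, dtype=float)
        self.n_obs_vec = np.asarray(n, dtype=float)
        self.var_y = None if var_y is None else np.asarray(var_y, dtype=float)

        if kind == "gauss":
            self.obs = np.isfinite(self.y) & np.isfinite(self.var_y) & (self.var_y > 0)
        else:
            self.obs = (
                np.isfinite(self.y) & np.isfinite(self.n_obs_vec) & (self.n_obs_vec > 0)
            )
        if not self.obs.any():
            raise ValueError("all districts missing: model unidentifiable")
        if kind == "binom":
            if np.any(self.y[self.obs] > self.n_obs_vec[self.obs]):
                raise ValueError("Y cannot exceed N")
            # constant lgamma normalization (kept so loglik is a true log pmf)
            yo, no = self.y[self.obs], self.n_obs_vec[self.obs]
            self._lognorm = float(
                np.sum(gammaln(no + 1) - gammaln(yo + 1) - gammaln(no - yo + 1))
            )
        else:
            self._lognorm = 0.0

        self.n_latent = self.p_cov + self.n_A
        self.latent_prior_sd = np.concatenate(
            [np.full(self.p_cov, np.sqrt(spec.var_beta)), np.ones(self.n_A)]
        )
        self.hyper_names = ["logit_rho", "log_sigma_phi"]

    # --- hyperparameters: h = (logit rho, log sigma_phi) ---
    def init_hyper(self, rng):
        return np.array([0.3 * rng.standard_normal(), 0.3 * rng.standard_normal() - 0.5])

    def make_cache(self, h, prev=None):
        rho = expit(h[0])
        sigma_phi = float(np.exp(h[1]))
        A = self.eig.whitener(rho, sigma_phi)
        s = self.eig.spectrum(rho)
        # log|det A| with A = sigma V diag(s)^{-1/2}
        logdetA = self.n_A * np.log(sigma_phi) - 0.5 * float(np.sum(np.log(s)))
        return {
            "A": A,
            "rho": rho,
            "sigma_phi": sigma_phi,
            "s": s,
            "logdetA": logdetA,
        }

    def hyper_logprior(self, h):
        lp = -0.5 * h[0] ** 2 / self.spec.var_logit_rho
        # precision tau = exp(-2t), t = log sigma_phi; Gamma(a, b) on tau with
        # Jacobian |dtau/dt| = 2 tau  =>  log p(t) = -2 a t - b e^{-2t} + const
        a, b = self.spec.prec_shape, self.spec.prec_rate
        t = h[1]
        lp += -2.0 * a * t - b * np.exp(-2.0 * t)
        return float(lp)

    # --- latent block: u = (beta, z), eta = X beta + A z ---
    def _eta(self, u, cache):
        beta, z = u[: self.p_cov], u[self.p_cov :]
        return self.X @ beta + cache["A"] @ z

    def _ll_eta(self, eta):
        o = self.obs
        if self.kind == "gauss":
            r = self.y[o] - eta[o]
            return float(-0.5 * np.sum(r * r / self.var_y[o]))
        yo, no, eo = self.y[o], self.n_obs_vec[o], eta[o]
        return float(np.sum(yo * eo - no * np.logaddexp(0.0, eo)) + self._lognorm)

    def _dll_deta(self, eta):
        g = np.zeros(self.n_A)
        o = self.obs
        if self.kind == "gauss":
            g[o] = (self.y[o] - eta[o]) / self.var_y[o]
        else:
            g[o] = self.y[o] - self.n_obs_vec[o] * expit(eta[o])
        return g

    def loglik(self, u, cache):
        return self._ll_eta(self._eta(u, cache))

    def grad_loglik(self, u, cache):
        g_eta = self._dll_deta(self._eta(u, cache))
        return np.concatenate([self.X.T @ g_eta, cache["A"].T @ g_eta])

    def centered_transform(self, u, cache, cache_new):
        """Re-whiten z so that phi is preserved under new (rho, sigma)."""
        beta, z = u[: self.p_cov], u[self.p_cov :]
        phi = cache["A"] @ z
        t = self.eig.V.T @ phi
        z_new = np.sqrt(cache_new["s"]) * t / cache_new["sigma_phi"]
        dlp = -0.5 * float(z_new @ z_new - z @ z) - (
            cache_new["logdetA"] - cache["logdetA"]
        )
        return np.concatenate([beta, z_new]), float(dlp)

    def draw_record(self, u, h, cache):
        beta, z = u[: self.p_cov], u[self.p_cov :]
        phi = cache["A"] @ z
        eta = self.X @ beta + phi
        rec = {
            "beta": beta.copy(),
            "phi": phi,
            "eta": eta,
            "p": expit(eta),
            "rho": cache["rho"],
            "sigma2_phi": cache["sigma_phi"] ** 2,
            "beta0": float(beta[0]),
        }
        return rec

    def diag_names(self):
        return ["beta0", "rho", "sigma2_phi"]


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center/scale non-intercept columns; returns (Xs, mean, scale)."""
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    mean[0], scale[0] = 0.0, 1.0  # intercept untouched
    scale[scale == 0] = 1.0
    return (X - mean) / scale, mean, scale


def _fit(
    kind: str,
    model_id: str,
    y,
    n,
    X,
    graph: AdjacencyGraph,
    spec: DiscreteModelSpec,
    seed: int,
    mcmc: MCMCConfig,
    var_y=None,
    fix_hyper=None,
) -> PosteriorFit:
    Xs, mean, scale = _standardize(X)
    core = _DiscreteCore(kind, y, n, Xs, graph, spec, var_y=var_y)
    if fix_hyper is not None:
        # (logit rho, log sigma_phi) pinned — a testing hook, not a prior
        core.fixed_hyper = np.asarray(fix_hyper, dtype=float)
    res: MCMCResult = run_gibbs(core, mcmc, seed)
    beta_std = res.draws["beta"]
    # back-transform coefficients to the original covariate scale
    beta_orig = beta_std / scale
    beta_orig[:, 0] = beta_std[:, 0] - beta_std[:, 1:] @ (mean[1:] / scale[1:])
    draws = dict(res.draws)
    draws["beta_std"] = beta_std
    draws["beta"] = beta_orig
    return PosteriorFit(
        model_id=model_id,
        district_ids=list(graph.ids),
        draws=draws,
        p_district=res.draws["p"],
        rhat=res.rhat,
        ess=res.ess,
        converged=res.converged,
        missing=~core.obs,
    )


def fit_dunwb(
    y: np.ndarray,
    n: np.ndarray,
    X: np.ndarray,
    graph: AdjacencyGraph,
    spec: DiscreteModelSpec | None = None,
    seed: int = 0,
    mcmc: MCMCConfig | None = None,
    fix_hyper=None,
) -> PosteriorFit:
    """Unweighted binomial spatial model on raw district counts."""
    spec = spec or DiscreteModelSpec(model_id="D-UNWB")
    return _fit(
        "binom", "D-UNWB", y, n, X, graph, spec, seed, mcmc or MCMCConfig(),
        fix_hyper=fix_hyper,
    )


def fit_dln(
    y_logit: np.ndarray,
    var_logit: np.ndarray,
    X: np.ndarray,
    graph: AdjacencyGraph,
    spec: DiscreteModelSpec | None = None,
    seed: int = 0,
    mcmc: MCMCConfig | None = None,
    fix_hyper=None,
) -> PosteriorFit:
    """Logit-normal model: empirical logits with known design variances.

    Missing (boundary) districts contribute no likelihood; their coverage
    draws are posterior predictive.
    """
    spec = spec or DiscreteModelSpec(model_id="D-LN")
    return _fit(
        "gauss", "D-LN", y_logit, np.ones_like(y_logit),
        X, graph, spec, seed, mcmc or MCMCConfig(), var_y=var_logit,
        fix_hyper=fix_hyper,
    )


def fit_dess(
    y_eff: np.ndarray,
    n_eff: np.ndarray,
    X: np.ndarray,
    graph: AdjacencyGraph,
    spec: DiscreteModelSpec | None = None,
    seed: int = 0,
    mcmc: MCMCConfig | None = None,
) -> PosteriorFit:
    """Effective-sample-size binomial model on (possibly non-integer) counts."""
    spec = spec or DiscreteModelSpec(model_id="D-ESS")
    return _fit("binom", "D-ESS", y_eff, n_eff, X, graph, spec, seed, mcmc or MCMCConfig())


def fit_discrete(
    model_id: str,
    direct_est,
    X: np.ndarray,
    graph: AdjacencyGraph,
    seed: int = 0,
    mcmc: MCMCConfig | None = None,
    spec: DiscreteModelSpec | None = None,
) -> PosteriorFit:
    """Dispatch on model id, pulling the right columns from a direct-estimate
    table (see :func:`vaxsae.survey.direct_estimates`)."""
    de = direct_est
    if model_id == "D-UNWB":
        return fit_dunwb(
            de["y_raw"].to_numpy(float), de["n_raw"].to_numpy(float), X, graph,
            spec, seed, mcmc,
        )
    if model_id == "D-LN":
        return fit_dln(
            de["y_logit"].to_numpy(float), de["var_logit"].to_numpy(float), X, graph,
            spec, seed, mcmc,
        )
    if model_id == "D-ESS":
        return fit_dess(
            de["y_eff"].to_numpy(float), de["n_eff"].to_numpy(float), X, graph,
            spec, seed, mcmc,
        )
    raise ValueError(f"unknown discrete model {model_id!r}")
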