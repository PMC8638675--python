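"""Gibbs sampler shared by the discrete and continuous coverage models.

All five models have the same shape after whitening: a latent Gaussian
block u = (beta, z, ...) with a fixed diagonal prior, a small vector of
hyperparameters h on an unconstrained scale, and a likelihood that touches
u only through a linear predictor that depends on h via a whitening map.

One Gibbs sweep therefore alternates

  1. a Hamiltonian Monte Carlo update of u given h (hand-coded gradients;
     dual-averaging step-size adaptation and diagonal mass estimation
     during warmup), and
  2. coordinate-wise adaptive random-walk Metropolis updates of h given u
     (the latent prior is invariant to h because u is whitened, so the
     acceptance ratio involves only the likelihood and the hyperprior).

Convergence is summarized by split-R-hat and bulk effective sample size
(via ArviZ) on all scalar parameters; a fit whose worst R-hat exceeds the
threshold is returned with ``converged = False`` rather than an error.
"""

from __future__ import annotations

import abc
from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["MCMCConfig", "GibbsModel", "MCMCResult", "run_gibbs"]


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings. Defaults: 4 chains, 1000 warmup + 1000 kept."""

    n_chains: int = 4
    n_warmup: int = 1000
    n_keep: int = 1000
    n_leapfrog: int = 12
    target_accept: float = 0.8
    rhat_threshold: float = 1.01
    init_step_size: float = 0.1

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.n_warmup < 10 or self.n_keep < 1:
            raise ValueError("need >= 1 chain, >= 10 warmup and >= 1 kept draw")


class GibbsModel(abc.ABC):
    """Interface the model classes implement for :func:`run_gibbs`.

    Attributes
    ----------
    n_latent : int
        Dimension of the whitened latent block u.
    latent_prior_sd : (n_latent,) ndarray
        Prior sd of each component of u (1 for whitened fields, large for
        vague regression coefficients).
    hyper_names : list of str
        Names of the unconstrained hyperparameters, in order.
    """

    n_latent: int
    latent_prior_sd: np.ndarray
    hyper_names: list[str]

    @abc.abstractmethod
    def init_hyper(self, rng: np.random.Generator) -> np.ndarray: ...

    def init_latent(self, rng: np.random.Generator) -> np.ndarray:
        u = 0.1 * rng.standard_normal(self.n_latent)
        return u

    @abc.abstractmethod
    def make_cache(self, h: np.ndarray, prev: tuple | None = None) -> Any:
        """Precompute whitening structures for hyperparameters ``h``.

        ``prev = (h_old, cache_old)`` lets implementations reuse expensive
        factorizations when the proposal left the relevant coordinates
        unchanged (eg a pure variance rescaling).
        """

    @abc.abstractmethod
    def loglik(self, u: np.ndarray, cache: Any) -> float: ...

    @abc.abstractmethod
    def grad_loglik(self, u: np.ndarray, cache: Any) -> np.ndarray: ...

    @abc.abstractmethod
    def hyper_logprior(self, h: np.ndarray) -> float:
        """Log prior of h on the sampling scale (Jacobians included)."""

    @abc.abstractmethod
    def draw_record(self, u: np.ndarray, h: np.ndarray, cache: Any) -> dict:
        """Natural-scale quantities to store for one draw."""

    def diag_names(self) -> list[str]:
        """Record keys (scalars) entering the R-hat/ESS diagnostics."""
        return []

    def centered_transform(self, u, cache, cache_new):
        """Optional interleaved-parameterization (ASIS) support.

        Return ``(u_new, dlp)`` where ``u_new`` re-whitens the latent state
        so the *natural-scale* fields are preserved under the new
        hyperparameters, and ``dlp`` is the change in the centered prior
        log density (standard-normal density of the whitened coordinates
        minus the log determinant of the whitening map).  Hyperparameter
        proposals accepted under this ratio leave the likelihood untouched
        and mix scale/range parameters through the complementary geometry.
        Return ``None`` if unsupported.
        """
        return None


@dataclass
class MCMCResult:
    """Stacked posterior draws plus convergence diagnostics."""

    draws: dict[str, np.ndarray]  # (n_chains*n_keep, ...) each
    rhat: dict[str, float]
    ess: dict[str, float]
    converged: bool
    accept_hmc: float
    accept_hyper: np.ndarray
    n_chains: int
    n_keep: int

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values()) if self.rhat else float("nan")


def _logpost(model: GibbsModel, u: np.ndarray, cache: Any, prior_ivar: np.ndarray):
    return model.loglik(u, cache) - 0.5 * float(np.sum(u * u * prior_ivar))


def _grad_logpost(model, u, cache, prior_ivar):
    return model.grad_loglik(u, cache) - u * prior_ivar


def _hmc_step(model, u, cache, prior_ivar, eps, n_leap, inv_mass, rng):
    """One HMC transition; returns (u_new, accept_prob, cur_logpost)."""
    p0 = rng.standard_normal(u.shape) / np.sqrt(inv_mass)
    lp0 = _logpost(model, u, cache, prior_ivar)
    H0 = lp0 - 0.5 * float(np.sum(p0 * p0 * inv_mass))
    q, p = u.copy(), p0.copy()
    g = _grad_logpost(model, q, cache, prior_ivar)
    for _ in range(n_leap):
        p = p + 0.5 * eps * g
        q = q + eps * (inv_mass * p)
        g = _grad_logpost(model, q, cache, prior_ivar)
        p = p + 0.5 * eps * g
    lp1 = _logpost(model, q, cache, prior_ivar)
    H1 = lp1 - 0.5 * float(np.sum(p * p * inv_mass))
    dH = H1 - H0
    if not np.isfinite(dH):
        return u, 0.0, lp0
    a = min(1.0, float(np.exp(min(dH, 0.0))))
    if rng.random() < a:
        return q, a, lp1
    return u, a, lp0


class _DualAveraging:
    """Nesterov dual averaging of log step size toward a target acceptance."""

    def __init__(self, eps0: float, target: float):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.log_eps = np.log(eps0)
        self.log_eps_bar = np.log(eps0)
        self.h_bar = 0.0
        self.t = 0
        self.gamma, self.t0, self.kappa = 0.05, 10.0, 0.75

    def update(self, accept_prob: float) -> float:
        self.t += 1
        frac = 1.0 / (self.t + self.t0)
        self.h_bar = (1 - frac) * self.h_bar + frac * (self.target - accept_prob)
        self.log_eps = self.mu - np.sqrt(self.t) / self.gamma * self.h_bar
        w = self.t ** (-self.kappa)
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar
        return float(np.exp(self.log_eps))

    @property
    def final(self) -> float:
        return float(np.exp(self.log_eps_bar))


def _run_chain(model: GibbsModel, cfg: MCMCConfig, rng: np.random.Generator):
    prior_ivar = 1.0 / np.asarray(model.latent_prior_sd, dtype=float) ** 2
    fixed = getattr(model, "fixed_hyper", None)
    n_hyper = 0 if fixed is not None else len(model.hyper_names)
    u = model.init_latent(rng)
    h = np.asarray(fixed, dtype=float) if fixed is not None else model.init_hyper(rng)
    cache = model.make_cache(h)
    cur_ll = model.loglik(u, cache)
    cur_hlp = model.hyper_logprior(h)

    inv_mass = np.ones(model.n_latent)
    da = _DualAveraging(cfg.init_step_size, cfg.target_accept)
    eps = cfg.init_step_size
    # adaptive RW proposal log-sds for hyperparameters
    prop_lsd = np.full(n_hyper, np.log(0.3))
    cent_lsd = np.full(n_hyper, np.log(0.3))
    use_centered = (
        n_hyper > 0
        and model.centered_transform(u, cache, cache) is not None
    )
    hyper_acc = np.zeros(n_hyper)
    hyper_try = np.zeros(n_hyper)
    hmc_acc_sum = 0.0
    hmc_n = 0

    records: list[dict] = []
    mass_window: list[np.ndarray] = []
    half = cfg.n_warmup // 2

    for it in range(cfg.n_warmup + cfg.n_keep):
        warm = it < cfg.n_warmup
        u, a, _ = _hmc_step(
            model, u, cache, prior_ivar, eps, cfg.n_leapfrog, inv_mass, rng
        )
        if warm:
            eps = da.update(a)
            if cfg.n_warmup // 4 <= it < half:
                mass_window.append(u.copy())
            if it == half and len(mass_window) >= 10:
                var = np.var(np.asarray(mass_window), axis=0)
                inv_mass = np.clip(var, 1e-4, 1e4)
                da = _DualAveraging(da.final, cfg.target_accept)
                eps = da.final
        else:
            eps = da.final
            hmc_acc_sum += a
            hmc_n += 1
        cur_ll = model.loglik(u, cache)

        for j in range(n_hyper):
            h_prop = h.copy()
            h_prop[j] += np.exp(prop_lsd[j]) * rng.standard_normal()
            try:
                cache_prop = model.make_cache(h_prop, prev=(h, cache))
                prop_ll = model.loglik(u, cache_prop)
                prop_hlp = model.hyper_logprior(h_prop)
                log_r = (prop_ll + prop_hlp) - (cur_ll + cur_hlp)
            except (np.linalg.LinAlgError, FloatingPointError, OverflowError):
                log_r = -np.inf
            a_j = float(np.exp(min(log_r, 0.0))) if np.isfinite(log_r) else 0.0
            if rng.random() < a_j:
                h, cache, cur_ll, cur_hlp = h_prop, cache_prop, prop_ll, prop_hlp
            if warm:
                prop_lsd[j] += (a_j - 0.44) / np.sqrt(1.0 + it)
            else:
                hyper_acc[j] += a_j
                hyper_try[j] += 1

        # interleaved centered-parameterization sweep: same hyperparameters,
        # complementary geometry (the natural-scale field held fixed)
        if use_centered:
            for j in range(n_hyper):
                h_prop = h.copy()
                h_prop[j] += np.exp(cent_lsd[j]) * rng.standard_normal()
                try:
                    cache_prop = model.make_cache(h_prop, prev=(h, cache))
                    out = model.centered_transform(u, cache, cache_prop)
                    u_prop, dlp = out
                    log_r = dlp + model.hyper_logprior(h_prop) - cur_hlp
                except (np.linalg.LinAlgError, FloatingPointError, OverflowError):
                    log_r = -np.inf
                a_j = float(np.exp(min(log_r, 0.0))) if np.isfinite(log_r) else 0.0
                if rng.random() < a_j:
                    u, h, cache = u_prop, h_prop, cache_prop
                    cur_hlp = model.hyper_logprior(h)
                    cur_ll = model.loglik(u, cache)
                if warm:
                    cent_lsd[j] += (a_j - 0.44) / np.sqrt(1.0 + it)

        if not warm:
            records.append(model.draw_record(u, h, cache))

    return records, hmc_acc_sum / max(hmc_n, 1), hyper_acc / np.maximum(hyper_try, 1)


def _stack(records_by_chain: list[list[dict]]) -> dict[str, np.ndarray]:
    keys = records_by_chain[0][0].keys()
    out = {}
    for k in keys:
        rows = [np.asarray(rec[k]) for recs in records_by_chain for rec in recs]
        out[k] = np.stack(rows, axis=0)
    return out


def run_gibbs(
    model: GibbsModel, cfg: MCMCConfig, seed: int
) -> MCMCResult:
    """Run the Gibbs sampler for ``model`` and return stacked draws.

    Chains receive independent substreams of ``seed``; the run is
    deterministic given (model data, cfg, seed).
    """
    import arviz as az

    records_by_chain = []
    hmc_accs, hyper_accs = [], []
    for c in range(cfg.n_chains):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, c]))
        recs, a_hmc, a_hyp = _run_chain(model, cfg, rng)
        records_by_chain.append(recs)
        hmc_accs.append(a_hmc)
        hyper_accs.append(a_hyp)

    draws = _stack(records_by_chain)

    rhat: dict[str, float] = {}
    ess: dict[str, float] = {}
    diag = {}
    for name in model.diag_names():
        arr = draws[name].reshape(cfg.n_chains, cfg.n_keep)
        diag[name] = arr
    if diag and cfg.n_chains * cfg.n_keep >= 4:
        ds = az.convert_to_dataset(diag)
        r = az.rhat(ds)
        e = az.ess(ds)
        for name in diag:
            rhat[name] = float(r[name].values)
            ess[name] = float(e[name].values)
    converged = bool(all(np.isnan(v) or v < cfg.rhat_threshold for v in rhat.values()))

    return MCMCResult(
        draws=draws,
        rhat=rhat,
        ess=ess,
        converged=converged,
        accept_hmc=float(np.mean(hmc_accs)),
        accept_hyper=np.mean(np.asarray(hyper_accs), axis=0),
        n_chains=cfg.n_chains,
        n_keep=cfg.n_keep,
    )
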