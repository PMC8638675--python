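"""Structural checks of the discrete model fits.

The quantitative oracle-equivalence checks (brute-force posterior
integration) live in test_acceptance.py; here we test invariances,
missing-data handling and information monotonicity on small fixtures.
"""

import numpy as np
import pytest

from vaxsae.car import AdjacencyGraph
from vaxsae.discrete import (
    DiscreteModelSpec,
    fit_dess,
    fit_discrete,
    fit_dln,
    fit_dunwb,
)
from vaxsae.mcmc import MCMCConfig

from conftest import W_PATH3

CFG = MCMCConfig(n_chains=2, n_warmup=400, n_keep=400)


@pytest.fixture(scope="module")
def graph():
    return AdjacencyGraph(W_PATH3)


X3 = np.ones((3, 1))


def test_single_district_symmetric_counts(quick_mcmc):
    """One district, y = n/2: the posterior of p is symmetric around 1/2."""
    g = AdjacencyGraph(np.zeros((1, 1)))
    fit = fit_dunwb(np.array([5.0]), np.array([10.0]), np.ones((1, 1)), g,
                    seed=4, mcmc=CFG)
    assert fit.p_district.mean() == pytest.approx(0.5, abs=0.02)


def test_label_equivariance(graph):
    """Permuting district order permutes the posterior summaries."""
    y = np.array([5.0, 9.0, 3.0])
    n = np.array([10.0, 12.0, 8.0])
    cfg = MCMCConfig(n_chains=2, n_warmup=800, n_keep=800)
    fit = fit_dunwb(y, n, X3, graph, seed=7, mcmc=cfg)
    perm = [2, 1, 0]  # reversing a path graph keeps the same adjacency
    fit_p = fit_dunwb(y[perm], n[perm], X3, graph, seed=7, mcmc=cfg)
    assert np.allclose(
        fit.p_district.mean(axis=0)[perm], fit_p.p_district.mean(axis=0), atol=0.03
    )


def test_dln_known_variance_point_mass_limit(graph):
    """As var_Y -> 0 the posterior of eta collapses onto Y_L."""
    y_logit = np.array([0.4, -0.2, 0.8])
    var = np.full(3, 1e-8)
    fit = fit_dln(y_logit, var, X3, graph, seed=3, mcmc=CFG)
    eta = fit.draws["eta"]
    assert np.allclose(eta.mean(axis=0), y_logit, atol=1e-3)
    assert np.all(eta.std(axis=0) < 1e-3)


def test_dln_missing_district_gets_predictive(graph):
    """A boundary district (missing Y_L) receives finite coverage draws
    with spread at least that of its observed neighbours."""
    y_logit = np.array([0.3, -0.4, np.nan])
    var = np.array([0.15, 0.25, np.nan])
    fit = fit_dln(y_logit, var, X3, graph, seed=5, mcmc=CFG)
    assert fit.missing.tolist() == [False, False, True]
    p = fit.p_district
    assert np.all(np.isfinite(p)) and np.all((p > 0) & (p < 1))
    assert p[:, 2].std() >= max(p[:, 0].std(), p[:, 1].std())


def test_dln_missing_district_matches_quadrature(graph):
    """Coverage means (including the imputed district) against brute-force
    integration of the exact posterior (tests/oracles.py, district 2
    response removed)."""
    oracle = np.array([0.54997474, 0.44200069, 0.47824165])
    # the imputed district's predictive is heavy-tailed (prior-only phi
    # under a fat-tailed precision prior), so its mean needs long chains
    fit = fit_dln(
        np.array([0.3, -0.4, np.nan]), np.array([0.15, 0.25, np.nan]), X3, graph,
        seed=23, mcmc=MCMCConfig(n_chains=4, n_warmup=1500, n_keep=4000),
    )
    assert np.max(np.abs(fit.p_district.mean(axis=0) - oracle)) < 0.01


def test_dln_all_missing_rejected(graph):
    with pytest.raises(ValueError, match="unidentifiable"):
        fit_dln(np.full(3, np.nan), np.full(3, np.nan), X3, graph, seed=0, mcmc=CFG)


def test_dess_matches_dunwb_under_srs(graph):
    """With N_E = N and Y_E = Y the effective-sample-size model is the
    unweighted binomial model; marginals agree within Monte-Carlo error."""
    y = np.array([5.0, 9.0, 3.0])
    n = np.array([10.0, 12.0, 8.0])
    cfg = MCMCConfig(n_chains=2, n_warmup=800, n_keep=800)
    f1 = fit_dunwb(y, n, X3, graph, seed=11, mcmc=cfg)
    f2 = fit_dess(y, n, X3, graph, seed=11, mcmc=cfg)
    assert np.allclose(
        f1.p_district.mean(axis=0), f2.p_district.mean(axis=0), atol=0.015
    )
    assert np.allclose(
        f1.p_district.std(axis=0), f2.p_district.std(axis=0), atol=0.02
    )


def test_dess_noninteger_counts_accepted(graph):
    fit = fit_dess(
        np.array([6.4, 21.3, 11.9]), np.array([11.2, 30.6, 17.0]), X3, graph,
        seed=2, mcmc=CFG,
    )
    assert np.all((fit.p_district > 0) & (fit.p_district < 1))


def test_monotone_information_dln(graph):
    """Inflating one district's known variance widens its coverage
    posterior."""
    y_logit = np.array([0.3, -0.4, 0.9])
    var_lo = np.array([0.15, 0.25, 0.2])
    var_hi = var_lo.copy()
    var_hi[1] = 2.5
    cfg = MCMCConfig(n_chains=2, n_warmup=600, n_keep=600)
    f_lo = fit_dln(y_logit, var_lo, X3, graph, seed=13, mcmc=cfg)
    f_hi = fit_dln(y_logit, var_hi, X3, graph, seed=13, mcmc=cfg)
    assert f_hi.p_district[:, 1].std() > f_lo.p_district[:, 1].std()


def test_decoupling_at_iid_limit(graph):
    """With rho pinned near 0 and a wide phi scale, a district's posterior
    ignores other districts' data."""
    fix = np.array([-30.0, np.log(8.0)])  # logit rho, log sigma_phi
    y_a = np.array([5.0, 9.0, 3.0])
    y_b = np.array([5.0, 1.0, 7.0])  # districts 1 and 2 perturbed
    n = np.array([10.0, 12.0, 8.0])
    cfg = MCMCConfig(n_chains=2, n_warmup=800, n_keep=800)
    f_a = fit_dunwb(y_a, n, X3, graph, seed=17, mcmc=cfg, fix_hyper=fix)
    f_b = fit_dunwb(y_b, n, X3, graph, seed=17, mcmc=cfg, fix_hyper=fix)
    assert abs(
        f_a.p_district[:, 0].mean() - f_b.p_district[:, 0].mean()
    ) < 0.02


def test_draws_respect_domains(graph):
    fit = fit_dunwb(np.array([5.0, 9.0, 3.0]), np.array([10.0, 12.0, 8.0]), X3,
                    graph, seed=1, mcmc=CFG)
    assert np.all((fit.draws["rho"] > 0) & (fit.draws["rho"] < 1))
    assert np.all(fit.draws["sigma2_phi"] > 0)
    assert np.all((fit.p_district > 0) & (fit.p_district < 1))


def test_dispatch_and_spec_validation(graph, small_country):
    with pytest.raises(ValueError, match="unknown"):
        fit_discrete("D-XXX", None, X3, graph)
    with pytest.raises(ValueError):
        DiscreteModelSpec(model_id="bogus")
    with pytest.raises(ValueError):
        DiscreteModelSpec(var_beta=-1.0)


def test_y_exceeding_n_rejected(graph):
    with pytest.raises(ValueError, match="exceed"):
        fit_dunwb(np.array([11.0, 1.0, 1.0]), np.array([10.0, 12.0, 8.0]), X3,
                  graph, seed=0, mcmc=CFG)
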