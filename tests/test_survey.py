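"""Design-based estimators: weight normalization, HT estimate, transforms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from vaxsae.survey import (
    direct_estimate,
    direct_estimates,
    effective_sample_size,
    empirical_logit,
    normalize_weights,
)


def _table(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id",
            "district_id",
            "stratum",
            "n_children",
            "n_vaccinated",
            "weight",
        ],
    )


class TestNormalizeWeights:
    def test_equal_weights_normalize_to_one(self):
        t = _table([(0, 0, "u", 10, 5, 3.0), (1, 0, "r", 10, 4, 3.0)])
        out = normalize_weights(t)
        assert np.allclose(out["w_norm"], 1.0)

    def test_two_cluster_hand_computation(self):
        # district total N = 20; sum w_k N_k = 2*10 + 4*10 = 60
        # normalized per-child weights: 2*20/60 = 2/3 and 4*20/60 = 4/3
        t = _table([(0, 0, "u", 10, 5, 2.0), (1, 0, "r", 10, 4, 4.0)])
        out = normalize_weights(t)
        assert np.allclose(out["w_norm"], [2 / 3, 4 / 3])
        assert (out["w_norm"] * out["n_children"]).sum() == pytest.approx(20.0)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_uniform_rescaling(self, scale):
        t = _table([(0, 0, "u", 12, 5, 1.5), (1, 0, "r", 8, 4, 2.5)])
        base = normalize_weights(t)["w_norm"].to_numpy()
        t2 = t.copy()
        t2["weight"] *= scale
        assert np.allclose(normalize_weights(t2)["w_norm"], base)

    def test_positive_weights_required(self):
        t = _table([(0, 0, "u", 10, 5, 0.0)])
        with pytest.raises(ValueError, match="positive"):
            normalize_weights(t)


class TestDirectEstimate:
    def test_equal_weights_give_raw_proportion(self):
        t = _table(
            [(0, 0, "u", 10, 7, 1.0), (1, 0, "u", 15, 6, 1.0), (2, 0, "r", 5, 5, 1.0)]
        )
        p, _ = direct_estimate(normalize_weights(t))
        assert p == pytest.approx(18 / 30)

    def test_identical_cluster_proportions_zero_variance(self):
        t = _table(
            [(0, 0, "u", 10, 4, 1.0), (1, 0, "u", 20, 8, 2.0), (2, 0, "u", 5, 2, 1.5)]
        )
        p, v = direct_estimate(normalize_weights(t))
        assert p == pytest.approx(0.4)
        assert v == pytest.approx(0.0, abs=1e-24)

    def test_matches_independent_linearization_oracle(self):
        """3 clusters, weights (1,1,2), proportions (.2,.4,.6), N=10 each,
        single stratum — against a from-scratch implementation of the
        with-replacement linearized ratio variance."""
        t = _table(
            [
                (0, 0, "s", 10, 2, 1.0),
                (1, 0, "s", 10, 4, 1.0),
                (2, 0, "s", 10, 6, 2.0),
            ]
        )
        p, v = direct_estimate(normalize_weights(t))

        # oracle, written directly from the standard formula on raw weights
        # (the ratio estimator is scale-invariant so normalization is moot)
        w = np.array([1.0, 1.0, 2.0])
        yk = np.array([2.0, 4.0, 6.0])
        nk = np.array([10.0, 10.0, 10.0])
        p_or = np.sum(w * yk) / np.sum(w * nk)
        z = w * (yk - p_or * nk) / np.sum(w * nk)
        n_psu = 3
        v_or = n_psu / (n_psu - 1) * np.sum((z - z.mean()) ** 2)
        assert p == pytest.approx(p_or)
        assert v == pytest.approx(v_or, rel=1e-12)

    def test_scale_invariance_of_estimate(self):
        t = _table([(0, 0, "u", 10, 3, 1.0), (1, 0, "r", 12, 9, 2.0)])
        p1, v1 = direct_estimate(normalize_weights(t))
        t2 = t.copy()
        t2["weight"] *= 13.7
        p2, v2 = direct_estimate(normalize_weights(t2))
        assert p1 == pytest.approx(p2)
        assert v1 == pytest.approx(v2)

    def test_single_cluster_variance_undefined(self):
        t = _table([(0, 0, "u", 10, 3, 1.0)])
        p, v = direct_estimate(normalize_weights(t))
        assert p == pytest.approx(0.3)
        assert np.isnan(v)

    def test_single_psu_stratum_collapsed(self):
        # one urban cluster + two rural: collapse makes variance computable
        t = _table(
            [(0, 0, "u", 10, 5, 1.0), (1, 0, "r", 10, 4, 1.0), (2, 0, "r", 10, 6, 1.0)]
        )
        _, v = direct_estimate(normalize_weights(t))
        assert np.isfinite(v) and v >= 0


class TestTransforms:
    def _est(self, p, v):
        return pd.DataFrame(
            {
                "district_id": range(len(p)),
                "p_hat_dir": p,
                "var_p_dir": v,
                "boundary_flag": [x in (0.0, 1.0) for x in p],
            }
        )

    def test_empirical_logit_hand_values(self):
        out = empirical_logit(self._est([0.5], [0.01]))
        assert out["y_logit"].iloc[0] == pytest.approx(0.0)
        assert out["var_logit"].iloc[0] == pytest.approx(0.16)  # 0.01 / 0.25^2

    def test_boundary_estimate_flagged_missing(self):
        out = empirical_logit(self._est([1.0], [0.02]))
        assert out["boundary_flag"].iloc[0]
        assert np.isnan(out["y_logit"].iloc[0])
        assert np.isnan(out["var_logit"].iloc[0])

    def test_logit_inverse_identity(self):
        e = np.e
        out = empirical_logit(self._est([e / (1 + e)], [0.01]))
        assert out["y_logit"].iloc[0] == pytest.approx(1.0)

    def test_roundtrip_expit(self):
        p = [0.12, 0.5, 0.87]
        out = empirical_logit(self._est(p, [0.01] * 3))
        assert np.allclose(expit(out["y_logit"]), p)

    def test_effective_sample_size_hand_values(self):
        out = effective_sample_size(self._est([0.5], [0.0025]))
        assert out["n_eff"].iloc[0] == pytest.approx(100.0)
        assert out["y_eff"].iloc[0] == pytest.approx(50.0)

    def test_zero_variance_flagged_missing(self):
        out = effective_sample_size(self._est([0.5], [0.0]))
        assert np.isnan(out["n_eff"].iloc[0])


class TestEffectiveSampleSizeDesigns:
    def test_srs_recovers_raw_sample_size(self):
        """Every child its own PSU with equal weights: the linearized
        variance is the SRS variance up to n/(n-1), so N_E ~ N within 5%."""
        rng = np.random.default_rng(4)
        n = 400
        y = rng.binomial(1, 0.6, size=n)
        t = _table([(k, 0, "s", 1, int(y[k]), 1.0) for k in range(n)])
        est = direct_estimates(t)
        assert est["n_eff"].iloc[0] == pytest.approx(n, rel=0.05)

    def test_perfect_within_cluster_correlation_collapses_to_clusters(self):
        """ICC ~ 1 (identical outcomes within cluster): N_E tracks the
        number of clusters, not the number of children."""
        rows = []
        for k in range(20):
            y = 10 if k % 2 == 0 else 0
            rows.append((k, 0, "s", 10, y, 1.0))
        est = direct_estimates(_table(rows))
        n_eff = est["n_eff"].iloc[0]
        assert n_eff == pytest.approx(20, rel=0.1)
        assert n_eff < 30  # far below the 200 children


def test_design_effect_bounds_on_simulated_survey(small_country):
    """Monitored property: with positive ICC the effective sample size
    should not exceed the raw count by much (design effect >= 1)."""
    est = direct_estimates(small_country.clusters)
    ok = est["n_eff"].notna()
    ratio = est.loc[ok, "n_eff"] / est.loc[ok, "n_raw"]
    # districts with few clusters have noisy variance estimates, so this is
    # a loose monitored bound, not an exact inequality
    assert (ratio <= 2.0).all()
    assert ratio.median() <= 1.05


def test_full_table_roundtrip_consistency(small_country):
    est = direct_estimates(small_country.clusters)
    ok = ~est["boundary_flag"] & est["y_logit"].notna()
    assert np.allclose(
        expit(est.loc[ok, "y_logit"]), est.loc[ok, "p_hat_dir"], atol=1e-12
    )
    assert (est["y_raw"] <= est["n_raw"]).all()
    assert (est.loc[est["y_eff"].notna(), "y_eff"] <= est.loc[est["y_eff"].notna(), "n_eff"]).all()
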