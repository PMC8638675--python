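"""Synthetic country generator: structure, determinism, statistical checks."""

import numpy as np
import pandas as pd
import pytest

from vaxsae.matern import MaternParams, matern_covariance
from vaxsae.synthetic import (
    ConfigError,
    CountryConfig,
    GridSurface,
    generate_country,
    simulate_latent_surface,
    simulate_survey,
    true_district_coverage,
)


def _bare_grid(xy, n_cov=0):
    n = xy.shape[0]
    return GridSurface(
        xy=xy,
        res_km=1.0,
        district=np.zeros(n, dtype=int),
        pop=np.ones(n),
        q=np.full(n, 1.0 / n),
        covariates=pd.DataFrame(
            {f"x{i+1}": np.zeros(n) for i in range(n_cov)}, index=range(n)
        ),
    )


class TestGenerateCountry:
    def test_cluster_count_and_district_floor(self):
        cfg = CountryConfig(
            n_districts=4, extent_km=(120.0, 120.0), n_clusters_total=40, seed=1
        )
        country = generate_country(cfg)
        assert len(country.clusters) == 40
        per_district = country.clusters.groupby("district_id").size()
        assert (per_district >= 2).all()

    def test_deterministic_given_seed(self):
        cfg = CountryConfig(
            n_districts=4, extent_km=(120.0, 120.0), n_clusters_total=40, seed=1
        )
        a, b = generate_country(cfg), generate_country(cfg)
        assert a.clusters.equals(b.clusters)
        assert np.array_equal(a.truth["p_true"], b.truth["p_true"])
        assert np.array_equal(a.grid.q, b.grid.q)
        assert np.array_equal(a.districts.graph.W, b.districts.graph.W)

    def test_population_shares_normalized_per_district(self):
        cfg = CountryConfig(
            n_districts=30,
            extent_km=(600.0, 900.0),
            grid_res_km=15.0,
            n_clusters_total=90,
            seed=2,
        )
        country = generate_country(cfg)
        for i in range(30):
            s = country.grid.q[country.grid.district == i].sum()
            assert abs(s - 1.0) <= 1e-12

    def test_districts_partition_grid(self, small_country):
        d = small_country.grid.district
        assert d.min() >= 0 and d.max() < small_country.districts.n
        # every cell assigned exactly once by construction (single label array)
        assert d.shape[0] == small_country.grid.n

    def test_clusters_inside_their_district_polygon(self, small_country):
        import shapely

        for _, row in small_country.clusters.iterrows():
            poly = small_country.districts.polygons[int(row["district_id"])]
            pt = shapely.points(row["x_km"], row["y_km"])
            assert poly.covers(pt)

    def test_both_strata_present_everywhere(self, small_country):
        strata = small_country.clusters.groupby("district_id")["stratum"].nunique()
        assert (strata == 2).all()

    def test_too_many_clusters_rejected(self):
        with pytest.raises(ConfigError, match="cluster"):
            generate_country(
                CountryConfig(
                    n_districts=2,
                    extent_km=(20.0, 20.0),
                    grid_res_km=5.0,
                    n_clusters_total=100,
                    seed=0,
                )
            )


class TestLatentSurface:
    def test_zero_sd_degenerates_to_covariate_surface(self):
        rng = np.random.default_rng(0)
        grid = _bare_grid(rng.uniform(0, 100, (50, 2)))
        out = simulate_latent_surface(grid, (0.0, 150.0), (0.3,), seed=9)
        from scipy.special import expit

        assert np.allclose(out["p_true"], expit(0.3))
        assert np.allclose(out["omega"], 0.0)

    def test_marginal_variance_recovered_over_replicates(self):
        """Sample variance of omega across >= 200 replicate draws ~ sigma^2."""
        rng = np.random.default_rng(1)
        xy = rng.uniform(0, 400, (200, 2))
        grid = _bare_grid(xy)
        draws = np.stack(
            [
                simulate_latent_surface(grid, (0.5, 200.0), (0.0,), seed=s)["omega"]
                for s in range(250)
            ]
        )
        # average the per-cell across-replicate variance
        var = draws.var(axis=0, ddof=1).mean()
        se = 0.25 * np.sqrt(2.0 / 249)  # rough MC error of a variance estimate
        assert abs(var - 0.25) < 4 * se

    def test_nearby_cells_nearly_perfectly_correlated(self):
        grid = _bare_grid(np.array([[0.0, 0.0], [1.0, 0.0]]))
        draws = np.stack(
            [
                simulate_latent_surface(grid, (1.0, 500.0), (0.0,), seed=s)["omega"]
                for s in range(500)
            ]
        )
        corr = np.corrcoef(draws[:, 0], draws[:, 1])[0, 1]
        assert corr > 0.99

    def test_probabilities_in_unit_interval(self, small_country):
        p = small_country.truth["p_true"]
        assert np.all((p > 0) & (p < 1))

    def test_variogram_monotone_up_to_range(self):
        """Binned empirical variogram of omega increases with distance,
        averaged over >= 100 replicates."""
        rng = np.random.default_rng(5)
        xy = rng.uniform(0, 200, (60, 2))
        grid = _bare_grid(xy)
        r = 150.0
        diffs2 = np.zeros((60, 60))
        for s in range(120):
            om = simulate_latent_surface(grid, (1.0, r), (0.0,), seed=1000 + s)["omega"]
            diffs2 += (om[:, None] - om[None, :]) ** 2
        diffs2 /= 120
        d = np.linalg.norm(xy[:, None] - xy[None, :], axis=2)
        iu = np.triu_indices(60, 1)
        bins = np.linspace(0, r, 7)
        idx = np.digitize(d[iu], bins)
        gamma = [
            diffs2[iu][idx == k].mean() for k in range(1, 7) if np.any(idx == k)
        ]
        assert all(b >= a - 1e-3 for a, b in zip(gamma, gamma[1:]))


class TestSurvey:
    def test_unbiased_counts_without_nugget(self):
        """With a constant p=0.5 surface and no nugget, the pooled
        vaccination fraction over 1000 clusters sits within 3 binomial
        standard errors of 0.5."""
        cfg = CountryConfig(
            n_districts=10,
            extent_km=(350.0, 350.0),
            grid_res_km=10.0,
            n_clusters_total=1000,
            children_per_cluster=(20, 20),
            nugget_sd=0.0,
            gp_params=(0.6, 150.0),
            seed=11,
        )
        country = generate_country(cfg)
        country.truth["logit_p"] = np.zeros(country.grid.n)  # p_true = 0.5
        clusters = simulate_survey(country, cfg)
        frac = clusters["n_vaccinated"].sum() / clusters["n_children"].sum()
        se = 0.5 / np.sqrt(1000 * 20)
        assert abs(frac - 0.5) < 3 * se

    def test_equal_population_gives_equal_weights_within_stratum(self):
        cfg = CountryConfig(
            n_districts=5, extent_km=(120.0, 120.0), n_clusters_total=50, seed=8
        )
        country = generate_country(cfg)
        grid = country.grid
        grid.pop = np.ones(grid.n)
        for i in range(country.districts.n):
            m = grid.district == i
            grid.q[m] = 1.0 / m.sum()
        clusters = simulate_survey(country, country.config)
        for (_, _), g in clusters.groupby(["district_id", "stratum"]):
            assert np.allclose(g["weight"], g["weight"].iloc[0])

    def test_minimum_two_children_per_cluster(self, small_country):
        assert (small_country.clusters["n_children"] >= 2).all()

    def test_urban_oversampling_lowers_urban_weights(self, small_country):
        cl = small_country.clusters
        med = cl.groupby("stratum")["weight"].median()
        assert med["urban"] < med["rural"]


def test_true_coverage_constant_surface(small_country):
    country = small_country
    saved = country.truth["p_true"]
    try:
        country.truth["p_true"] = np.full(country.grid.n, 0.7)
        agg = true_district_coverage(country)
        assert np.allclose(agg, 0.7)
        assert np.all((agg > 0) & (agg < 1))
    finally:
        country.truth["p_true"] = saved


def test_invalid_configs_rejected():
    with pytest.raises(ConfigError):
        CountryConfig(n_districts=1)
    with pytest.raises(ConfigError):
        CountryConfig(urban_fraction=1.5)
    with pytest.raises(ConfigError):
        CountryConfig(children_per_cluster=(0, 1))
    with pytest.raises(ConfigError):
        CountryConfig(gp_params=(0.5, -10.0))
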