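"""File formats and the end-to-end study pipeline.

Tables travel as CSV, districts as GeoJSON (polygon features carrying the
adjacency list as a property), the grid as a CSV of cell centroids, and
posterior draws as self-describing netCDF via xarray.  ``run_study`` wires
the whole design together on a synthetic country: generate, compute direct
estimates, fit every requested model, aggregate, map exceedance
probabilities and (optionally) run the leave-one-district-out comparison,
recording seeds and versions in a manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml
from shapely.geometry import mapping as shp_mapping
from shapely.geometry import shape as shp_shape

from . import __version__
from .aggregation import (
    DEFAULT_THRESHOLDS,
    aggregate_surface,
    summarize_districts,
)
from .car import AdjacencyGraph
from .continuous import GPFit, PosteriorSurface, fit_gp, predict_surface
from .discrete import DISCRETE_MODELS, PosteriorFit, fit_discrete
from .evaluation import ALL_MODELS, run_comparison
from .matern import PCPriorSpec
from .mcmc import MCMCConfig
from .survey import direct_estimates
from .synthetic import (
    CLUSTER_COLUMNS,
    CountryConfig,
    DistrictFrame,
    GridSurface,
    SyntheticCountry,
    generate_country,
)

__all__ = [
    "read_cluster_table",
    "write_cluster_table",
    "read_districts",
    "write_districts",
    "read_grid",
    "write_grid",
    "write_estimates",
    "read_estimates",
    "save_surface",
    "load_surface",
    "save_gpfit",
    "load_gpfit",
    "save_discrete_fit",
    "StudyConfig",
    "load_study_config",
    "run_study",
]

log = logging.getLogger("vaxsae")


# ---------------------------------------------------------------- tables

def read_cluster_table(path) -> pd.DataFrame:
    """Load a cluster CSV, enforcing the schema and the N >= 2 filter.

    Clusters where at most one child was surveyed are excluded (standard
    survey practice), with the excluded count logged.
    """
    df = pd.read_csv(path)
    missing = [c for c in CLUSTER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cluster table at {path} lacks columns: {missing}")
    small = df["n_children"] <= 1
    if small.any():
        warnings.warn(
            f"excluding {int(small.sum())} cluster(s) with <= 1 child surveyed",
            stacklevel=2,
        )
        log.info("excluded %d clusters with N <= 1", int(small.sum()))
        df = df[~small].reset_index(drop=True)
    return df


def write_cluster_table(clusters: pd.DataFrame, path) -> None:
    clusters.to_csv(path, index=False)


def write_estimates(est: pd.DataFrame, path) -> None:
    """District-level estimates as CSV; missing values as empty fields."""
    est.to_csv(path, index=False)


def read_estimates(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ------------------------------------------------------------- districts

def write_districts(districts: DistrictFrame, path) -> None:
    """GeoJSON FeatureCollection; adjacency embedded as a neighbor list."""
    W = districts.graph.W
    features = []
    for i, poly in enumerate(districts.polygons):
        features.append(
            {
                "type": "Feature",
                "geometry": shp_mapping(poly),
                "properties": {
                    "district_id": districts.ids[i],
                    "neighbors": [districts.ids[j] for j in np.flatnonzero(W[i])],
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_districts(path) -> DistrictFrame:
    with open(path) as fh:
        gj = json.load(fh)
    feats = sorted(gj["features"], key=lambda f: f["properties"]["district_id"])
    polys = [shp_shape(f["geometry"]) for f in feats]
    ids = [f["properties"]["district_id"] for f in feats]
    pos = {d: k for k, d in enumerate(ids)}
    W = np.zeros((len(ids), len(ids)))
    for k, f in enumerate(feats):
        for nb in f["properties"]["neighbors"]:
            W[k, pos[nb]] = W[pos[nb], k] = 1.0
    return DistrictFrame(polygons=polys, graph=AdjacencyGraph(W, ids=ids))


# ------------------------------------------------------------------ grid

def write_grid(grid: GridSurface, path) -> None:
    df = pd.DataFrame(
        {
            "x_km": grid.xy[:, 0],
            "y_km": grid.xy[:, 1],
            "district": grid.district,
            "pop": grid.pop,
            "q": grid.q,
        }
    )
    for c in grid.covariates.columns:
        df[c] = grid.covariates[c].to_numpy()
    df.attrs["res_km"] = grid.res_km
    df.insert(0, "res_km", grid.res_km)
    df.to_csv(path, index=False)


def read_grid(path) -> GridSurface:
    df = pd.read_csv(path)
    cov_cols = [c for c in df.columns if c.startswith("x") and c not in ("x_km",)]
    return GridSurface(
        xy=df[["x_km", "y_km"]].to_numpy(),
        res_km=float(df["res_km"].iloc[0]),
        district=df["district"].to_numpy(),
        pop=df["pop"].to_numpy(),
        q=df["q"].to_numpy(),
        covariates=df[cov_cols],
    )


# ------------------------------------------------------- posterior draws

def save_surface(surface: PosteriorSurface, path) -> None:
    ds = xr.Dataset(
        {"p": (("draw", "cell"), surface.p)},
        coords={
            "x_km": ("cell", surface.xy[:, 0]),
            "y_km": ("cell", surface.xy[:, 1]),
        },
        attrs={"model_id": surface.model_id},
    )
    ds.to_netcdf(path, engine="scipy")


def load_surface(path) -> PosteriorSurface:
    with xr.open_dataset(path, engine="scipy") as ds:
        return PosteriorSurface(
            p=ds["p"].values,
            xy=np.column_stack([ds["x_km"].values, ds["y_km"].values]),
            model_id=ds.attrs.get("model_id", ""),
        )


def save_gpfit(fit: GPFit, path) -> None:
    data = {
        "beta": (("draw", "coef"), fit.draws["beta"]),
        "beta_std": (("draw", "coef"), fit.draws["beta_std"]),
        "omega": (("draw", "cluster"), fit.draws["omega"]),
    }
    for k in ("sigma2_omega", "range_r", "sigma2_eps"):
        data[k] = (("draw",), np.asarray(fit.draws[k], dtype=float))
    ds = xr.Dataset(
        data,
        coords={
            "cluster_x": ("cluster", fit.coords[:, 0]),
            "cluster_y": ("cluster", fit.coords[:, 1]),
        },
        attrs={
            "model_id": fit.model_id,
            "x_mean": fit.x_mean.tolist(),
            "x_scale": fit.x_scale.tolist(),
            "converged": int(fit.converged),
            "rhat": json.dumps(fit.rhat),
            "ess": json.dumps(fit.ess),
        },
    )
    ds.to_netcdf(path, engine="scipy")


def load_gpfit(path) -> GPFit:
    with xr.open_dataset(path, engine="scipy") as ds:
        draws = {
            "beta": ds["beta"].values,
            "beta_std": ds["beta_std"].values,
            "omega": ds["omega"].values,
            "sigma2_omega": ds["sigma2_omega"].values,
            "range_r": ds["range_r"].values,
            "sigma2_eps": ds["sigma2_eps"].values,
        }
        return GPFit(
            model_id=ds.attrs["model_id"],
            coords=np.column_stack([ds["cluster_x"].values, ds["cluster_y"].values]),
            draws=draws,
            x_mean=np.asarray(ds.attrs["x_mean"], dtype=float),
            x_scale=np.asarray(ds.attrs["x_scale"], dtype=float),
            rhat=json.loads(ds.attrs["rhat"]),
            ess=json.loads(ds.attrs["ess"]),
            converged=bool(ds.attrs["converged"]),
        )


def save_discrete_fit(fit: PosteriorFit, path) -> None:
    ds = xr.Dataset(
        {
            "p_district": (("draw", "district"), fit.p_district),
            "beta": (("draw", "coef"), fit.draws["beta"]),
            "beta_std": (("draw", "coef"), fit.draws["beta_std"]),
            "phi": (("draw", "district"), fit.draws["phi"]),
            "rho": (("draw",), np.asarray(fit.draws["rho"], dtype=float)),
            "sigma2_phi": (("draw",), np.asarray(fit.draws["sigma2_phi"], dtype=float)),
        },
        coords={"district": ("district", np.asarray(fit.district_ids))},
        attrs={
            "model_id": fit.model_id,
            "converged": int(fit.converged),
            "rhat": json.dumps(fit.rhat),
            "ess": json.dumps(fit.ess),
        },
    )
    ds.to_netcdf(path, engine="scipy")


# ------------------------------------------------------------ run_study

@dataclass
class StudyConfig:
    """Full study design: country, model list, CV switch, thresholds, seeds."""

    country: CountryConfig = field(default_factory=CountryConfig)
    models: tuple[str, ...] = ALL_MODELS
    covariates: str = "with"  # "with" | "without" | "both"
    cross_validate: bool = True
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    seed: int = 0
    n_chains: int = 2
    n_warmup: int = 400
    n_keep: int = 400
    n_surface_draws: int = 100

    def __post_init__(self) -> None:
        unknown = set(self.models) - set(ALL_MODELS)
        if unknown:
            raise ValueError(f"unknown models: {sorted(unknown)}")
        if self.covariates not in ("with", "without", "both"):
            raise ValueError("covariates must be 'with', 'without' or 'both'")


def load_study_config(path) -> StudyConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    country = CountryConfig(**raw.pop("country", {}))
    for key in ("models", "thresholds"):
        if key in raw:
            raw[key] = tuple(raw[key])
    if "country" in raw:
        del raw["country"]
    return StudyConfig(country=country, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _fit_full_model(model_id, country, direct, names, seed, cfg: StudyConfig):
    """Full-data fit of one model; returns district coverage draws."""
    graph = country.districts.graph
    mcmc = MCMCConfig(n_chains=cfg.n_chains, n_warmup=cfg.n_warmup, n_keep=cfg.n_keep)
    if model_id in DISCRETE_MODELS:
        from .evaluation import district_design

        X = district_design(country, names)
        fit = fit_discrete(model_id, direct, X, graph, seed=seed, mcmc=mcmc)
        return fit, fit.p_district, None
    clusters = country.clusters
    coords = clusters[["x_km", "y_km"]].to_numpy()
    X = np.column_stack(
        [np.ones(len(clusters))] + [clusters[c].to_numpy() for c in names]
    )
    pc = PCPriorSpec(r0=0.05 * country.config.extent_km[1])
    fit = fit_gp(
        coords,
        clusters["n_vaccinated"].to_numpy(float),
        clusters["n_children"].to_numpy(float),
        X,
        model_id=model_id,
        pc=pc,
        seed=seed,
        mcmc=mcmc,
    )
    grid = country.grid
    Xg = grid.design_matrix(names)
    surf = predict_surface(
        fit, grid.xy, Xg, seed=seed, n_draws=cfg.n_surface_draws, blocks=grid.district
    )
    agg, _ = aggregate_surface(surf.p, grid.q, grid.district)
    return fit, agg, surf


def run_study(config: StudyConfig, outdir) -> Path:
    """Execute the full synthetic study; returns the artifact directory.

    Artifacts: the synthetic country (clusters, districts, grid, truth),
    the direct-estimate table, per-model district estimate tables with
    exceedance probabilities, posterior draw files, the LODO comparison
    table when requested, and a manifest with seeds, versions and hashes.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("generating synthetic country (seed=%d)", config.country.seed)
    country = generate_country(config.country)
    write_cluster_table(country.clusters, out / "clusters.csv")
    write_districts(country.districts, out / "districts.geojson")
    write_grid(country.grid, out / "grid.csv")
    pd.DataFrame(
        {
            "x_km": country.grid.xy[:, 0],
            "y_km": country.grid.xy[:, 1],
            "p_true": country.truth["p_true"],
            "omega": country.truth["omega"],
        }
    ).to_csv(out / "truth.csv", index=False)

    direct = direct_estimates(country.clusters)
    direct = (
        direct.set_index("district_id")
        .reindex(country.districts.graph.ids)
        .reset_index()
    )
    write_estimates(direct, out / "direct_estimates.csv")
    log.info(
        "direct estimates: %d districts, %d boundary",
        len(direct),
        int(direct["boundary_flag"].sum()),
    )

    arms = {"with": [True], "without": [False], "both": [True, False]}[config.covariates]
    all_names = list(country.grid.covariates.columns)
    for with_cov in arms:
        names = all_names if with_cov else []
        tag = "cov" if with_cov else "nocov"
        for k, model_id in enumerate(config.models):
            fit_seed = (config.seed * 7919 + k * 101 + (99991 if with_cov else 0)) % (
                2**31
            )
            fit, draws, surf = _fit_full_model(
                model_id, country, direct, names, fit_seed, config
            )
            est = summarize_districts(
                draws, country.districts.graph.ids, config.thresholds
            )
            slug = model_id.lower().replace("-", "_")
            write_estimates(est, out / f"estimates_{slug}_{tag}.csv")
            if model_id in DISCRETE_MODELS:
                save_discrete_fit(fit, out / f"fit_{slug}_{tag}.nc")
            else:
                save_gpfit(fit, out / f"fit_{slug}_{tag}.nc")
                if surf is not None:
                    save_surface(surf, out / f"surface_{slug}_{tag}.nc")
            log.info("fitted %s (%s): converged=%s", model_id, tag, fit.converged)

    if config.cross_validate:
        cv = run_comparison(
            country,
            models=config.models,
            covariates=config.covariates,
            seed=config.seed,
            mcmc_discrete=MCMCConfig(
                n_chains=config.n_chains,
                n_warmup=config.n_warmup,
                n_keep=config.n_keep,
            ),
            n_surface_draws=config.n_surface_draws,
        )
        cv.table.to_csv(out / "comparison.csv", index=False)

    manifest = {
        "package": "vaxsae",
        "version": __version__,
        "seed": config.seed,
        "country_seed": config.country.seed,
        "models": list(config.models),
        "covariates": config.covariates,
        "files": {
            p.name: _sha256(p) for p in sorted(out.iterdir()) if p.is_file()
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
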