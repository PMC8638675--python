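"""Synthetic country generator emulating DHS-style vaccination surveys.

Builds a rectangular planar country (coordinates in km) partitioned into
irregular districts (Voronoi cells of random seed points), lays a regular
grid of cell centroids over it, equips the grid with a log-Gaussian
population field and smooth covariate fields, simulates a latent
logit-coverage surface with a Matérn (nu = 1) Gaussian process, and then
draws a stratified two-stage cluster survey from it: within each district
an urban stratum (the highest-population cells) and a rural stratum are
sampled with probability proportional to population, urban oversampled,
and the design weight is the inverse inclusion probability.

Everything is deterministic given the single integer seed in the config;
each stage draws from its own named substream so stages can be re-run
independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial import Voronoi
from shapely.geometry import Polygon, box

from ._rng import substream
from .car import AdjacencyGraph
from .matern import MaternParams, matern_covariance

__all__ = [
    "ConfigError",
    "DegenerateDesignError",
    "CountryConfig",
    "DistrictFrame",
    "GridSurface",
    "SyntheticCountry",
    "generate_country",
    "simulate_latent_surface",
    "simulate_survey",
    "true_district_coverage",
]

CLUSTER_COLUMNS = [
    "cluster_id",
    "x_km",
    "y_km",
    "district_id",
    "stratum",
    "n_children",
    "n_vaccinated",
    "weight",
]


class ConfigError(ValueError):
    """Raised for self-inconsistent country configurations."""


class DegenerateDesignError(RuntimeError):
    """Raised when a sampling stratum carries no population."""


@dataclass(frozen=True)
class CountryConfig:
    """Study conditions for one synthetic country.

    Defaults describe a mid-sized survey: 25 districts over a 350 x 350 km
    country gridded at 5 km, ~300 clusters of 10-30 children aged 12-23
    months, a latent surface with sd 0.6 and range 150 km on the logit
    scale, and mild between-cluster (nugget) noise.
    """

    n_districts: int = 25
    extent_km: tuple[float, float] = (350.0, 350.0)
    grid_res_km: float = 5.0
    n_clusters_total: int = 300
    children_per_cluster: tuple[int, int] = (10, 30)
    urban_fraction: float = 0.35
    urban_quantile: float = 0.2
    gp_params: tuple[float, float] = (0.6, 150.0)  # (sigma_omega, range km)
    beta: tuple[float, ...] = (0.5, 0.4)  # intercept + covariate effects
    nugget_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_districts < 2:
            raise ConfigError("n_districts must be >= 2")
        if self.grid_res_km <= 0:
            raise ConfigError("grid_res_km must be positive")
        if self.extent_km[0] <= 0 or self.extent_km[1] <= 0:
            raise ConfigError("extent must be positive")
        if not 0.0 < self.urban_fraction < 1.0:
            raise ConfigError("urban_fraction must lie in (0, 1)")
        if not 0.0 < self.urban_quantile < 1.0:
            raise ConfigError("urban_quantile must lie in (0, 1)")
        if self.gp_params[1] <= 0:
            raise ConfigError("Matérn range must be positive")
        if self.gp_params[0] < 0 or self.nugget_sd < 0:
            raise ConfigError("sds must be >= 0")
        lo, hi = self.children_per_cluster
        if lo > hi or hi < 2:
            raise ConfigError("children_per_cluster range must allow N >= 2")
        if self.n_clusters_total < 2 * self.n_districts:
            raise ConfigError("need at least 2 clusters per district")

    @property
    def n_covariates(self) -> int:
        return len(self.beta) - 1


@dataclass
class DistrictFrame:
    """District polygons, ids and the shared-border adjacency graph."""

    polygons: list[Polygon]
    graph: AdjacencyGraph

    @property
    def ids(self) -> list[int]:
        return self.graph.ids

    @property
    def n(self) -> int:
        return len(self.polygons)


@dataclass
class GridSurface:
    """Regular raster of cell centroids with population and covariates."""

    xy: np.ndarray  # (n, 2) centroid coordinates, km
    res_km: float
    district: np.ndarray  # (n,) district index of each cell
    pop: np.ndarray  # (n,) relative population
    q: np.ndarray  # (n,) population share within its district
    covariates: pd.DataFrame  # (n, p-1) smooth covariate fields

    @property
    def n(self) -> int:
        return self.xy.shape[0]

    def design_matrix(self, names: list[str] | None = None) -> np.ndarray:
        """Intercept column plus the requested covariates (all by default)."""
        if names is None:
            names = list(self.covariates.columns)
        cols = [np.ones(self.n)] + [self.covariates[c].to_numpy() for c in names]
        return np.column_stack(cols)


@dataclass
class SyntheticCountry:
    districts: DistrictFrame
    grid: GridSurface
    truth: dict[str, np.ndarray]  # omega, logit_p, p_true on the grid
    clusters: pd.DataFrame | None
    config: CountryConfig


def _voronoi_districts(config: CountryConfig, rng: np.random.Generator) -> DistrictFrame:
    w, h = config.extent_km
    pts = rng.uniform((0, 0), (w, h), size=(config.n_districts, 2))
    # Mirror the seeds across all four edges so every original cell is a
    # bounded polygon that exactly tiles the rectangle.
    mirrors = [
        pts,
        pts * (-1, 1),
        pts * (1, -1),
        (2 * w - pts[:, 0, None], pts[:, 1, None] * 1.0),
        (pts[:, 0, None] * 1.0, 2 * h - pts[:, 1, None]),
    ]
    all_pts = np.vstack(
        [m if isinstance(m, np.ndarray) else np.hstack(m) for m in mirrors]
    )
    vor = Voronoi(all_pts)
    rect = box(0.0, 0.0, w, h)
    polys = []
    for i in range(config.n_districts):
        region = vor.regions[vor.point_region[i]]
        poly = Polygon(vor.vertices[region]).intersection(rect)
        polys.append(poly)

    n = config.n_districts
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            inter = polys[i].boundary.intersection(polys[j].boundary)
            if inter.length > 1e-9:
                W[i, j] = W[j, i] = 1.0
    return DistrictFrame(polygons=polys, graph=AdjacencyGraph(W))


def _smooth_field(
    xy: np.ndarray,
    extent: tuple[float, float],
    rng: np.random.Generator,
    n_coarse: int = 12,
    range_frac: float = 0.4,
) -> np.ndarray:
    """A smooth Gaussian field: Matérn draw on a coarse lattice, bilinearly
    interpolated to the cell centroids.  Used for population and covariates."""
    w, h = extent
    gx = np.linspace(0.0, w, n_coarse)
    gy = np.linspace(0.0, h, n_coarse)
    GX, GY = np.meshgrid(gx, gy, indexing="ij")
    nodes = np.column_stack([GX.ravel(), GY.ravel()])
    C = matern_covariance(nodes, MaternParams(1.0, range_frac * max(w, h)))
    L = np.linalg.cholesky(C + 1e-8 * np.eye(len(nodes)))
    z = (L @ rng.standard_normal(len(nodes))).reshape(n_coarse, n_coarse)
    interp = RegularGridInterpolator((gx, gy), z, bounds_error=False, fill_value=None)
    return interp(xy)


def _build_grid(
    config: CountryConfig, districts: DistrictFrame, rng: np.random.Generator
) -> GridSurface:
    w, h = config.extent_km
    res = config.grid_res_km
    xs = np.arange(res / 2.0, w, res)
    ys = np.arange(res / 2.0, h, res)
    XX, YY = np.meshgrid(xs, ys, indexing="ij")
    xy = np.column_stack([XX.ravel(), YY.ravel()])

    # Assign each centroid to the first (lowest-id) district covering it, so
    # centroids exactly on a border go deterministically to the smaller id.
    assign = np.full(xy.shape[0], -1, dtype=int)
    for i, poly in enumerate(districts.polygons):
        free = assign < 0
        if not free.any():
            break
        shapely.prepare(poly)
        hit = shapely.contains_xy(poly, xy[free, 0], xy[free, 1])
        # include boundary points
        if not hit.all():
            onb = shapely.intersects(poly.boundary, shapely.points(xy[free][~hit]))
            hit[~hit] = onb
        idx = np.flatnonzero(free)[hit]
        assign[idx] = i
    if (assign < 0).any():  # fp edge cases: nearest district polygon
        miss = np.flatnonzero(assign < 0)
        for k in miss:
            pt = shapely.points(xy[k])
            assign[k] = int(
                np.argmin([poly.distance(pt) for poly in districts.polygons])
            )

    counts = np.bincount(assign, minlength=districts.n)
    if (counts < 2).any():
        raise ConfigError(
            "every district needs >= 2 grid cells; refine grid_res_km or "
            f"reduce n_districts (cell counts: {counts.tolist()})"
        )

    logpop = 1.0 * _smooth_field(xy, config.extent_km, rng, range_frac=0.25)
    pop = np.exp(logpop - logpop.max())
    q = np.empty_like(pop)
    for i in range(districts.n):
        m = assign == i
        q[m] = pop[m] / pop[m].sum()

    cov = {}
    for c in range(config.n_covariates):
        f = _smooth_field(xy, config.extent_km, rng, range_frac=0.35)
        cov[f"x{c + 1}"] = (f - f.mean()) / f.std()
    covariates = pd.DataFrame(cov, index=range(xy.shape[0]))

    return GridSurface(
        xy=xy, res_km=res, district=assign, pop=pop, q=q, covariates=covariates
    )


def simulate_latent_surface(
    grid: GridSurface,
    gp_params: tuple[float, float],
    beta: tuple[float, ...],
    seed: int,
) -> dict[str, np.ndarray]:
    """Draw the latent coverage truth on the grid.

    omega is a zero-mean Matérn (nu = 1) Gaussian field over the cell
    centroids, drawn by exact Cholesky of the dense covariance;
    p_true(s) = expit(x(s)' beta + omega(s)).  The cluster-level nugget is
    *not* part of the grid truth. sigma_omega = 0 degenerates to the pure
    covariate surface.
    """
    sigma_omega, range_r = gp_params
    if range_r <= 0:
        raise ValueError("Matérn range must be positive")
    if sigma_omega < 0:
        raise ValueError("sigma_omega must be >= 0")
    beta = np.asarray(beta, dtype=float)
    X = grid.design_matrix()
    if X.shape[1] != beta.size:
        raise ValueError(
            f"beta has {beta.size} entries but design matrix has {X.shape[1]} columns"
        )
    rng = substream(seed, "latent-surface")
    if sigma_omega == 0.0:
        omega = np.zeros(grid.n)
    else:
        C = matern_covariance(grid.xy, MaternParams(sigma_omega**2, range_r))
        L = safe_cholesky(C, sigma_omega**2)
        omega = L @ rng.standard_normal(grid.n)
    logit_p = X @ beta + omega
    p_true = _expit(logit_p)
    return {"omega": omega, "logit_p": logit_p, "p_true": p_true}


def safe_cholesky(
    C: np.ndarray, scale: float | None = None, clip_eigs: bool = False
) -> np.ndarray:
    """Cholesky with an escalating jitter schedule (1e-8 to 1e-4 x scale).

    With ``clip_eigs`` a final eigenvalue-clipping (PSD projection) fallback
    returns a factor of the nearest PSD matrix instead of raising — used for
    conditional covariances whose small negative eigenvalues are pure
    floating-point debris from near-singular interpolation systems.
    """
    n = C.shape[0]
    scale = float(np.mean(np.diag(C))) if scale is None else scale
    if scale <= 0:
        scale = 1.0
    jitter = 0.0
    for level in [0.0, 1e-8, 1e-7, 1e-6, 1e-5, 1e-4]:
        jitter = level * scale
        try:
            return np.linalg.cholesky(C + jitter * np.eye(n))
        except np.linalg.LinAlgError:
            continue
    lam, V = np.linalg.eigh(C)
    if clip_eigs:
        return V * np.sqrt(np.clip(lam, 0.0, None))
    raise np.linalg.LinAlgError(
        f"covariance not positive definite after jitter escalation to "
        f"{jitter:.1e} (n={n}, min eigenvalue {float(lam[0]):.3e})"
    )


def _expit(x: np.ndarray) -> np.ndarray:
    from scipy.special import expit

    return expit(x)


def _allocate(
    total: int, shares: np.ndarray, minimum: int, caps: np.ndarray | None = None
) -> np.ndarray:
    """Largest-remainder allocation of `total` with floor and optional caps."""
    n = shares.size
    if total < minimum * n:
        raise ConfigError(f"cannot allocate {total} clusters with floor {minimum} x {n}")
    if caps is None:
        caps = np.full(n, total)
    if np.any(caps < minimum):
        raise ConfigError("a district has fewer grid cells than the cluster floor")
    if total > caps.sum():
        raise ConfigError(
            f"{total} clusters requested but only {int(caps.sum())} grid cells exist"
        )
    alloc = np.full(n, minimum)
    # distribute the remainder proportionally among districts with headroom
    while alloc.sum() < total:
        rest = total - alloc.sum()
        free = alloc < caps
        raw = shares[free] / shares[free].sum() * rest
        add = np.minimum(np.floor(raw).astype(int), (caps - alloc)[free])
        if add.sum() == 0:  # largest remainders, one unit each
            order = np.argsort(-(raw - np.floor(raw)))
            idx = np.flatnonzero(free)[order]
            for k in idx[:rest]:
                if alloc[k] < caps[k]:
                    alloc[k] += 1
        else:
            alloc[free] += add
    return alloc


def _stratify(grid: GridSurface, district: int, urban_quantile: float):
    """Cell indices of the urban (top population quantile) and rural strata."""
    cells = np.flatnonzero(grid.district == district)
    order = cells[np.argsort(-grid.pop[cells], kind="stable")]
    n_urban = max(1, int(round(urban_quantile * cells.size)))
    n_urban = min(n_urban, cells.size - 1)  # both strata non-empty
    return order[:n_urban], order[n_urban:]


def simulate_survey(country: SyntheticCountry, config: CountryConfig | None = None) -> pd.DataFrame:
    """Draw the stratified two-stage cluster survey from the latent truth.

    Clusters (= grid cells) are sampled without replacement within each
    stratum with probability proportional to cell population; the design
    weight is the inverse of the approximate inclusion probability
    n_h * pop_k / pop_h.  Cluster counts follow
    Y ~ Binomial(N, expit(logit p_true + eps)), eps ~ N(0, nugget_sd^2),
    and N is redrawn until N >= 2 (surveys exclude single-child clusters).
    """
    config = config or country.config
    grid = country.grid
    rng = substream(config.seed, "survey")
    logit_p = country.truth["logit_p"]

    dist_pop = np.array(
        [grid.pop[grid.district == i].sum() for i in range(country.districts.n)]
    )
    dist_cells = np.array(
        [(grid.district == i).sum() for i in range(country.districts.n)]
    )
    n_per_district = _allocate(
        config.n_clusters_total, dist_pop, minimum=2, caps=dist_cells
    )

    rows = []
    cid = 0
    lo, hi = config.children_per_cluster
    for i in range(country.districts.n):
        urban_cells, rural_cells = _stratify(grid, i, config.urban_quantile)
        n_i = int(n_per_district[i])
        n_urban = int(np.clip(round(config.urban_fraction * n_i), 1, n_i - 1))
        n_rural = n_i - n_urban
        # never request more clusters than a stratum has cells
        if n_urban > urban_cells.size:
            n_rural += n_urban - urban_cells.size
            n_urban = urban_cells.size
        if n_rural > rural_cells.size:
            n_urban += n_rural - rural_cells.size
            n_rural = rural_cells.size
        if n_urban > urban_cells.size or n_i > urban_cells.size + rural_cells.size:
            raise ConfigError(
                f"district {i}: {n_i} clusters requested but only "
                f"{urban_cells.size + rural_cells.size} grid cells available"
            )
        for stratum, cells, n_take in (
            ("urban", urban_cells, n_urban),
            ("rural", rural_cells, n_rural),
        ):
            pop_h = grid.pop[cells]
            if pop_h.sum() <= 0:
                raise DegenerateDesignError(
                    f"district {i} stratum {stratum!r} has zero population"
                )
            p_sel = pop_h / pop_h.sum()
            take = rng.choice(cells, size=n_take, replace=False, p=p_sel)
            incl = np.minimum(n_take * grid.pop[take] / pop_h.sum(), 1.0)
            for cell, pi_k in zip(take, incl):
                n_child = int(rng.integers(lo, hi + 1))
                while n_child <= 1:  # excluded: redraw instead of emitting
                    n_child = int(rng.integers(lo, hi + 1))
                eps = rng.normal(0.0, config.nugget_sd) if config.nugget_sd > 0 else 0.0
                p_cl = float(_expit(np.array([logit_p[cell] + eps]))[0])
                y = int(rng.binomial(n_child, p_cl))
                row = {
                    "cluster_id": cid,
                    "x_km": grid.xy[cell, 0],
                    "y_km": grid.xy[cell, 1],
                    "district_id": i,
                    "stratum": stratum,
                    "n_children": n_child,
                    "n_vaccinated": y,
                    "weight": 1.0 / pi_k,
                }
                for c in grid.covariates.columns:
                    row[c] = grid.covariates[c].iloc[cell]
                rows.append(row)
                cid += 1
    return pd.DataFrame(rows)


def generate_country(config: CountryConfig) -> SyntheticCountry:
    """Generate the full synthetic country: districts, grid, truth, survey.

    Deterministic given ``config.seed``. Raises :class:`ConfigError` when the
    requested design cannot be realized (eg more clusters than grid cells).
    """
    n_cells_approx = int(
        np.floor(config.extent_km[0] / config.grid_res_km)
        * np.floor(config.extent_km[1] / config.grid_res_km)
    )
    if config.n_clusters_total > n_cells_approx:
        raise ConfigError(
            f"{config.n_clusters_total} clusters requested but the grid has "
            f"only {n_cells_approx} cells"
        )
    districts = _voronoi_districts(config, substream(config.seed, "voronoi"))
    grid = _build_grid(config, districts, substream(config.seed, "grid-fields"))
    truth = simulate_latent_surface(grid, config.gp_params, config.beta, config.seed)
    country = SyntheticCountry(
        districts=districts, grid=grid, truth=truth, clusters=None, config=config
    )
    country.clusters = simulate_survey(country, config)
    return country


def true_district_coverage(country: SyntheticCountry) -> np.ndarray:
    """Population-weighted aggregate of p_true per district."""
    grid = country.grid
    p = country.truth["p_true"]
    out = np.empty(country.districts.n)
    for i in range(country.districts.n):
        m = grid.district == i
        out[i] = float(np.dot(p[m], grid.q[m]))
    return out
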