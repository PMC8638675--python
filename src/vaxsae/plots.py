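"""Basic plotting helpers: district choropleths and grid surfaces.

Thin matplotlib wrappers for quick visual checks of estimates and
exceedance probabilities; not a mapping framework.
"""

from __future__ import annotations

import numpy as np

__all__ = ["plot_district_map", "plot_surface"]


def plot_district_map(districts, values, ax=None, cmap="viridis", vmin=None,
                      vmax=None, label=None):
    """Choropleth of one value per district over the district polygons.

    Parameters
    ----------
    districts : DistrictFrame
    values : sequence of length n_districts (NaN -> hatched grey)
    """
    import matplotlib.pyplot as plt
    from matplotlib.collections import PatchCollection
    from matplotlib.patches import Polygon as MplPolygon

    values = np.asarray(values, dtype=float)
    if values.size != districts.n:
        raise ValueError("one value per district required")
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    patches, vals = [], []
    for poly, v in zip(districts.polygons, values):
        geoms = poly.geoms if hasattr(poly, "geoms") else [poly]
        for g in geoms:
            xy = np.asarray(g.exterior.coords)
            if np.isnan(v):
                ax.add_patch(
                    MplPolygon(xy, facecolor="0.85", hatch="//", edgecolor="k")
                )
            else:
                patches.append(MplPolygon(xy))
                vals.append(v)
    coll = PatchCollection(patches, cmap=cmap, edgecolor="k", linewidth=0.5)
    coll.set_array(np.asarray(vals))
    coll.set_clim(vmin, vmax)
    ax.add_collection(coll)
    ax.autoscale_view()
    ax.set_aspect("equal")
    ax.set_xlabel("x (km)")
    ax.set_ylabel("y (km)")
    cb = ax.figure.colorbar(coll, ax=ax, shrink=0.8)
    if label:
        cb.set_label(label)
    return ax


def plot_surface(grid_xy, values, res_km=None, ax=None, cmap="viridis",
                 label=None):
    """Gridded surface (eg posterior-mean coverage) as a raster image."""
    import matplotlib.pyplot as plt

    grid_xy = np.asarray(grid_xy, dtype=float)
    values = np.asarray(values, dtype=float)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    xs = np.unique(grid_xy[:, 0])
    ys = np.unique(grid_xy[:, 1])
    img = np.full((ys.size, xs.size), np.nan)
    ix = np.searchsorted(xs, grid_xy[:, 0])
    iy = np.searchsorted(ys, grid_xy[:, 1])
    img[iy, ix] = values
    half = (res_km or (xs[1] - xs[0] if xs.size > 1 else 1.0)) / 2.0
    im = ax.imshow(
        img,
        origin="lower",
        extent=(xs[0] - half, xs[-1] + half, ys[0] - half, ys[-1] + half),
        cmap=cmap,
    )
    ax.set_xlabel("x (km)")
    ax.set_ylabel("y (km)")
    cb = ax.figure.colorbar(im, ax=ax, shrink=0.8)
    if label:
        cb.set_label(label)
    return ax
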