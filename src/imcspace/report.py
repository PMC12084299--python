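"""Figure rendering: Voronoi tissue maps and cohort summary figures.

Every figure is a pure function of a table that is written alongside it, so
any plot can be regenerated from its CSV.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib import colormaps
from scipy.spatial import Voronoi
from shapely.geometry import Polygon, box


def voronoi_polygons(
    points: np.ndarray, bounds: tuple[float, float, float, float]
) -> list[Polygon]:
    """Bounded Voronoi tessellation of ``points`` clipped to ``bounds``.

    Unbounded outer regions are closed by mirroring the points across the
    four sides of the bounding rectangle before tessellating, then clipping
    each original point's region to the rectangle. Returns one shapely
    polygon per input point, in order.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise ValueError("Voronoi tessellation needs at least 3 points")
    x0, y0, x1, y1 = bounds
    mirrored = [pts]
    for mirror in (
        lambda p: np.column_stack([2 * x0 - p[:, 0], p[:, 1]]),
        lambda p: np.column_stack([2 * x1 - p[:, 0], p[:, 1]]),
        lambda p: np.column_stack([p[:, 0], 2 * y0 - p[:, 1]]),
        lambda p: np.column_stack([p[:, 0], 2 * y1 - p[:, 1]]),
    ):
        mirrored.append(mirror(pts))
    vor = Voronoi(np.vstack(mirrored))
    clip = box(x0, y0, x1, y1)
    polys: list[Polygon] = []
    for i in range(len(pts)):
        region = vor.regions[vor.point_region[i]]
        poly = Polygon(vor.vertices[region]).buffer(0).intersection(clip)
        polys.append(poly)
    return polys


def _collinear(pts: np.ndarray) -> bool:
    if len(pts) < 3:
        return True
    centered = pts - pts.mean(axis=0)
    return np.linalg.matrix_rank(centered, tol=1e-9) < 2


def render_voronoi(
    cells: pd.DataFrame,
    color_by: str = "cell_type",
    bounds: tuple[float, float, float, float] | None = None,
    ax=None,
):
    """Voronoi map of one ROI, polygons colored by ``color_by`` category.

    ``bounds`` is (x0, y0, x1, y1) of the ROI rectangle (default: tight
    bounding box of the centroids). Fewer than 3 cells or collinear
    centroids fall back to a scatter plot with a warning. Returns
    (figure, polygons); polygons is None in the fallback.
    """
    pts = cells[["x", "y"]].to_numpy(dtype=float)
    if bounds is None:
        bounds = (pts[:, 0].min(), pts[:, 1].min(), pts[:, 0].max(), pts[:, 1].max())
    categories = cells[color_by].astype(str).to_numpy()
    cats = sorted(set(categories))
    cmap = colormaps["tab20"]
    color_of = {c: cmap(i % 20) for i, c in enumerate(cats)}

    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 6))
    else:
        fig = ax.figure

    polys = None
    if len(pts) < 3 or _collinear(pts):
        warnings.warn(
            "fewer than 3 non-collinear cells; falling back to scatter",
            RuntimeWarning,
            stacklevel=2,
        )
        for c in cats:
            sel = categories == c
            ax.scatter(pts[sel, 0], pts[sel, 1], color=color_of[c], label=c, s=12)
    else:
        polys = voronoi_polygons(pts, bounds)
        for poly, cat in zip(polys, categories):
            if poly.is_empty:
                continue
            xs, ys = poly.exterior.xy
            ax.fill(xs, ys, color=color_of[cat], edgecolor="white", linewidth=0.3)
        handles = [plt.Rectangle((0, 0), 1, 1, color=color_of[c]) for c in cats]
        ax.legend(handles, cats, loc="center left", bbox_to_anchor=(1.01, 0.5), fontsize=7)
    ax.set_xlim(bounds[0], bounds[2])
    ax.set_ylim(bounds[3], bounds[1])  # image convention: y down
    ax.set_aspect("equal")
    ax.set_title(f"Voronoi map ({color_by})")
    return fig, polys


def _heatmap(ax, data: pd.DataFrame, title: str, marks: pd.DataFrame | None = None):
    im = ax.imshow(data.to_numpy(dtype=float), aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(data.columns)), [str(c) for c in data.columns], rotation=90, fontsize=6)
    ax.set_yticks(range(len(data.index)), [str(i) for i in data.index], fontsize=6)
    ax.set_title(title)
    if marks is not None:
        for yi, idx in enumerate(data.index):
            for xi, col in enumerate(data.columns):
                if marks.loc[idx, col]:
                    ax.text(xi, yi, "*", ha="center", va="center", color="white")
    ax.figure.colorbar(im, ax=ax, shrink=0.7)


def render_summary_figures(outdir, tables: dict[str, pd.DataFrame]) -> list[Path]:
    """Render the cohort summary figure set from stage tables.

    Recognized keys in ``tables``: ``cluster_markers`` (cluster x marker
    means), ``composition`` (sample x type fractions, with a ``group``
    column optional), ``cn_centroids`` (CN x type), ``interactions``
    (classification table from the permutation test). Each figure's data is
    written as CSV next to its PNG; a missing table skips that figure with
    a warning. Returns the written figure paths.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, fig, data: pd.DataFrame):
        data.to_csv(out / f"{name}.csv")
        path = out / f"{name}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(path)

    if "cluster_markers" in tables:
        data = tables["cluster_markers"]
        fig, ax = plt.subplots(figsize=(8, 5))
        _heatmap(ax, data, "Mean marker expression per population")
        emit("cluster_marker_heatmap", fig, data)
    else:
        warnings.warn("cluster_markers table missing; heatmap skipped", RuntimeWarning, stacklevel=2)

    if "composition" in tables:
        data = tables["composition"]
        frac = data.select_dtypes("number")
        fig, ax = plt.subplots(figsize=(8, 4))
        bottom = np.zeros(len(frac))
        cmap = colormaps["tab20"]
        for i, ct in enumerate(frac.columns):
            vals = 100 * frac[ct].to_numpy(dtype=float)
            ax.bar(range(len(frac)), vals, bottom=bottom, label=str(ct), color=cmap(i % 20))
            bottom += vals
        ax.set_xticks(range(len(frac)), [str(i) for i in frac.index], rotation=90, fontsize=6)
        ax.set_ylabel("% of cells")
        ax.legend(fontsize=6, loc="center left", bbox_to_anchor=(1.01, 0.5))
        ax.set_title("Cell-type composition per sample")
        emit("composition_bars", fig, data)
    else:
        warnings.warn("composition table missing; bars skipped", RuntimeWarning, stacklevel=2)

    if "cn_centroids" in tables:
        data = tables["cn_centroids"]
        fig, ax = plt.subplots(figsize=(7, 4))
        _heatmap(ax, data, "CN composition (k-means centroids)")
        emit("cn_heatmap", fig, data)
    else:
        warnings.warn("cn_centroids table missing; CN heatmap skipped", RuntimeWarning, stacklevel=2)

    inter = tables.get("interactions")
    if inter is not None and len(inter):
        score = inter.assign(
            value=np.where(
                inter["classification"] == "interaction",
                1,
                np.where(inter["classification"] == "avoidance", -1, 0),
            )
        )
        mat = score.pivot_table(
            index="from_type", columns="to_type", values="value", aggfunc="mean"
        ).fillna(0)
        sig = score.pivot_table(
            index="from_type", columns="to_type", values="value",
            aggfunc=lambda v: np.mean(np.abs(v)) > 0.5,
        ).fillna(False)
        fig, ax = plt.subplots(figsize=(6, 5))
        _heatmap(ax, mat, "Directed interactions (+1) / avoidances (-1)", marks=sig)
        emit("interaction_heatmap", fig, mat)
    else:
        warnings.warn("interaction table missing or empty; heatmap skipped", RuntimeWarning, stacklevel=2)

    return written
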