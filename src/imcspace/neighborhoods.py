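"""Cellular neighborhoods (CNs): spatial kNN, composition profiles, k-means.

A cell's neighborhood window is the cell itself plus its k nearest
neighbors by centroid Euclidean distance (k = 20 by default), built per
ROI — never across ROI boundaries, since each ROI is an independent tissue
acquisition. Window composition profiles (fractions over annotated cell
types) are pooled cohort-wide and clustered by standard k-means (Euclidean,
k = 10 by default) into CN "function units", which are then annotated by
their enriched types and compared between clinical groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree, distance
from sklearn.cluster import KMeans


@dataclass
class SpatialGraph:
    """Per-ROI k-nearest-neighbor structure over cell centroids.

    ``per_roi`` maps roi_id to a dict with:

    * ``cell_ids``  -- (n,) cell ids in table order,
    * ``neighbors`` -- (n, m) positional indices into ``cell_ids``,
      m = min(k, n - 1), distance-ordered, ties at the k-th distance broken
      by ascending cell id,
    * ``distances`` -- (n, m) matching distances (nondecreasing per row).
    """

    k: int
    per_roi: dict[str, dict[str, np.ndarray]] = field(repr=False)

    @property
    def roi_ids(self) -> list[str]:
        return list(self.per_roi)

    def window_size(self, roi_id: str) -> int:
        ent = self.per_roi[roi_id]
        return 1 + ent["neighbors"].shape[1]


# ROIs larger than this use a KD-tree with tie-aware over-query instead of
# the dense all-pairs distance matrix
_DENSE_LIMIT = 3000


def _knn_dense(xy: np.ndarray, cell_ids: np.ndarray, m: int):
    d = distance.squareform(distance.pdist(xy))
    np.fill_diagonal(d, np.inf)
    order = np.lexsort((np.broadcast_to(cell_ids, d.shape), d), axis=1)
    nbr = order[:, :m]
    return nbr, np.take_along_axis(d, nbr, axis=1)


def _knn_tree(xy: np.ndarray, cell_ids: np.ndarray, m: int):
    n = len(xy)
    tree = cKDTree(xy)
    extra = min(n, m + 8)
    dist, idx = tree.query(xy, k=extra)
    nbr = np.empty((n, m), dtype=int)
    out_d = np.empty((n, m))
    for i in range(n):
        di, ii = dist[i], idx[i]
        keep = ii != i
        di, ii = di[keep], ii[keep]
        # expand if the k-th distance ties with dropped candidates
        if len(di) > m and di[m - 1] == di[-1]:
            di_all, ii_all = tree.query(xy[i], k=n)
            keep = ii_all != i
            di, ii = di_all[keep], ii_all[keep]
        order = np.lexsort((cell_ids[ii], di))[:m]
        nbr[i] = ii[order]
        out_d[i] = di[order]
    return nbr, out_d


def spatial_knn(cells: pd.DataFrame, k: int = 20) -> SpatialGraph:
    """Exact per-ROI k-nearest-neighbor graph on cell centroids.

    Self is excluded; neighbor lists have length min(k, n_cells - 1); ties
    at the cutoff distance are broken by ascending cell id so the graph is
    deterministic. A single-cell ROI gets an empty neighbor list with a
    warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not np.all(np.isfinite(cells[["x", "y"]].to_numpy(dtype=float))):
        raise ValueError("cell coordinates must be finite")
    per_roi: dict[str, dict[str, np.ndarray]] = {}
    for roi_id, sub in cells.groupby("roi_id", sort=False):
        xy = sub[["x", "y"]].to_numpy(dtype=float)
        ids = sub["cell_id"].to_numpy()
        n = len(sub)
        m = min(k, n - 1)
        if n == 1:
            warnings.warn(
                f"ROI {roi_id!r} has a single cell; empty neighbor list",
                RuntimeWarning,
                stacklevel=2,
            )
            nbr = np.empty((1, 0), dtype=int)
            dists = np.empty((1, 0))
        elif n <= _DENSE_LIMIT:
            nbr, dists = _knn_dense(xy, ids, m)
        else:
            nbr, dists = _knn_tree(xy, ids, m)
        per_roi[str(roi_id)] = {
            "cell_ids": ids,
            "neighbors": nbr,
            "distances": dists,
        }
    return SpatialGraph(k=k, per_roi=per_roi)


def window_indices(entry: dict[str, np.ndarray]) -> np.ndarray:
    """(n, 1 + m) positional indices of each cell's CN window (center first)."""
    n = len(entry["cell_ids"])
    return np.hstack([np.arange(n)[:, None], entry["neighbors"]])


def neighborhood_profiles(
    graph: SpatialGraph, cells: pd.DataFrame, type_col: str = "cell_type"
) -> pd.DataFrame:
    """Per-cell CN composition profile.

    For every cell, the fraction of each annotated type within its window
    (center cell + neighbors); rows sum to 1. The type vocabulary is the
    sorted set of observed labels (cells without a type count under
    "unassigned"). Returns roi_id, cell_id plus one fraction column per type.
    """
    labels = cells[type_col].fillna("unassigned").astype(str)
    vocab = sorted(labels.unique())
    code_of = {t: i for i, t in enumerate(vocab)}
    codes_all = labels.map(code_of).to_numpy()
    by_roi = {
        str(k): v
        for k, v in cells.assign(_code=codes_all).groupby("roi_id", sort=False)
    }

    frames = []
    for roi_id, entry in graph.per_roi.items():
        sub = by_roi[roi_id]
        # align to graph order via cell ids (robust to table reordering)
        codes = sub.set_index("cell_id")["_code"].loc[entry["cell_ids"]].to_numpy()
        win = window_indices(entry)
        n, w = win.shape
        flat = codes[win].ravel() + np.repeat(np.arange(n), w) * len(vocab)
        counts = np.bincount(flat, minlength=n * len(vocab)).reshape(n, len(vocab))
        prof = counts / w
        frame = pd.DataFrame(prof, columns=vocab)
        frame.insert(0, "cell_id", entry["cell_ids"])
        frame.insert(0, "roi_id", roi_id)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


@dataclass
class CNModel:
    """Fitted cellular-neighborhood model.

    ``centroids`` is k_cn x T (rows on the simplex, ordered by descending
    cluster size, cn ids 1-based to match CN1..CN10 conventions);
    ``assignments`` aligns with the profile table used for fitting;
    ``enrichment`` is centroid / cohort-global type fraction.
    """

    centroids: pd.DataFrame
    assignments: pd.DataFrame  # roi_id, cell_id, cn_id
    enrichment: pd.DataFrame
    inertia: float

    @property
    def k_cn(self) -> int:
        return len(self.centroids)


def cluster_neighborhoods(
    profiles: pd.DataFrame,
    k_cn: int = 10,
    seed: int = 0,
    n_init: int = 10,
    global_fractions: pd.Series | None = None,
) -> CNModel:
    """K-means over CN composition profiles (Euclidean, k-means++ init).

    Best of ``n_init`` restarts by within-cluster sum of squares; tol 1e-6,
    max 300 iterations; deterministic under ``seed``. CN ids are assigned
    1..k_cn by descending cluster size. Fewer distinct profiles than k_cn
    reduces k_cn with a warning; identical profiles collapse to a single CN.
    """
    type_cols = [c for c in profiles.columns if c not in ("roi_id", "cell_id")]
    X = profiles[type_cols].to_numpy(dtype=float)
    n_distinct = len(np.unique(X, axis=0))
    if n_distinct < k_cn:
        warnings.warn(
            f"only {n_distinct} distinct profiles for k_cn={k_cn}; reduced",
            RuntimeWarning,
            stacklevel=2,
        )
        k_cn = max(n_distinct, 1)

    if k_cn == 1:
        labels = np.zeros(len(X), dtype=int)
        centers = X.mean(axis=0, keepdims=True)
        inertia = float(((X - centers) ** 2).sum())
    else:
        km = KMeans(
            n_clusters=k_cn,
            init="k-means++",
            n_init=n_init,
            tol=1e-6,
            max_iter=300,
            random_state=seed,
        ).fit(X)
        labels, centers, inertia = km.labels_, km.cluster_centers_, float(km.inertia_)

    ids, counts = np.unique(labels, return_counts=True)
    order = ids[np.lexsort((ids, -counts))]
    remap = {old: new + 1 for new, old in enumerate(order)}
    cn_ids = np.array([remap[v] for v in labels], dtype=int)
    centroids = pd.DataFrame(
        centers[order], columns=type_cols, index=pd.Index(range(1, k_cn + 1), name="cn_id")
    )

    if global_fractions is None:
        global_fractions = profiles[type_cols].mean(axis=0)
    global_fractions = global_fractions.reindex(type_cols)
    with np.errstate(divide="ignore", invalid="ignore"):
        enr = centroids.div(global_fractions, axis=1)
    enrichment = enr.replace([np.inf, -np.inf], np.nan)

    assignments = profiles[["roi_id", "cell_id"]].copy()
    assignments["cn_id"] = cn_ids
    return CNModel(
        centroids=centroids,
        assignments=assignments,
        enrichment=enrichment,
        inertia=inertia,
    )


def annotate_cns(model: CNModel, factor: float = 1.5) -> dict[int, str]:
    """Label each CN by its enriched types (centroid/global above ``factor``).

    Types are listed in descending enrichment; a CN with no type above the
    factor is labeled "unenriched". Deterministic.
    """
    labels: dict[int, str] = {}
    for cn_id, row in model.enrichment.iterrows():
        enriched = row[row > factor].sort_values(ascending=False)
        if enriched.empty:
            labels[int(cn_id)] = "unenriched"
        else:
            labels[int(cn_id)] = " & ".join(enriched.index) + " enriched"
    return labels


def cn_abundance_compare(
    cells: pd.DataFrame,
    sample_col: str = "sample_id",
    group_col: str = "group",
    cn_col: str = "cn_id",
    adjust: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-sample CN fraction table plus two-group Wilcoxon rank-sum tests.

    P-values are reported unadjusted by default; Benjamini-Hochberg
    adjustment is available behind ``adjust``. A group with fewer than two
    samples skips the tests but fractions are still reported.
    """
    counts = cells.groupby([sample_col, cn_col], observed=True).size().unstack(fill_value=0)
    fractions = counts.div(counts.sum(axis=1), axis=0)
    unit_group = cells.groupby(sample_col, observed=True)[group_col].first()
    groups = sorted(g for g in unit_group.unique() if g != "")
    if len(groups) != 2:
        return fractions, None
    ga, gb = groups
    if (unit_group == ga).sum() < 2 or (unit_group == gb).sum() < 2:
        warnings.warn(
            "a group has < 2 samples; CN abundance tests skipped",
            RuntimeWarning,
            stacklevel=2,
        )
        return fractions, None
    rows = []
    for cn in fractions.columns:
        a = fractions.loc[unit_group == ga, cn].to_numpy()
        b = fractions.loc[unit_group == gb, cn].to_numpy()
        if np.ptp(np.concatenate([a, b])) == 0:
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append(
            {
                "cn_id": cn,
                "group_a": ga,
                "group_b": gb,
                "mean_a": a.mean(),
                "mean_b": b.mean(),
                "statistic": stat,
                "p_value": p,
            }
        )
    tests = pd.DataFrame(rows)
    if adjust and len(tests):
        p = tests["p_value"].to_numpy()
        order = np.argsort(p)
        ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(adj)
        out[order] = np.clip(adj, 0, 1)
        tests["p_adjusted"] = out
    return fractions, tests
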