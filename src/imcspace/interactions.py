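"""Cell-cell interaction / avoidance statistics and association analyses.

The interaction count for a directed type pair (A -> B) in one ROI is the
mean, over all type-A cells, of the number of type-B cells inside the A
cell's CN window (center + k nearest neighbors). Significance against
"random observations" comes from a within-ROI label permutation null: cell
positions and the kNN graph stay fixed, type labels are shuffled, and
empirical add-one p-values are computed for enrichment (interaction) and
depletion (avoidance). Group-level contrasts use Student's t on per-ROI
observed counts. Also here: the density-quartile association of functional
marker positivity with a target type's infiltration, and compositional
correlations between type fractions across ROIs.
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .neighborhoods import SpatialGraph, window_indices
from .phenotype import NORM_PREFIX


def _roi_codes(
    graph: SpatialGraph, cells: pd.DataFrame, type_col: str
) -> tuple[list[str], dict[str, np.ndarray], np.ndarray]:
    """Per-ROI integer type codes aligned to graph order, plus vocabulary."""
    labels = cells[type_col].fillna("unassigned").astype(str)
    vocab = np.array(sorted(labels.unique()))
    code_of = {t: i for i, t in enumerate(vocab)}
    tmp = cells.assign(_code=labels.map(code_of))
    by_roi = {str(k): v for k, v in tmp.groupby("roi_id", sort=False)}
    codes: dict[str, np.ndarray] = {}
    for roi_id, entry in graph.per_roi.items():
        sub = by_roi[roi_id]
        codes[roi_id] = (
            sub.set_index("cell_id")["_code"].loc[entry["cell_ids"]].to_numpy()
        )
    return list(graph.per_roi), codes, vocab


def _pair_stats(codes: np.ndarray, win: np.ndarray, n_types: int) -> np.ndarray:
    """T x T matrix: mean count of to_type in windows of from_type cells.

    Rows for types absent from ``codes`` are NaN (pair absent, not zero).
    """
    n, w = win.shape
    win_codes = codes[win]
    flat = win_codes.ravel() + np.repeat(np.arange(n), w) * n_types
    per_cell = np.bincount(flat, minlength=n * n_types).reshape(n, n_types)
    sums = np.zeros((n_types, n_types))
    np.add.at(sums, codes, per_cell)
    n_from = np.bincount(codes, minlength=n_types).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return sums / n_from[:, None]


def count_interactions(
    graph: SpatialGraph, cells: pd.DataFrame, type_col: str = "cell_type"
) -> pd.DataFrame:
    """Observed directed interaction counts per ROI.

    One row per (roi_id, from_type, to_type) with the mean count of
    ``to_type`` cells within the CN windows of ``from_type`` cells and the
    number of from-type cells. Pairs whose from_type is absent from an ROI
    are omitted (absent, not zero).
    """
    roi_ids, codes, vocab = _roi_codes(graph, cells, type_col)
    t = len(vocab)
    rows = []
    for roi_id in roi_ids:
        entry = graph.per_roi[roi_id]
        win = window_indices(entry)  # a single-cell ROI keeps its self-window
        mat = _pair_stats(codes[roi_id], win, t)
        n_from = np.bincount(codes[roi_id], minlength=t)
        for i in range(t):
            if n_from[i] == 0:
                continue
            for j in range(t):
                rows.append(
                    {
                        "roi_id": roi_id,
                        "from_type": vocab[i],
                        "to_type": vocab[j],
                        "observed": mat[i, j],
                        "n_from": int(n_from[i]),
                    }
                )
    return pd.DataFrame(rows)


def permutation_test(
    graph: SpatialGraph,
    cells: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    type_col: str = "cell_type",
) -> pd.DataFrame:
    """Within-ROI label-permutation test for interactions and avoidances.

    Positions and the kNN graph are fixed; type labels are shuffled
    uniformly within each ROI (the label multiset is preserved exactly).
    Add-one empirical p-values:

    * ``p_enrich`` = (1 + #{perm stat >= observed}) / (n_perm + 1)
    * ``p_avoid``  = (1 + #{perm stat <= observed}) / (n_perm + 1)

    so p >= 1/(n_perm + 1) always. A pair whose from_type would be absent in
    a permutation contributes a statistic of 0 for that permutation (cannot
    occur here because the multiset is preserved). Classification:
    "interaction" if p_enrich < alpha, "avoidance" if p_avoid < alpha,
    else "ns". Deterministic under ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    roi_ids, codes, vocab = _roi_codes(graph, cells, type_col)
    t = len(vocab)
    master = np.random.SeedSequence(seed)
    children = master.spawn(len(roi_ids))

    rows = []
    for roi_id, child in zip(roi_ids, children):
        entry = graph.per_roi[roi_id]
        c = codes[roi_id]
        present = np.unique(c)
        if len(present) < 2:
            warnings.warn(
                f"ROI {roi_id!r} has fewer than 2 cell types; permutation test skipped",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        win = window_indices(entry)
        obs = _pair_stats(c, win, t)
        rng = np.random.default_rng(child)
        ge = np.zeros((t, t))
        le = np.zeros((t, t))
        null_sum = np.zeros((t, t))
        null_sq = np.zeros((t, t))
        for _ in range(n_perm):
            perm = rng.permutation(c)
            mat = np.nan_to_num(_pair_stats(perm, win, t))
            ge += mat >= obs
            le += mat <= obs
            null_sum += mat
            null_sq += mat * mat
        null_mean = null_sum / n_perm
        null_var = np.maximum(null_sq / n_perm - null_mean**2, 0.0)
        p_enrich = (1.0 + ge) / (n_perm + 1.0)
        p_avoid = (1.0 + le) / (n_perm + 1.0)
        n_from = np.bincount(c, minlength=t)
        for i in range(t):
            if n_from[i] == 0:
                continue
            for j in range(t):
                pe, pa = p_enrich[i, j], p_avoid[i, j]
                if pe < alpha:
                    cls = "interaction"
                elif pa < alpha:
                    cls = "avoidance"
                else:
                    cls = "ns"
                rows.append(
                    {
                        "roi_id": roi_id,
                        "from_type": vocab[i],
                        "to_type": vocab[j],
                        "observed": obs[i, j],
                        "null_mean": null_mean[i, j],
                        "null_sd": math.sqrt(null_var[i, j]),
                        "p_enrich": pe,
                        "p_avoid": pa,
                        "n_perm": n_perm,
                        "classification": cls,
                    }
                )
    return pd.DataFrame(rows)


def compare_interactions_groups(
    results: pd.DataFrame,
    roi_groups: pd.Series | dict,
    welch: bool = True,
) -> pd.DataFrame:
    """Two-sample Student's t test on per-ROI observed counts, per type pair.

    ``results`` is a count_interactions / permutation_test table;
    ``roi_groups`` maps roi_id to group label (exactly two groups). Welch's
    unequal-variance correction is on by default. Pairs with fewer than two
    ROIs in either group are skipped; a zero-variance degenerate pair gets
    p = 1 with ``degenerate`` flagged.
    """
    if isinstance(roi_groups, dict):
        roi_groups = pd.Series(roi_groups)
    tab = results.copy()
    tab["group"] = tab["roi_id"].map(roi_groups)
    groups = sorted(tab["group"].dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, found {groups}")
    ga, gb = groups
    rows = []
    for (ft, tt), sub in tab.groupby(["from_type", "to_type"], sort=True):
        a = sub.loc[sub["group"] == ga, "observed"].dropna().to_numpy()
        b = sub.loc[sub["group"] == gb, "observed"].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            continue
        degenerate = a.var() == 0 and b.var() == 0
        if degenerate:
            tstat, p = 0.0, 1.0
        else:
            tstat, p = stats.ttest_ind(a, b, equal_var=not welch)
        rows.append(
            {
                "from_type": ft,
                "to_type": tt,
                "group_a": ga,
                "group_b": gb,
                "mean_a": a.mean(),
                "mean_b": b.mean(),
                "direction": np.sign(a.mean() - b.mean()),
                "t": float(tstat),
                "p_value": float(p),
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


def _exact_spearman_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with exact two-sided permutation p (tiny n only)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan"), float("nan")

    def rho(a, b):
        return float(np.corrcoef(a, b)[0, 1])

    obs = rho(rx, ry)
    n = len(x)
    if n > 8:
        return stats.spearmanr(x, y)
    count = total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(rho(rx, np.asarray(perm))) >= abs(obs) - 1e-12:
            count += 1
    return obs, count / total


def density_quartile_association(
    cells: pd.DataFrame,
    target_type: str,
    functional_markers: list[str],
    positivity_threshold: float = 0.5,
    roi_areas: pd.Series | dict | None = None,
    type_col: str = "cell_type",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Four equal-size infiltration bins of images vs marker-positive fractions.

    Images (ROIs) are ranked by target-type density (cells per mm^2 when
    ``roi_areas`` is given, else cells per image — rank-equivalent for
    equal-size ROIs) and split into four rank bins of equal size (remainders
    to the lower bins), labeled absent/low/medium/high; the lowest bin is
    "absent" only if it contains zero-density images, else "lowest".
    Density ties at bin boundaries break by image id. Per bin and marker,
    the fraction of all cells with normalized marker value above the
    positivity threshold is reported, with a Spearman trend statistic
    (exact permutation p over the 4 bin ranks) per marker.

    Returns (per-image bin table, per-marker trend table).
    """
    roi_ids = sorted(cells["roi_id"].astype(str).unique())
    if len(roi_ids) < 4:
        raise ValueError("need at least 4 images for quartile binning")
    if target_type not in set(cells[type_col].dropna()):
        warnings.warn(
            f"target type {target_type!r} absent from the cohort", RuntimeWarning, stacklevel=2
        )
    counts = (
        cells[cells[type_col] == target_type].groupby(cells["roi_id"].astype(str)).size()
    )
    counts = counts.reindex(roi_ids, fill_value=0).astype(float)
    if roi_areas is not None:
        areas = pd.Series(roi_areas).reindex(roi_ids)
        density = counts / areas
    else:
        density = counts

    order = sorted(roi_ids, key=lambda r: (density[r], r))
    n = len(order)
    base, rem = divmod(n, 4)
    sizes = [base + (1 if b < rem else 0) for b in range(4)]
    bin_of: dict[str, int] = {}
    pos = 0
    for b, size in enumerate(sizes):
        for r in order[pos : pos + size]:
            bin_of[r] = b
        pos += size
    lowest_has_zero = any(density[r] == 0 for r, b in bin_of.items() if b == 0)
    labels = ["absent" if lowest_has_zero else "lowest", "low", "medium", "high"]

    image_table = pd.DataFrame(
        {
            "roi_id": roi_ids,
            "density": [density[r] for r in roi_ids],
            "bin_rank": [bin_of[r] for r in roi_ids],
            "bin": [labels[bin_of[r]] for r in roi_ids],
        }
    )

    cells_bin = cells.assign(_bin=cells["roi_id"].astype(str).map(bin_of))
    trend_rows = []
    for m in functional_markers:
        col = NORM_PREFIX + m if NORM_PREFIX + m in cells.columns else m
        fractions = []
        for b in range(4):
            sub = cells_bin[cells_bin["_bin"] == b]
            frac = float((sub[col] > positivity_threshold).mean()) if len(sub) else float("nan")
            fractions.append(frac)
            trend_rows.append({"marker": m, "bin": labels[b], "bin_rank": b, "fraction": frac})
        rho, p = _exact_spearman_p(np.arange(4, dtype=float), np.asarray(fractions))
        for row in trend_rows[-4:]:
            row["spearman_rho"] = rho
            row["trend_p"] = p
    return image_table, pd.DataFrame(trend_rows)


def roi_type_fractions(cells: pd.DataFrame, type_col: str = "cell_type") -> pd.DataFrame:
    """Per-ROI cell-type fraction table (rows = ROIs, columns = types)."""
    counts = cells.groupby(["roi_id", type_col], observed=True).size().unstack(fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0)


def composition_correlation(
    fractions: pd.DataFrame,
    anchor_type: str = "epithelial",
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlate the anchor type's per-ROI fraction with every other type's.

    Each observation is one ROI. ``method`` is "pearson" (default, matching
    scatter-plot usage) or "spearman". A constant fraction vector yields an
    undefined correlation reported as NA.
    """
    if len(fractions) < 3:
        raise ValueError("need at least 3 ROIs")
    if anchor_type not in fractions.columns:
        raise ValueError(f"anchor type {anchor_type!r} not in fraction table")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    anchor = fractions[anchor_type].to_numpy(dtype=float)
    rows = []
    for ct in fractions.columns:
        if ct == anchor_type:
            continue
        other = fractions[ct].to_numpy(dtype=float)
        if np.ptp(anchor) == 0 or np.ptp(other) == 0:
            r, p = float("nan"), float("nan")
        elif method == "pearson":
            r, p = stats.pearsonr(anchor, other)
        else:
            r, p = stats.spearmanr(anchor, other)
        rows.append(
            {
                "anchor_type": anchor_type,
                "cell_type": ct,
                "method": method,
                "r": float(r),
                "p_value": float(p),
                "n_roi": len(fractions),
            }
        )
    return pd.DataFrame(rows)
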