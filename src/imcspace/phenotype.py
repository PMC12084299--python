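"""Expression normalization, graph clustering and cell-type annotation.

Per-channel intensities are range-normalized to the cohort-wide 99th
percentile, cells are clustered PhenoGraph-style (k-nearest-neighbour graph
in normalized lineage-marker space, Jaccard edge reweighting, modularity
community detection) and clusters are mapped to named populations by
ordered marker gating rules. Batch alignment (e.g. Harmony) is not
reimplemented: ``cluster_expression`` accepts an externally corrected
feature matrix through the ``features`` argument.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
import pandas as pd
import yaml
from scipy import sparse, stats
from sklearn.neighbors import NearestNeighbors

NORM_PREFIX = "norm_"


def norm_columns(markers) -> list[str]:
    return [NORM_PREFIX + m for m in markers]


def normalize_percentile(cells: pd.DataFrame, markers, q: float = 99.0) -> pd.DataFrame:
    """Range-normalize each marker to its q-th percentile over ALL cells.

    The divisor is the linear-interpolation percentile of the raw values
    pooled across every ROI of the cohort; normalized values are clipped to
    [0, 1] and stored in ``norm_<marker>`` columns. A marker whose
    percentile is 0 normalizes to all-zero with a warning.
    """
    if not (0 < q <= 100):
        raise ValueError("q must lie in (0, 100]")
    out = cells.copy()
    for m in markers:
        raw = cells[m].to_numpy(dtype=float)
        divisor = float(np.percentile(raw, q)) if len(raw) else 0.0
        if divisor <= 0:
            warnings.warn(
                f"marker {m!r}: {q}th percentile is 0; normalized values set to 0",
                RuntimeWarning,
                stacklevel=2,
            )
            out[NORM_PREFIX + m] = 0.0
        else:
            out[NORM_PREFIX + m] = np.clip(raw / divisor, 0.0, 1.0)
    return out


def _jaccard_graph(X: np.ndarray, k: int) -> igraph.Graph:
    n = len(X)
    nn = NearestNeighbors(n_neighbors=k).fit(X)
    idx = nn.kneighbors(return_distance=False)  # query on fit data excludes self
    rows = np.repeat(np.arange(n), k)
    adj = sparse.csr_matrix(
        (np.ones(n * k), (rows, idx.ravel())), shape=(n, n)
    )
    shared = adj @ adj.T  # |N(i) & N(j)| over directed neighbour sets
    union = adj + adj.T
    union.data[:] = 1.0
    coo = sparse.triu(union, k=1).tocoo()
    inter = np.asarray(shared[coo.row, coo.col]).ravel()
    jac = inter / (2.0 * k - inter)
    keep = jac > 0
    edges = list(zip(coo.row[keep].tolist(), coo.col[keep].tolist()))
    g = igraph.Graph(n=n, edges=edges)
    g.es["weight"] = jac[keep].tolist()
    return g


def cluster_expression(
    cells: pd.DataFrame,
    markers,
    k_expr: int = 30,
    seed: int = 0,
    resolution: float = 0.3,
    features: np.ndarray | None = None,
) -> pd.DataFrame:
    """PhenoGraph-style clustering of normalized expression.

    Builds the ``k_expr``-nearest-neighbour graph (Euclidean) on the
    ``norm_<marker>`` columns (or the externally supplied ``features``
    matrix, e.g. after batch correction), reweights edges by the Jaccard
    overlap of neighbour sets and partitions with Leiden under the
    Reichardt-Bornholdt configuration-model objective at a fixed seed.
    ``resolution`` controls granularity: at 1.0 plain modularity tends to
    split large homogeneous populations purely for graph-size reasons (the
    resolution limit works in reverse on kNN graphs), so the default is
    0.3, which keeps one community per well-separated population while
    still resolving rare populations. Returns a copy of ``cells`` with a
    ``cluster_id`` column; cluster ids are contiguous integers ordered by
    descending size.
    """
    out = cells.copy()
    n = len(out)
    if n == 0:
        out["cluster_id"] = pd.Series(dtype=int)
        return out
    if features is None:
        X = out[norm_columns(markers)].to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        if len(X) != n:
            raise ValueError("features matrix does not match cell count")

    if len(np.unique(X, axis=0)) == 1:
        out["cluster_id"] = 0
        return out
    k = k_expr
    if k >= n:
        k = n - 1
        warnings.warn(
            f"k_expr={k_expr} >= number of cells ({n}); lowered to {k}",
            RuntimeWarning,
            stacklevel=2,
        )
    g = _jaccard_graph(X, k)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    labels = np.asarray(part.membership)
    out["cluster_id"] = _relabel_by_size(labels)
    return out


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Map labels to contiguous ints ordered by descending cluster size."""
    ids, counts = np.unique(labels, return_counts=True)
    order = ids[np.lexsort((ids, -counts))]
    mapping = {old: new for new, old in enumerate(order)}
    return np.array([mapping[v] for v in labels], dtype=int)


@dataclass
class Rule:
    """One gating rule: all positive markers above, all negative below threshold."""

    cell_type: str
    positive: list[str] = field(default_factory=list)
    negative: list[str] = field(default_factory=list)
    threshold: float = 0.5
    immune: bool = False


@dataclass
class AnnotationRules:
    """Ordered gating rules plus the multi-immune fallback label.

    A cluster matching more than one immune rule is called ``fallback``
    ("mixed immune"); otherwise the first matching rule in file order wins;
    a cluster matching nothing is "unassigned" (reported, never dropped).
    """

    rules: list[Rule]
    fallback: str = "mixed immune"

    def validate(self, markers) -> None:
        known = set(markers)
        for rule in self.rules:
            unknown = (set(rule.positive) | set(rule.negative)) - known
            if unknown:
                raise ValueError(
                    f"rule {rule.cell_type!r} references unknown markers {sorted(unknown)}"
                )

    @classmethod
    def from_yaml(cls, path) -> "AnnotationRules":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        rules = [Rule(**r) for r in payload["rules"]]
        return cls(rules=rules, fallback=payload.get("fallback", "mixed immune"))

    def to_yaml(self, path) -> None:
        payload = {
            "rules": [vars(r) for r in self.rules],
            "fallback": self.fallback,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def default_rules() -> AnnotationRules:
    """Gating rules matching the default synthetic panel's lineage signatures."""
    r = Rule
    # CD8+T and B carry no negative gates on purpose: a population positive
    # for both lineages matches two immune rules and lands in the
    # multi-immune fallback ("mixed immune")
    return AnnotationRules(
        rules=[
            r("Treg", ["CD3", "CD4", "FOXP3"], immune=True),
            r("CD8+ T", ["CD3", "CD8a"], immune=True),
            r("CD4+ T", ["CD3", "CD4"], ["FOXP3"], immune=True),
            r("B", ["CD20"], immune=True),
            r("NK", ["CD57"], immune=True),
            r("neutrophil", ["CD15"], immune=True),
            r("macrophage", ["CD68"], immune=True),
            r("epithelial", ["E-cadherin"]),
            r("mesenchymal", ["Vimentin"], ["aSMA"]),
            r("aSMA+ fibroblast", ["aSMA"]),
            r("endothelial", ["CD31"]),
        ]
    )


def cluster_mean_expression(cells: pd.DataFrame, markers) -> pd.DataFrame:
    """Cluster x marker matrix of mean normalized expression."""
    cols = norm_columns(markers)
    means = cells.groupby("cluster_id")[cols].mean()
    means.columns = list(markers)
    return means


def annotate_clusters(
    cells: pd.DataFrame, rules: AnnotationRules, markers
) -> pd.DataFrame:
    """Assign a cell type to every cluster by ordered marker gating.

    Annotation is a pure function of the cluster mean expression and the
    rules: no randomness, deterministic tie-break by rule order.
    """
    rules.validate(markers)
    means = cluster_mean_expression(cells, markers)
    assignment: dict[int, str] = {}
    for cid, mean in means.iterrows():
        matches = [
            rule
            for rule in rules.rules
            if all(mean[m] > rule.threshold for m in rule.positive)
            and all(mean[m] <= rule.threshold for m in rule.negative)
        ]
        immune_matches = [rule for rule in matches if rule.immune]
        if len(immune_matches) > 1:
            assignment[cid] = rules.fallback
        elif matches:
            assignment[cid] = matches[0].cell_type
        else:
            assignment[cid] = "unassigned"
    out = cells.copy()
    out["cell_type"] = out["cluster_id"].map(assignment)
    n_un = int((out["cell_type"] == "unassigned").sum())
    if n_un:
        warnings.warn(
            f"{n_un} cells in clusters matching no rule were labeled 'unassigned'",
            RuntimeWarning,
            stacklevel=2,
        )
    return out


def composition_summary(
    cells: pd.DataFrame,
    by: str = "sample_id",
    group_col: str = "group",
    type_col: str = "cell_type",
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-unit cell-type fractions plus two-group Wilcoxon rank-sum tests.

    Fractions sum to 1 within each grouping unit. When exactly two groups
    are present, each cell type's per-sample fractions are compared with
    the Wilcoxon rank-sum (Mann-Whitney U) test; otherwise tests are
    skipped with a warning.
    """
    counts = cells.groupby([by, type_col], observed=True).size().unstack(fill_value=0)
    fractions = counts.div(counts.sum(axis=1), axis=0)
    unit_group = cells.groupby(by, observed=True)[group_col].first()

    groups = [g for g in unit_group.unique() if g != ""]
    if len(groups) != 2:
        if len(groups) > 0:
            warnings.warn(
                f"composition tests need exactly 2 groups, found {len(groups)}; skipped",
                RuntimeWarning,
                stacklevel=2,
            )
        return fractions, None
    ga, gb = sorted(groups)
    rows = []
    for ct in fractions.columns:
        a = fractions.loc[unit_group == ga, ct].to_numpy()
        b = fractions.loc[unit_group == gb, ct].to_numpy()
        if len(a) == 0 or len(b) == 0:
            warnings.warn(f"empty group for {ct!r}; omitted", RuntimeWarning, stacklevel=2)
            continue
        if np.ptp(np.concatenate([a, b])) == 0:
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append(
            {
                "cell_type": ct,
                "group_a": ga,
                "group_b": gb,
                "mean_a": a.mean(),
                "mean_b": b.mean(),
                "statistic": stat,
                "p_value": p,
            }
        )
    return fractions, pd.DataFrame(rows)
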