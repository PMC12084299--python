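"""Synthetic multi-ROI tissue cohorts with known ground truth.

Clinical IMC data of the kind this package analyses is rarely deposited, so
every downstream stage is exercised against simulated tissue in which the
answers are planted and known exactly:

* cell centres are placed by a homogeneous Poisson process, with optional
  Neyman-Scott attraction (type-B offspring scattered within a cluster
  radius of type-A parents), hard-core avoidance between chosen type pairs,
  and rectangular niches with their own compositions;
* cells are rendered as non-overlapping discs into an integer label mask;
* marker signal per cell is lognormal per (type, marker), spread over the
  cell's pixels, with additive background, channel spillover and Poisson
  counting noise.

Default cohort structure follows a two-group labial-salivary-gland design:
3 control and 15 case samples, 2 ROIs each (36 ROIs), 12 cell types with a
higher immune fraction in the case group.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .panel import PanelTable, default_panel
from .preprocess import SegmentedROI, SpilloverMatrix

CELL_TYPES: tuple[str, ...] = (
    "epithelial",
    "mesenchymal",
    "endothelial",
    "aSMA+ fibroblast",
    "CD8+ T",
    "CD4+ T",
    "Treg",
    "B",
    "NK",
    "neutrophil",
    "macrophage",
    "mixed immune",
)

#: lineage signatures used by the default expression model
_SIGNATURES: dict[str, tuple[str, ...]] = {
    "epithelial": ("E-cadherin",),
    "mesenchymal": ("Vimentin",),
    "endothelial": ("CD31",),
    "aSMA+ fibroblast": ("aSMA",),
    "CD8+ T": ("CD45", "CD3", "CD8a"),
    "CD4+ T": ("CD45", "CD3", "CD4"),
    "Treg": ("CD45", "CD3", "CD4", "FOXP3"),
    "B": ("CD45", "CD20"),
    "NK": ("CD45", "CD57"),
    "neutrophil": ("CD45", "CD15"),
    "macrophage": ("CD45", "CD68"),
    "mixed immune": ("CD45", "CD3", "CD8a", "CD20"),
}

IMMUNE_TYPES: tuple[str, ...] = CELL_TYPES[4:]

# default per-group compositions; immune fraction ~0.145 (control) vs ~0.26
# (case), epithelial dominant, matching the tissue this design emulates
DEFAULT_PROPORTIONS: dict[str, dict[str, float]] = {
    "control": {
        "epithelial": 0.550, "mesenchymal": 0.150, "endothelial": 0.090,
        "aSMA+ fibroblast": 0.065, "CD8+ T": 0.025, "CD4+ T": 0.012,
        "Treg": 0.008, "B": 0.015, "NK": 0.008, "neutrophil": 0.007,
        "macrophage": 0.030, "mixed immune": 0.040,
    },
    "pSS": {
        "epithelial": 0.460, "mesenchymal": 0.130, "endothelial": 0.080,
        "aSMA+ fibroblast": 0.070, "CD8+ T": 0.060, "CD4+ T": 0.025,
        "Treg": 0.015, "B": 0.035, "NK": 0.010, "neutrophil": 0.010,
        "macrophage": 0.035, "mixed immune": 0.070,
    },
}

# positive signal: tight lognormal well above background; background: dim but
# broad on the log scale, so that even for a rare marker (positive fraction
# ~1%, where the cohort 99th percentile can fall into the background tail)
# background cluster means stay well below half the normalization divisor
_HIGH, _LOW, _DNA = 20.0, 0.15, 15.0
_SIGMA_HIGH, _SIGMA_LOW = 0.15, 0.8


def default_expression_model(
    panel: PanelTable | None = None, cell_types: tuple[str, ...] = CELL_TYPES
) -> dict[str, dict[str, tuple[float, float]]]:
    """Lognormal (log-location, log-scale) per (cell type, marker).

    Purely synthetic: high lineage-marker signal on each type's signature
    markers, low signal elsewhere, DNA positive in all types, functional and
    disease markers low by default. Not estimated from any real tissue.
    """
    panel = panel or default_panel()
    model: dict[str, dict[str, tuple[float, float]]] = {}
    for ct in cell_types:
        sig = _SIGNATURES.get(ct, ())
        row: dict[str, tuple[float, float]] = {}
        for _, rec in panel.frame.iterrows():
            m = rec["marker"]
            if rec["category"] == "dna":
                row[m] = (math.log(_DNA), _SIGMA_HIGH)
            elif m in sig:
                row[m] = (math.log(_HIGH), _SIGMA_HIGH)
            else:
                row[m] = (math.log(_LOW), _SIGMA_LOW)
        model[ct] = row
    return model


@dataclass
class AttractionPair:
    """Plant spatial attraction: type_b offspring cluster around type_a parents."""

    type_a: str
    type_b: str
    cluster_radius: float = 15.0
    offspring_per_parent: int = 5


@dataclass
class AvoidancePair:
    """Plant spatial avoidance: no type_a--type_b pair within exclusion_radius."""

    type_a: str
    type_b: str
    exclusion_radius: float = 40.0


@dataclass
class NicheRegion:
    """Axis-aligned rectangle [x0, x1) x [y0, y1) with its own composition."""

    name: str
    x0: float
    y0: float
    x1: float
    y1: float
    proportions: dict[str, float]

    @property
    def area(self) -> float:
        return max(self.x1 - self.x0, 0.0) * max(self.y1 - self.y0, 0.0)

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1


class PackingError(RuntimeError):
    """Requested cell density incompatible with non-overlapping discs."""


@dataclass
class SyntheticCohortSpec:
    """Full generative description of a simulated cohort."""

    n_samples_per_group: dict[str, int] = field(
        default_factory=lambda: {"control": 3, "pSS": 15}
    )
    rois_per_sample: int = 2
    roi_width: int = 300
    roi_height: int = 300
    mean_cells_per_roi: float = 500.0
    cell_types: tuple[str, ...] = CELL_TYPES
    proportions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(p) for g, p in DEFAULT_PROPORTIONS.items()}
    )
    attraction_pairs: list[AttractionPair] = field(default_factory=list)
    avoidance_pairs: list[AvoidancePair] = field(default_factory=list)
    niche_layout: list[NicheRegion] | None = None
    expression_model: dict[str, dict[str, tuple[float, float]]] | None = None
    background_rate: float = 0.3
    spillover: SpilloverMatrix | None = None
    cell_radius: float = 2.0
    counting_noise: bool = True
    max_place_attempts: int = 100
    seed: int = 0
    panel: PanelTable = field(default_factory=default_panel)

    def __post_init__(self) -> None:
        self.cell_types = tuple(self.cell_types)
        if self.expression_model is None:
            self.expression_model = default_expression_model(self.panel, self.cell_types)
        self.validate()

    def validate(self) -> None:
        if self.rois_per_sample < 0 or self.mean_cells_per_roi < 0:
            raise ValueError("counts must be >= 0")
        if any(n < 0 for n in self.n_samples_per_group.values()):
            raise ValueError("sample counts must be >= 0")
        if min(self.roi_width, self.roi_height) <= 2 * self.cell_radius:
            raise ValueError("ROI dimensions must exceed 2 x cell_radius")
        for group in self.n_samples_per_group:
            if group not in self.proportions:
                raise ValueError(f"no composition given for group {group!r}")
        for group, props in self.proportions.items():
            unknown = set(props) - set(self.cell_types)
            if unknown:
                raise ValueError(f"composition of {group!r} names unknown types {sorted(unknown)}")
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"proportions for {group!r} sum to {total}, not 1")
        if self.niche_layout:
            roi_area = self.roi_width * self.roi_height
            total = sum(r.area for r in self.niche_layout)
            if abs(total - roi_area) > 1e-6 * roi_area:
                raise ValueError("niche_layout must partition the ROI rectangle")
            for region in self.niche_layout:
                if abs(sum(region.proportions.values()) - 1.0) > 1e-9:
                    raise ValueError(f"niche {region.name!r} proportions do not sum to 1")
        for pair in self.attraction_pairs:
            if pair.cluster_radius <= 0:
                raise ValueError("cluster_radius must be > 0")
            if pair.offspring_per_parent < 1:
                raise ValueError("offspring_per_parent must be >= 1")
        for pair in self.avoidance_pairs:
            if pair.exclusion_radius < 0:
                raise ValueError("exclusion_radius must be >= 0")
        offspring = {p.type_b for p in self.attraction_pairs} | {
            p.type_b for p in self.avoidance_pairs
        }
        anchors = {p.type_a for p in self.attraction_pairs} | {
            p.type_a for p in self.avoidance_pairs
        }
        cyclic = offspring & anchors
        if cyclic:
            raise ValueError(
                f"types {sorted(cyclic)} are both anchor (type_a) and dependent (type_b); "
                "chained spatial structure is not supported"
            )

    def marker_names(self) -> list[str]:
        return self.panel.markers

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        payload["panel"] = self.panel.frame.to_dict(orient="list")
        payload["spillover"] = (
            None if self.spillover is None else self.spillover.matrix.tolist()
        )
        payload["cell_types"] = list(self.cell_types)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


@dataclass
class GroundTruth:
    """Planted truth for a generated ROI or cohort.

    ``cells`` has one row per cell: roi_id, cell_id, true_type and (when a
    niche layout is set) niche_id. ``planted_pairs`` records the attraction /
    avoidance structure that was injected.
    """

    cells: pd.DataFrame = field(repr=False)
    planted_pairs: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "cells": self.cells.to_dict(orient="list"),
            "planted_pairs": self.planted_pairs,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


class _HardCoreGrid:
    """Uniform hash grid for 'is any accepted point within d?' queries."""

    def __init__(self, min_dist: float):
        self.min_dist = float(min_dist)
        self.cell = max(self.min_dist, 1e-9)
        self.buckets: dict[tuple[int, int], list[tuple[float, float]]] = {}

    def _key(self, x: float, y: float) -> tuple[int, int]:
        return (int(x // self.cell), int(y // self.cell))

    def ok(self, x: float, y: float) -> bool:
        kx, ky = self._key(x, y)
        d2 = self.min_dist * self.min_dist
        for ix in (kx - 1, kx, kx + 1):
            for iy in (ky - 1, ky, ky + 1):
                for px, py in self.buckets.get((ix, iy), ()):
                    if (px - x) ** 2 + (py - y) ** 2 <= d2:
                        return False
        return True

    def add(self, x: float, y: float) -> None:
        self.buckets.setdefault(self._key(x, y), []).append((x, y))


def _type_counts(rng, spec: SyntheticCohortSpec, props: dict[str, float], n: int) -> dict[str, int]:
    p = np.array([props.get(ct, 0.0) for ct in spec.cell_types], dtype=float)
    draws = rng.multinomial(n, p / p.sum()) if n > 0 else np.zeros(len(p), int)
    return {ct: int(c) for ct, c in zip(spec.cell_types, draws)}


def sample_roi_points(
    spec: SyntheticCohortSpec, group: str, seed
) -> pd.DataFrame:
    """Sample cell centres and true types for one ROI (no rendering).

    Returns a DataFrame with x, y, true_type and niche_id columns. Placement
    honours hard-core non-overlap of cell discs, planted attraction
    (Neyman-Scott offspring around parents), planted avoidance (rejection
    resampling outside the exclusion radius) and the niche layout.
    """
    rng = np.random.default_rng(seed)
    props = spec.proportions[group]
    w, h, r = spec.roi_width, spec.roi_height, spec.cell_radius
    lo_x, hi_x = r, w - r
    lo_y, hi_y = r, h - r
    roi_area = w * h

    # per-niche (or global) type counts
    if spec.niche_layout:
        regions = spec.niche_layout
        region_counts = [
            _type_counts(rng, spec, reg.proportions, rng.poisson(spec.mean_cells_per_roi * reg.area / roi_area))
            for reg in regions
        ]
    else:
        regions = [NicheRegion("", 0.0, 0.0, float(w), float(h), dict(props))]
        region_counts = [_type_counts(rng, spec, props, rng.poisson(spec.mean_cells_per_roi))]

    attraction_by_b = {p.type_b: p for p in spec.attraction_pairs}
    avoidance_by_b: dict[str, list[AvoidancePair]] = {}
    for p in spec.avoidance_pairs:
        avoidance_by_b.setdefault(p.type_b, []).append(p)
    dependent = set(attraction_by_b) | set(avoidance_by_b)

    grid = _HardCoreGrid(2.0 * r)
    xs: list[float] = []
    ys: list[float] = []
    types: list[str] = []
    niches: list[str] = []
    by_type_pos: dict[str, list[tuple[float, float]]] = {ct: [] for ct in spec.cell_types}

    def clamp_box(reg: NicheRegion) -> tuple[float, float, float, float]:
        return (max(reg.x0, lo_x), min(reg.x1, hi_x), max(reg.y0, lo_y), min(reg.y1, hi_y))

    def place(ct: str, reg: NicheRegion, proposal) -> None:
        bx0, bx1, by0, by1 = clamp_box(reg)
        excl = avoidance_by_b.get(ct, [])
        for _ in range(spec.max_place_attempts):
            x, y = proposal(bx0, bx1, by0, by1)
            if not (bx0 <= x <= bx1 and by0 <= y <= by1):
                continue
            if not grid.ok(x, y):
                continue
            violated = False
            for pair in excl:
                d2 = pair.exclusion_radius**2
                for ax, ay in by_type_pos[pair.type_a]:
                    if (ax - x) ** 2 + (ay - y) ** 2 <= d2:
                        violated = True
                        break
                if violated:
                    break
            if violated:
                continue
            grid.add(x, y)
            xs.append(x); ys.append(y); types.append(ct); niches.append(reg.name)
            by_type_pos[ct].append((x, y))
            return
        raise PackingError(
            f"could not place a {ct!r} cell after {spec.max_place_attempts} attempts "
            f"(ROI for group {group!r}): density too high for non-overlapping discs"
        )

    def uniform(bx0, bx1, by0, by1):
        return rng.uniform(bx0, bx1), rng.uniform(by0, by1)

    # phase 1: anchor / unstructured types
    for reg, counts in zip(regions, region_counts):
        for ct in spec.cell_types:
            if ct in dependent:
                continue
            for _ in range(counts[ct]):
                place(ct, reg, uniform)

    # phase 2: dependent types (Neyman-Scott offspring, hard-core avoiders)
    for reg, counts in zip(regions, region_counts):
        for ct in spec.cell_types:
            if ct not in dependent:
                continue
            n_b = counts[ct]
            if n_b == 0:
                continue
            att = attraction_by_b.get(ct)
            parents: np.ndarray | None = None
            if att is not None:
                cand = [
                    (x, y) for x, y in by_type_pos[att.type_a] if reg.contains(x, y)
                ] or by_type_pos[att.type_a]
                if cand:
                    n_par = min(len(cand), max(1, math.ceil(n_b / att.offspring_per_parent)))
                    idx = rng.choice(len(cand), size=n_par, replace=False)
                    parents = np.asarray(cand)[idx]
                else:
                    warnings.warn(
                        f"attraction pair ({att.type_a!r} -> {ct!r}): no parent cells "
                        "placed; offspring fall back to uniform placement",
                        RuntimeWarning,
                        stacklevel=2,
                    )

            if parents is None:
                proposal = uniform
            else:
                radius = att.cluster_radius

                def proposal(bx0, bx1, by0, by1, _parents=parents, _radius=radius):
                    px, py = _parents[rng.integers(len(_parents))]
                    rr = _radius * math.sqrt(rng.uniform())
                    theta = rng.uniform(0.0, 2.0 * math.pi)
                    return px + rr * math.cos(theta), py + rr * math.sin(theta)

            for _ in range(n_b):
                place(ct, reg, proposal)

    return pd.DataFrame(
        {
            "x": np.array(xs, dtype=float),
            "y": np.array(ys, dtype=float),
            "true_type": pd.Series(types, dtype=object),
            "niche_id": pd.Series(niches, dtype=object),
        }
    )


def _draw_expression(
    rng, spec: SyntheticCohortSpec, types: pd.Series
) -> np.ndarray:
    """Per-cell lognormal mean signal, cells x channels."""
    markers = spec.marker_names()
    loc = np.zeros((len(spec.cell_types), len(markers)))
    scale = np.zeros_like(loc)
    for ti, ct in enumerate(spec.cell_types):
        row = spec.expression_model[ct]
        for mi, m in enumerate(markers):
            loc[ti, mi], scale[ti, mi] = row[m]
    t_idx = np.array([spec.cell_types.index(t) for t in types], dtype=int)
    z = rng.standard_normal((len(t_idx), len(markers)))
    return np.exp(loc[t_idx] + scale[t_idx] * z)


def _render_roi(
    rng,
    spec: SyntheticCohortSpec,
    points: pd.DataFrame,
    expr: np.ndarray,
    roi_id: str,
    sample_id: str,
    group: str,
) -> SegmentedROI:
    h, w = spec.roi_height, spec.roi_width
    c = len(spec.marker_names())
    mask = np.zeros((h, w), dtype=np.int32)
    img = np.zeros((c, h, w), dtype=float)

    r = spec.cell_radius
    ir = int(math.ceil(r))
    for i, (x, y) in enumerate(zip(points["x"], points["y"])):
        y0, y1 = max(int(y) - ir - 1, 0), min(int(y) + ir + 2, h)
        x0, x1 = max(int(x) - ir - 1, 0), min(int(x) + ir + 2, w)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        disc = (yy - y) ** 2 + (xx - x) ** 2 <= r * r
        mask[yy[disc], xx[disc]] = i + 1
        img[:, yy[disc], xx[disc]] = expr[i][:, None]

    img += spec.background_rate
    if spec.spillover is not None and not spec.spillover.is_identity:
        img = np.einsum("ij,ihw->jhw", spec.spillover.matrix, img)
    if spec.counting_noise:
        img = rng.poisson(img).astype(float)
    return SegmentedROI(
        img.astype(np.float32), mask, spec.marker_names(),
        roi_id=roi_id, sample_id=sample_id, group=group,
    )


def generate_roi(
    spec: SyntheticCohortSpec,
    group: str,
    seed,
    roi_id: str = "roi_1",
    sample_id: str = "sample_1",
    render: bool = True,
) -> tuple[SegmentedROI | None, pd.DataFrame, GroundTruth]:
    """Generate one ROI: label-mask image stack, true cell table, ground truth.

    The cell table carries the true centroids and the true per-cell mean raw
    signal (before background, spillover and counting noise); the rendered
    image carries all three corruptions so the preprocessing chain has real
    work to do. ``render=False`` skips image rendering (point-pattern studies).
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_place, s_expr, s_noise = ss.spawn(3)
    points = sample_roi_points(spec, group, s_place)
    expr = _draw_expression(np.random.default_rng(s_expr), spec, points["true_type"])

    markers = spec.marker_names()
    n = len(points)
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(1, n + 1, dtype=int),
            "roi_id": roi_id,
            "sample_id": sample_id,
            "group": group,
            "x": points["x"].to_numpy(),
            "y": points["y"].to_numpy(),
            "area": np.nan,
        }
    )
    cells[markers] = expr

    truth = GroundTruth(
        cells=pd.DataFrame(
            {
                "roi_id": roi_id,
                "cell_id": cells["cell_id"],
                "true_type": points["true_type"].to_numpy(),
                "niche_id": points["niche_id"].to_numpy(),
            }
        ),
        planted_pairs={
            "attraction": [asdict(p) for p in spec.attraction_pairs],
            "avoidance": [asdict(p) for p in spec.avoidance_pairs],
        },
    )

    roi = None
    if render:
        roi = _render_roi(
            np.random.default_rng(s_noise), spec, points, expr, roi_id, sample_id, group
        )
        if n > 0:
            areas = np.bincount(roi.mask.ravel(), minlength=n + 1)[1:]
            cells["area"] = areas.astype(int)
    return roi, cells, truth


def generate_cohort(
    spec: SyntheticCohortSpec, render: bool = True
) -> tuple[list[SegmentedROI], pd.DataFrame, GroundTruth]:
    """Generate the full multi-group cohort.

    Per-ROI seeds are derived from the master seed and the (group, sample,
    roi) indices via :class:`numpy.random.SeedSequence`, so any single ROI is
    reproducible in isolation and the whole cohort is byte-identical under a
    fixed spec + seed.
    """
    rois: list[SegmentedROI] = []
    tables: list[pd.DataFrame] = []
    truths: list[pd.DataFrame] = []
    seen: set[str] = set()
    for gi, (group, n_samples) in enumerate(spec.n_samples_per_group.items()):
        for si in range(n_samples):
            sample_id = f"{group}_s{si + 1:02d}"
            if sample_id in seen:
                raise ValueError(f"duplicate sample identifier {sample_id!r}")
            seen.add(sample_id)
            for ri in range(spec.rois_per_sample):
                roi_id = f"{sample_id}_r{ri + 1}"
                child = np.random.SeedSequence(
                    entropy=spec.seed, spawn_key=(gi, si, ri)
                )
                roi, cells, truth = generate_roi(
                    spec, group, child, roi_id=roi_id, sample_id=sample_id, render=render
                )
                if roi is not None:
                    rois.append(roi)
                tables.append(cells)
                truths.append(truth.cells)
    cells = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    truth_cells = pd.concat(truths, ignore_index=True) if truths else pd.DataFrame()
    truth = GroundTruth(
        cells=truth_cells,
        planted_pairs={
            "attraction": [asdict(p) for p in spec.attraction_pairs],
            "avoidance": [asdict(p) for p in spec.avoidance_pairs],
        },
    )
    return rois, cells, truth


def write_cohort(outdir, spec: SyntheticCohortSpec, rois, cells, truth) -> None:
    """Write a generated cohort to disk (OME-TIFFs, masks, tables, truth, spec)."""
    from pathlib import Path
    from .preprocess import write_roi

    out = Path(outdir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)
    for roi in rois:
        write_roi(roi, out / "images" / f"{roi.roi_id}.ome.tiff", out / "masks" / f"{roi.roi_id}.tiff")
    cells.to_csv(out / "cells_true.csv", index=False)
    truth.to_json(out / "ground_truth.json")
    spec.to_yaml(out / "cohort_spec.yaml")
    spec.panel.to_csv(out / "panel.csv")
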