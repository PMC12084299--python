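"""End-to-end pipeline orchestration.

``run_pipeline`` chains quantify -> normalize -> cluster -> annotate ->
neighborhoods -> interactions -> report over a configured input (either a
simulated cohort or on-disk images + masks), writing every stage table to
the output directory plus a JSON manifest of parameters, seed and stage
checksums. Re-running an identical config reproduces identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import interactions as istats
from . import neighborhoods as nbr
from . import phenotype as phen
from . import preprocess as prep
from . import report as rep
from . import synthetic as syn
from .panel import PanelTable, default_panel

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage (and ROI)."""


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Exactly one input source: ``simulate`` (a synthetic cohort spec, dict
    form) or ``images``/``masks``/``panel`` paths. All randomness derives
    from ``seed``.
    """

    seed: int = 0
    simulate: dict | None = None
    images: str | None = None
    masks: str | None = None
    panel: str | None = None
    spillover: str | None = None
    rules: str | None = None
    median_window: int = 3
    adjust: tuple[float, float] | None = (1.0, 99.0)
    q: float = 99.0
    k_expr: int = 30
    k_spatial: int = 20
    k_cn: int = 10
    n_perm: int = 1000
    alpha: float = 0.05
    positivity_threshold: float = 0.5
    group_col: str = "group"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.images is None):
            raise ValueError("config needs exactly one of 'simulate' or 'images'")
        if self.images is not None:
            if self.masks is None or self.panel is None:
                raise ValueError("image input requires 'masks' and 'panel' paths")
            for label in ("images", "masks", "panel", "spillover", "rules"):
                path = getattr(self, label)
                if path is not None and not Path(path).exists():
                    raise FileNotFoundError(f"config {label!r}: no such path: {path}")
        elif self.rules is not None and not Path(self.rules).exists():
            raise FileNotFoundError(f"config 'rules': no such path: {self.rules}")
        if self.median_window % 2 == 0:
            raise ValueError("median_window must be odd")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if "adjust" in payload and payload["adjust"] is not None:
            payload["adjust"] = tuple(payload["adjust"])
        return cls(**payload)

    def to_dict(self) -> dict:
        d = dict(vars(self))
        if d["adjust"] is not None:
            d["adjust"] = list(d["adjust"])
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    frame.to_csv(path, index=index, float_format="%.10g")


def _load_input(config: RunConfig):
    """Return (rois, panel, spillover, truth_cells_or_None)."""
    if config.simulate is not None:
        payload = dict(config.simulate)
        payload.setdefault("seed", config.seed)
        for key, cls in (("attraction_pairs", syn.AttractionPair), ("avoidance_pairs", syn.AvoidancePair)):
            if key in payload:
                payload[key] = [
                    cls(**p) if isinstance(p, dict) else p for p in payload[key]
                ]
        spec = syn.SyntheticCohortSpec(**payload)
        rois, _, truth = syn.generate_cohort(spec)
        spill = spec.spillover
        return rois, spec.panel, spill, truth.cells
    panel = PanelTable.from_csv(config.panel)
    spill = (
        prep.SpilloverMatrix.from_csv(config.spillover)
        if config.spillover is not None
        else None
    )
    rois = []
    image_dir, mask_dir = Path(config.images), Path(config.masks)
    for img_path in sorted(image_dir.glob("*.tif*")):
        roi_id = img_path.name.split(".")[0]
        candidates = list(mask_dir.glob(f"{roi_id}.tif*"))
        if not candidates:
            raise FileNotFoundError(f"no mask found for ROI {roi_id!r} in {mask_dir}")
        rois.append(
            prep.read_roi(img_path, candidates[0], panel.markers, roi_id=roi_id)
        )
    if not rois:
        raise FileNotFoundError(f"no images found in {image_dir}")
    return rois, panel, spill, None


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Execute the full analysis; returns the output directory.

    Stage tables written: cells_raw, cells_annotated, cluster_markers,
    composition(+tests), cn_centroids, cn_fractions(+tests), interactions
    (per-ROI permutation results), interaction_group_tests, figures, and
    manifest.json with the config, seed and per-file SHA-256 checksums.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load_input"
    try:
        rois, panel, spill, truth = _load_input(config)

        stage = "quantify"
        tables = []
        for roi in rois:
            try:
                tables.append(
                    prep.preprocess_and_quantify(
                        roi,
                        spillover=spill,
                        median_window=config.median_window,
                        adjust=config.adjust,
                    )
                )
            except Exception as exc:  # noqa: BLE001 - re-raise with ROI context
                raise StageError(f"stage 'quantify' failed on ROI {roi.roi_id!r}: {exc}") from exc
        cells = pd.concat(tables, ignore_index=True)
        _write(cells, out / "cells_raw.csv")

        stage = "normalize"
        markers = panel.markers
        lineage = panel.lineage_markers
        cells = phen.normalize_percentile(cells, markers, q=config.q)

        stage = "cluster"
        cells = phen.cluster_expression(cells, lineage, k_expr=config.k_expr, seed=config.seed)

        stage = "annotate"
        rules = (
            phen.AnnotationRules.from_yaml(config.rules)
            if config.rules is not None
            else phen.default_rules()
        )
        cells = phen.annotate_clusters(cells, rules, markers)
        _write(cells, out / "cells_annotated.csv")
        _write(phen.cluster_mean_expression(cells, markers), out / "cluster_markers.csv", index=True)

        stage = "composition"
        fractions, comp_tests = phen.composition_summary(cells, group_col=config.group_col)
        _write(fractions, out / "composition.csv", index=True)
        if comp_tests is not None:
            _write(comp_tests, out / "composition_tests.csv")

        stage = "neighborhoods"
        graph = nbr.spatial_knn(cells, k=config.k_spatial)
        profiles = nbr.neighborhood_profiles(graph, cells)
        model = nbr.cluster_neighborhoods(profiles, k_cn=config.k_cn, seed=config.seed)
        cells = cells.merge(model.assignments, on=["roi_id", "cell_id"], how="left")
        cn_labels = nbr.annotate_cns(model)
        centroids = model.centroids.copy()
        centroids["label"] = [cn_labels[i] for i in centroids.index]
        _write(centroids, out / "cn_centroids.csv", index=True)
        cn_fracs, cn_tests = nbr.cn_abundance_compare(cells, group_col=config.group_col)
        _write(cn_fracs, out / "cn_fractions.csv", index=True)
        if cn_tests is not None:
            _write(cn_tests, out / "cn_tests.csv")

        stage = "interactions"
        results = istats.permutation_test(
            graph, cells, n_perm=config.n_perm, seed=config.seed, alpha=config.alpha
        )
        _write(results, out / "interactions.csv")
        roi_groups = cells.groupby("roi_id")[config.group_col].first()
        if roi_groups.nunique() == 2 and len(results):
            _write(
                istats.compare_interactions_groups(results, roi_groups),
                out / "interaction_group_tests.csv",
            )
        _write(cells, out / "cells_final.csv")
        if truth is not None:
            _write(truth, out / "ground_truth.csv")

        stage = "report"
        rep.render_summary_figures(
            out / "figures",
            {
                "cluster_markers": pd.read_csv(out / "cluster_markers.csv", index_col=0),
                "composition": fractions,
                "cn_centroids": model.centroids,
                "interactions": results,
            },
        )
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "pipeline_order": list(prep.PIPELINE_ORDER),
        "checksums": {
            p.name: _sha256(p) for p in sorted(out.glob("*.csv"))
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %s", out)
    return out
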