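"""Antibody panel handling.

An IMC panel maps acquisition channels (metal isotope tags) to marker names
and assigns each marker a category:

* ``lineage``    -- markers used to call cell identity (enter clustering),
* ``functional`` -- activation / inflammation markers (gated, not clustered),
* ``pSS_marker`` -- disease-associated markers (gated, not clustered),
* ``dna``        -- intercalator channels (excluded from analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

CATEGORIES = ("lineage", "functional", "pSS_marker", "dna")


@dataclass
class PanelTable:
    """Channel-ordered marker panel.

    ``frame`` has one row per channel with columns
    ``channel`` (0-based index), ``metal``, ``marker``, ``category``.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"channel", "metal", "marker", "category"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"panel missing columns: {sorted(missing)}")
        if self.frame["marker"].duplicated().any():
            dup = self.frame["marker"][self.frame["marker"].duplicated()].tolist()
            raise ValueError(f"duplicate marker names in panel: {dup}")
        bad = set(self.frame["category"]) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown panel categories: {sorted(bad)}")
        if not (self.frame["category"] == "lineage").any():
            raise ValueError("panel must contain at least one lineage marker")
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def markers(self) -> list[str]:
        return self.frame["marker"].tolist()

    def markers_of(self, *categories: str) -> list[str]:
        sel = self.frame["category"].isin(categories)
        return self.frame.loc[sel, "marker"].tolist()

    @property
    def lineage_markers(self) -> list[str]:
        return self.markers_of("lineage")

    @property
    def functional_markers(self) -> list[str]:
        return self.markers_of("functional", "pSS_marker")

    @classmethod
    def from_csv(cls, path) -> "PanelTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def default_panel() -> PanelTable:
    """A compact labial-salivary-gland style panel.

    Thirteen lineage markers resolve the twelve tissue populations
    (epithelial, mesenchymal, endothelial, aSMA+ fibroblast and eight
    immune populations); the functional / disease markers are carried for
    positivity gating only. Metal assignments are nominal.
    """
    rows = [
        ("La139", "E-cadherin", "lineage"),
        ("Pr141", "Vimentin", "lineage"),
        ("Nd143", "CD31", "lineage"),
        ("Nd145", "aSMA", "lineage"),
        ("Nd146", "CD45", "lineage"),
        ("Sm147", "CD3", "lineage"),
        ("Nd148", "CD4", "lineage"),
        ("Sm149", "CD8a", "lineage"),
        ("Nd150", "FOXP3", "lineage"),
        ("Sm152", "CD20", "lineage"),
        ("Eu153", "CD57", "lineage"),
        ("Sm154", "CD15", "lineage"),
        ("Gd155", "CD68", "lineage"),
        ("Gd156", "Ki67", "functional"),
        ("Gd158", "GranzymeB", "functional"),
        ("Tb159", "CCR7", "functional"),
        ("Gd160", "S100A9", "functional"),
        ("Dy161", "SSA", "pSS_marker"),
        ("Dy162", "SSB", "pSS_marker"),
        ("Dy163", "MMP9", "pSS_marker"),
        ("Ir191", "DNA1", "dna"),
    ]
    frame = pd.DataFrame(
        {
            "channel": range(len(rows)),
            "metal": [r[0] for r in rows],
            "marker": [r[1] for r in rows],
            "category": [r[2] for r in rows],
        }
    )
    return PanelTable(frame)
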