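"""Registry of the 72 white-matter bundles of the TractSeg segmentation.

Tract masks themselves are inputs (bundle segmentation is a published-tool
step); the registry only encodes the bundle names and the anatomical
attributes the analysis needs: hemisphere (left / right / commissural),
region (supratentorial / infratentorial) and whether the bundle is excluded
from tract statistics.  The fornix is excluded for unavoidable CSF
partial-volume effects and the striatal projection bundles for their
anatomical overlap with the thalamic projections.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd

__all__ = ["TractRegistry", "load_registry"]

HEMISPHERES = ("left", "right", "commissural")
REGIONS = ("supratentorial", "infratentorial")


@dataclass
class TractRegistry:
    """Bundle names with hemisphere/region labels and exclusion flags."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"name", "hemisphere", "region", "excluded"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"registry table missing columns: {sorted(missing)}")
        bad_h = set(self.table["hemisphere"]) - set(HEMISPHERES)
        bad_r = set(self.table["region"]) - set(REGIONS)
        if bad_h or bad_r:
            raise ValueError(f"unknown hemisphere/region labels: {bad_h | bad_r}")
        if self.table["name"].duplicated().any():
            raise ValueError("duplicate bundle names in registry")
        self.table = self.table.reset_index(drop=True)

    @property
    def names(self) -> list[str]:
        """All bundle names, before exclusion."""
        return list(self.table["name"])

    @property
    def excluded(self) -> set[str]:
        return set(self.table.loc[self.table["excluded"] == 1, "name"])

    @property
    def included(self) -> list[str]:
        return list(self.table.loc[self.table["excluded"] == 0, "name"])

    def hemisphere(self, name: str) -> str:
        return self._lookup(name, "hemisphere")

    def region(self, name: str) -> str:
        return self._lookup(name, "region")

    def _lookup(self, name: str, col: str):
        rows = self.table.loc[self.table["name"] == name, col]
        if rows.empty:
            raise KeyError(f"unknown bundle name: {name!r}")
        return rows.iloc[0]

    def homologue_base(self, name: str) -> str:
        """Base name shared by left/right homologues (``CST`` for ``CST_left``)."""
        for suffix in ("_left", "_right"):
            if name.endswith(suffix):
                return name[: -len(suffix)]
        return name

    def __len__(self) -> int:
        return len(self.table)


def load_registry() -> TractRegistry:
    """Load the packaged 72-bundle registry."""
    ref = importlib.resources.files("perilesion") / "data" / "tract_registry.tsv"
    with importlib.resources.as_file(ref) as path:
        table = pd.read_csv(path, sep="\t")
    return TractRegistry(table)
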