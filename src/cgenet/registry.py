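"""Region registry: canonical region ids, anatomical grouping, and the fixed
pseudoanatomical 2-D layout used for network figures.

The packaged default covers the 27 forebrain regions of interest commonly
profiled in rat immediate-early-gene mapping studies, grouped into five
anatomical territories (prefrontal cortex, sensorimotor cortex, striatum,
hippocampus/septum, amygdala/hypothalamus). Layout coordinates are an
arbitrary packaged constant on a unitless plane: cortex at the top, striatum
center, hippocampus/septum left, amygdala/hypothalamus at the bottom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import UnknownRegion

AREA_GROUPS = (
    "prefrontal cortex",
    "sensorimotor cortex",
    "striatum",
    "hippocampus/septum",
    "amygdala/hypothalamus",
)


@dataclass(frozen=True)
class Region:
    id: str
    full_name: str
    area_group: str
    layout_xy: tuple[float, float]


@dataclass(frozen=True)
class RegionRegistry:
    """Ordered collection of regions with unique, case-normalized ids."""

    regions: tuple[Region, ...]
    _lookup: dict[str, Region] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        lookup: dict[str, Region] = {}
        for reg in self.regions:
            if not reg.id:
                raise ValueError("empty region id")
            key = reg.id.lower()
            if key in lookup:
                raise ValueError(f"duplicate region id {reg.id!r}")
            lookup[key] = reg
        object.__setattr__(self, "_lookup", lookup)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.regions]

    def __len__(self) -> int:
        return len(self.regions)

    def __contains__(self, region_id: str) -> bool:
        return region_id.lower() in self._lookup

    def resolve(self, region_id: str) -> str:
        """Canonicalize a (case-insensitive) region id to registry spelling."""
        try:
            return self._lookup[region_id.lower()].id
        except KeyError:
            raise UnknownRegion(f"region {region_id!r} not in registry") from None

    def region(self, region_id: str) -> Region:
        reg = self._lookup.get(region_id.lower())
        if reg is None:
            raise UnknownRegion(f"region {region_id!r} not in registry")
        return reg

    def layout(self) -> dict[str, tuple[float, float]]:
        return {r.id: r.layout_xy for r in self.regions}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": [r.id for r in self.regions],
                "full_name": [r.full_name for r in self.regions],
                "area_group": [r.area_group for r in self.regions],
                "x": [r.layout_xy[0] for r in self.regions],
                "y": [r.layout_xy[1] for r in self.regions],
            }
        )


def load_registry(path: str | Path) -> RegionRegistry:
    """Read a registry TSV with header region_id, full_name, area_group, x, y."""
    df = pd.read_csv(path, sep="\t", dtype={"region_id": str})
    required = {"region_id", "full_name", "area_group", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"registry file missing columns: {sorted(missing)}")
    regions = tuple(
        Region(
            id=row.region_id,
            full_name=row.full_name,
            area_group=row.area_group,
            layout_xy=(float(row.x), float(row.y)),
        )
        for row in df.itertuples()
    )
    return RegionRegistry(regions)


def default_region_registry() -> RegionRegistry:
    """The packaged 27-region registry with fixed pseudoanatomical layout."""
    with resources.as_file(
        resources.files("cgenet").joinpath("data/regions.tsv")
    ) as p:
        return load_registry(p)
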