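"""Region polygons (states, urbanized-area city boundaries) and membership.

Regions are shapely polygons in the same planar-km coordinates as the
grid.  A grid cell belongs to a region when the cell's *centroid* lies in
the region polygon, which is unambiguous for cells straddling a border.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from shapely.prepared import prep

__all__ = ["Region", "RegionSet"]


@dataclass
class Region:
    region_id: str
    kind: str  # "state" or "city"
    geometry: object  # shapely geometry
    population: float = 0.0


class RegionOverlapError(ValueError):
    """Two regions of one set claim the same cell centroid."""


@dataclass
class RegionSet:
    regions: list[Region]

    def __iter__(self):
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    @property
    def ids(self) -> list[str]:
        return [r.region_id for r in self.regions]

    def assign_points(self, xy: np.ndarray, allow_unassigned: bool = True) -> pd.Series:
        """Region id for each (x, y) point; NaN where no region contains it.

        Raises :class:`RegionOverlapError` if a point falls in two regions,
        since one cell must resolve to at most one scaling factor.
        """
        from shapely.geometry import Point

        prepared = [(r.region_id, prep(r.geometry), r.geometry) for r in self.regions]
        out: list[object] = []
        for x, y in np.asarray(xy, dtype=float):
            p = Point(x, y)
            interior = [rid for rid, g, _ in prepared if g.contains(p)]
            if len(interior) > 1:
                raise RegionOverlapError(
                    f"point ({x:g}, {y:g}) lies in regions {interior}; regions must be disjoint"
                )
            if interior:
                out.append(interior[0])
                continue
            # Boundary points: deterministic tie-break by region id.
            touching = sorted(rid for rid, _, geom in prepared if geom.covers(p))
            if not touching and not allow_unassigned:
                raise ValueError(f"point ({x:g}, {y:g}) lies in no region")
            out.append(touching[0] if touching else None)
        return pd.Series(out, dtype=object)

    def assign_cells(self, grid, allow_unassigned: bool = True) -> pd.Series:
        """Region id per grid cell (by centroid), indexed by cell_id."""
        ids = self.assign_points(grid.centroids(), allow_unassigned=allow_unassigned)
        ids.index = pd.Index(grid.cell_ids, name="cell_id")
        return ids

    # --- GeoJSON --------------------------------------------------------------

    def to_geojson(self) -> dict:
        return {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "geometry": mapping(r.geometry),
                    "properties": {
                        "region_id": r.region_id,
                        "kind": r.kind,
                        "population": r.population,
                    },
                }
                for r in self.regions
            ],
        }

    def write_geojson(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_geojson(), fh)

    @classmethod
    def from_geojson(cls, obj: dict) -> "RegionSet":
        regions = [
            Region(
                region_id=str(f["properties"]["region_id"]),
                kind=f["properties"].get("kind", "state"),
                geometry=shape(f["geometry"]),
                population=float(f["properties"].get("population", 0.0)),
            )
            for f in obj["features"]
        ]
        return cls(regions)

    @classmethod
    def read_geojson(cls, path) -> "RegionSet":
        with open(path) as fh:
            return cls.from_geojson(json.load(fh))
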