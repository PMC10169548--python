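"""Population-driven variable-resolution grid.

The grid emulates the "static" quadtree-style grid used by reduced-form
air-quality models such as InMAP: the domain is tiled with coarse square
cells (288 km by default) and any cell holding more than a population
threshold, or exceeding a population-density threshold, is recursively
subdivided down a fixed ladder of cell sizes until the 1 km floor.
Cell size then doubles as an urbanicity proxy: 1/2/4 km cells are urban,
12 km semi-urban, 24 km and larger rural.

Coordinates are planar, in kilometres, on an equal-area projection fixed
upstream; cell bounds are half-open ``[x0, x1) x [y0, y1)`` so every point
of the domain belongs to exactly one cell.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GridSpec",
    "GridCell",
    "VariableGrid",
    "RegularRaster",
    "build_variable_grid",
    "classify_cells",
    "classify_size_km",
    "regrid_raster_to_grid",
    "summarize_population_by_stratum",
]

#: Default ladder of allowed cell edge lengths, km, coarse to fine.
DEFAULT_SIZE_LADDER_KM: tuple[float, ...] = (288, 96, 48, 24, 12, 4, 2, 1)

#: Cell sizes classified urban / semi-urban; everything coarser is rural.
URBAN_SIZES_KM = frozenset({1.0, 2.0, 4.0})
SEMI_URBAN_SIZES_KM = frozenset({12.0})

STRATA = ("urban", "semi_urban", "rural")


class GridConfigError(ValueError):
    """Raised when a grid specification is internally inconsistent."""


@dataclass(frozen=True)
class GridSpec:
    """Parameters controlling variable-grid construction.

    Parameters
    ----------
    size_ladder_km:
        Strictly decreasing sequence of allowed cell edge lengths (km).
        Each adjacent ratio must be an integer; the default ladder
        288/96/48/24/12/4/2/1 has ratios 3,2,2,2,3,2,2.
    pop_threshold:
        A cell with more people than this is subdivided (default 40,000).
    density_threshold:
        A cell denser than this (people per km^2) is subdivided.
        Default 500 people/km^2, a conventional urban-density cutoff.
    domain_origin:
        (x, y) of the domain's lower-left corner, km.
    domain_extent:
        (width, height) of the domain, km; each must be a multiple of the
        coarsest ladder size.
    """

    size_ladder_km: tuple[float, ...] = DEFAULT_SIZE_LADDER_KM
    pop_threshold: float = 40_000.0
    density_threshold: float = 500.0
    domain_origin: tuple[float, float] = (0.0, 0.0)
    domain_extent: tuple[float, float] = (576.0, 576.0)

    def __post_init__(self) -> None:
        ladder = tuple(float(s) for s in self.size_ladder_km)
        object.__setattr__(self, "size_ladder_km", ladder)
        if len(ladder) < 1:
            raise GridConfigError("size ladder must be non-empty")
        if any(b >= a for a, b in zip(ladder, ladder[1:])):
            raise GridConfigError("size ladder must be strictly decreasing")
        for a, b in zip(ladder, ladder[1:]):
            ratio = a / b
            if abs(ratio - round(ratio)) > 1e-9:
                raise GridConfigError(
                    f"adjacent ladder sizes {a} and {b} have non-integer ratio"
                )
        if self.pop_threshold <= 0 or self.density_threshold <= 0:
            raise GridConfigError("thresholds must be positive")
        w, h = self.domain_extent
        coarsest = ladder[0]
        for extent in (w, h):
            if extent <= 0 or abs(extent / coarsest - round(extent / coarsest)) > 1e-9:
                raise GridConfigError(
                    "domain extent must be a positive multiple of the coarsest cell size"
                )

    @property
    def split_ratios(self) -> tuple[int, ...]:
        """Integer subdivision factor for each ladder step."""
        return tuple(
            int(round(a / b))
            for a, b in zip(self.size_ladder_km, self.size_ladder_km[1:])
        )


@dataclass(frozen=True)
class GridCell:
    """One square cell of the variable grid (half-open bounds, km)."""

    cell_id: str
    bounds: tuple[float, float, float, float]  # x0, y0, x1, y1
    size_km: float
    population: float = 0.0
    location_class: str | None = None

    @property
    def centroid(self) -> tuple[float, float]:
        x0, y0, x1, y1 = self.bounds
        return (0.5 * (x0 + x1), 0.5 * (y0 + y1))

    @property
    def area_km2(self) -> float:
        return self.size_km * self.size_km

    def contains(self, x: float, y: float) -> bool:
        x0, y0, x1, y1 = self.bounds
        return (x0 <= x < x1) and (y0 <= y < y1)


@dataclass
class VariableGrid:
    """A non-overlapping tiling of the domain by ladder-sized cells."""

    cells: list[GridCell]
    spec: GridSpec

    def __len__(self) -> int:
        return len(self.cells)

    def __iter__(self):
        return iter(self.cells)

    @property
    def cell_ids(self) -> list[str]:
        return [c.cell_id for c in self.cells]

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: one row per cell."""
        rows = []
        for c in self.cells:
            x0, y0, x1, y1 = c.bounds
            rows.append(
                dict(
                    cell_id=c.cell_id,
                    x0=x0,
                    y0=y0,
                    x1=x1,
                    y1=y1,
                    size_km=c.size_km,
                    population=c.population,
                    location_class=c.location_class,
                )
            )
        return pd.DataFrame(rows)

    def centroids(self) -> np.ndarray:
        """(n, 2) array of cell centroids, in cell order."""
        return np.array([c.centroid for c in self.cells], dtype=float)

    def total_population(self) -> float:
        return float(sum(c.population for c in self.cells))

    def total_area_km2(self) -> float:
        return float(sum(c.area_km2 for c in self.cells))

    def cell_index_of_points(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Index of the cell containing each point; -1 if outside the domain.

        Uses the half-open convention, vectorised over points.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        out = np.full(x.shape, -1, dtype=int)
        x0 = np.array([c.bounds[0] for c in self.cells])
        y0 = np.array([c.bounds[1] for c in self.cells])
        x1 = np.array([c.bounds[2] for c in self.cells])
        y1 = np.array([c.bounds[3] for c in self.cells])
        for i in range(x.size):
            px, py = x.flat[i], y.flat[i]
            hit = np.where((x0 <= px) & (px < x1) & (y0 <= py) & (py < y1))[0]
            if hit.size:
                out.flat[i] = hit[0]
        return out

    # --- GeoJSON round trip -------------------------------------------------

    def to_geojson(self) -> dict:
        features = []
        for c in self.cells:
            x0, y0, x1, y1 = c.bounds
            features.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [
                            [[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]]
                        ],
                    },
                    "properties": {
                        "cell_id": c.cell_id,
                        "size_km": c.size_km,
                        "population": c.population,
                        "location_class": c.location_class,
                    },
                }
            )
        return {
            "type": "FeatureCollection",
            "features": features,
            "grid_spec": {
                "size_ladder_km": list(self.spec.size_ladder_km),
                "pop_threshold": self.spec.pop_threshold,
                "density_threshold": self.spec.density_threshold,
                "domain_origin": list(self.spec.domain_origin),
                "domain_extent": list(self.spec.domain_extent),
            },
        }

    def write_geojson(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_geojson(), fh)

    @classmethod
    def from_geojson(cls, obj: dict) -> "VariableGrid":
        specd = obj.get("grid_spec", {})
        spec = GridSpec(
            size_ladder_km=tuple(specd.get("size_ladder_km", DEFAULT_SIZE_LADDER_KM)),
            pop_threshold=specd.get("pop_threshold", 40_000.0),
            density_threshold=specd.get("density_threshold", 500.0),
            domain_origin=tuple(specd.get("domain_origin", (0.0, 0.0))),
            domain_extent=tuple(specd.get("domain_extent", (576.0, 576.0))),
        )
        cells = []
        for feat in obj["features"]:
            ring = feat["geometry"]["coordinates"][0]
            xs = [p[0] for p in ring]
            ys = [p[1] for p in ring]
            props = feat["properties"]
            cells.append(
                GridCell(
                    cell_id=str(props["cell_id"]),
                    bounds=(min(xs), min(ys), max(xs), max(ys)),
                    size_km=float(props["size_km"]),
                    population=float(props.get("population", 0.0)),
                    location_class=props.get("location_class"),
                )
            )
        return cls(cells=cells, spec=spec)

    @classmethod
    def read_geojson(cls, path) -> "VariableGrid":
        with open(path) as fh:
            return cls.from_geojson(json.load(fh))


@dataclass
class RegularRaster:
    """Per-species (or scalar) values on a regular square grid.

    ``values`` is indexed ``[row, col]`` with row 0 at the *southern* edge;
    the centre of pixel ``(i, j)`` is at
    ``(origin_x + (j + 0.5) * cell_km, origin_y + (i + 0.5) * cell_km)``.
    The default 1 km pixel emulates a 0.01-degree satellite product on the
    planar projection.
    """

    values: np.ndarray
    cell_km: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = np.nan

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D [row, col]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_mask(self) -> np.ndarray:
        if np.isnan(self.nodata):
            return ~np.isnan(self.values)
        return self.values != self.nodata

    def center_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """1-D arrays of pixel-centre x (per column) and y (per row)."""
        ny, nx = self.values.shape
        ox, oy = self.origin
        xs = ox + (np.arange(nx) + 0.5) * self.cell_km
        ys = oy + (np.arange(ny) + 0.5) * self.cell_km
        return xs, ys

    def to_xarray(self, name: str = "value"):
        import xarray as xr

        xs, ys = self.center_coords()
        return xr.DataArray(
            self.values,
            coords={"y": ys, "x": xs},
            dims=("y", "x"),
            name=name,
            attrs={"cell_km": self.cell_km, "origin": list(self.origin)},
        )

    def write_netcdf(self, path, name: str = "value") -> None:
        self.to_xarray(name).to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_xarray(cls, da) -> "RegularRaster":
        cell_km = float(da.attrs.get("cell_km", float(da.x[1] - da.x[0])))
        ox = float(da.x[0]) - 0.5 * cell_km
        oy = float(da.y[0]) - 0.5 * cell_km
        return cls(values=np.asarray(da.values, dtype=float), cell_km=cell_km, origin=(ox, oy))

    @classmethod
    def read_netcdf(cls, path, name: str = "value") -> "RegularRaster":
        import xarray as xr

        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_xarray(ds[name].load())


# ---------------------------------------------------------------------------
# Construction


def _integral_image(arr: np.ndarray) -> np.ndarray:
    """Summed-area table with a zero top/left border."""
    out = np.zeros((arr.shape[0] + 1, arr.shape[1] + 1), dtype=float)
    np.cumsum(np.cumsum(arr, axis=0), axis=1, out=out[1:, 1:])
    return out


def _box_sum(sat: np.ndarray, r0: int, r1: int, c0: int, c1: int) -> float:
    """Sum of arr[r0:r1, c0:c1] from its summed-area table."""
    return sat[r1, c1] - sat[r0, c1] - sat[r1, c0] + sat[r0, c0]


def _pixel_slice(raster: RegularRaster, bounds, tol: float = 1e-9):
    """Half-open pixel-index window whose centres fall inside ``bounds``."""
    x0, y0, x1, y1 = bounds
    ox, oy = raster.origin
    d = raster.cell_km
    ny, nx = raster.shape
    # centre of col j is ox + (j + .5) d; inside means x0 <= centre < x1
    c0 = int(np.ceil((x0 - ox) / d - 0.5 - tol))
    c1 = int(np.ceil((x1 - ox) / d - 0.5 - tol))
    r0 = int(np.ceil((y0 - oy) / d - 0.5 - tol))
    r1 = int(np.ceil((y1 - oy) / d - 0.5 - tol))
    return max(r0, 0), min(r1, ny), max(c0, 0), min(c1, nx)


def build_variable_grid(population_surface: RegularRaster, spec: GridSpec) -> VariableGrid:
    """Recursively tile the domain, splitting populous or dense cells.

    Starting from the coarsest tiling, any cell whose population exceeds
    ``spec.pop_threshold`` *or* whose density exceeds
    ``spec.density_threshold`` is subdivided into ``r x r`` children at the
    next ladder size, recursing until the finest size.  Child population is
    the sum of population-surface mass within the child's bounds, so total
    population is conserved by construction.
    """
    if np.any(population_surface.values[population_surface.valid_mask()] < 0):
        raise ValueError("population surface contains negative values")

    pop = np.where(population_surface.valid_mask(), population_surface.values, 0.0)
    sat = _integral_image(pop)

    ladder = spec.size_ladder_km
    ratios = spec.split_ratios
    ox, oy = spec.domain_origin
    width, height = spec.domain_extent
    coarsest = ladder[0]
    nxc = int(round(width / coarsest))
    nyc = int(round(height / coarsest))

    def cell_pop(bounds) -> float:
        r0, r1, c0, c1 = _pixel_slice(population_surface, bounds)
        if r1 <= r0 or c1 <= c0:
            return 0.0
        return _box_sum(sat, r0, r1, c0, c1)

    cells: list[GridCell] = []

    def recurse(x0: float, y0: float, level: int, tag: str) -> None:
        size = ladder[level]
        bounds = (x0, y0, x0 + size, y0 + size)
        p = cell_pop(bounds)
        density = p / (size * size)
        must_split = level + 1 < len(ladder) and (
            p > spec.pop_threshold or density > spec.density_threshold
        )
        if not must_split:
            cells.append(
                GridCell(cell_id=tag, bounds=bounds, size_km=size, population=p)
            )
            return
        r = ratios[level]
        child = ladder[level + 1]
        for iy in range(r):
            for ix in range(r):
                recurse(x0 + ix * child, y0 + iy * child, level + 1, f"{tag}.{iy}{ix}")

    for iy in range(nyc):
        for ix in range(nxc):
            recurse(ox + ix * coarsest, oy + iy * coarsest, 0, f"c{iy:02d}{ix:02d}")

    return VariableGrid(cells=cells, spec=spec)


def classify_size_km(size_km: float, ladder: Sequence[float] = DEFAULT_SIZE_LADDER_KM) -> str:
    """Urbanicity stratum implied by a cell's edge length."""
    if size_km not in set(float(s) for s in ladder):
        raise ValueError(f"cell size {size_km} km is not on the ladder {ladder}")
    if size_km in URBAN_SIZES_KM:
        return "urban"
    if size_km in SEMI_URBAN_SIZES_KM:
        return "semi_urban"
    return "rural"


def classify_cells(grid: VariableGrid) -> VariableGrid:
    """Assign urban / semi-urban / rural purely from cell size.

    1, 2 and 4 km cells are urban; 12 km semi-urban; 24 km and larger rural.
    Idempotent.
    """
    ladder = grid.spec.size_ladder_km
    cells = [
        replace(c, location_class=classify_size_km(c.size_km, ladder)) for c in grid.cells
    ]
    return VariableGrid(cells=cells, spec=grid.spec)


def regrid_raster_to_grid(
    raster: RegularRaster, grid: VariableGrid, species: str = "value"
) -> pd.DataFrame:
    """Zonal mean of a regular raster over each variable-grid cell.

    A raster pixel belongs to the cell containing its centre point
    (half-open bounds); the cell value is the unweighted mean of its valid
    pixels.  Cells with no valid pixel get NaN and are flagged in the
    ``missing`` column so downstream pairing can exclude them.

    Returns a DataFrame with columns cell_id, species, value, n_pixels,
    missing.
    """
    vals = np.where(raster.valid_mask(), raster.values, 0.0)
    cnts = raster.valid_mask().astype(float)
    sat_v = _integral_image(vals)
    sat_n = _integral_image(cnts)

    rows = []
    for c in grid.cells:
        r0, r1, c0, c1 = _pixel_slice(raster, c.bounds)
        if r1 <= r0 or c1 <= c0:
            n = 0.0
            mean = np.nan
        else:
            n = _box_sum(sat_n, r0, r1, c0, c1)
            mean = _box_sum(sat_v, r0, r1, c0, c1) / n if n > 0 else np.nan
        rows.append(
            dict(
                cell_id=c.cell_id,
                species=species,
                value=mean,
                n_pixels=int(round(n)),
                missing=n == 0,
            )
        )
    return pd.DataFrame(rows)


def summarize_population_by_stratum(grid: VariableGrid) -> dict[str, float]:
    """Share of total population living in urban / semi-urban / rural cells."""
    totals = {s: 0.0 for s in STRATA}
    for c in grid.cells:
        if c.location_class is None:
            raise ValueError("grid must be classified first (classify_cells)")
        totals[c.location_class] += c.population
    grand = sum(totals.values())
    if grand <= 0:
        raise ValueError("total population is zero; shares undefined")
    return {s: totals[s] / grand for s in STRATA}
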