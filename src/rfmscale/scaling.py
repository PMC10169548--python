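"""Observation-driven scaling factors for reduced-form model output.

The bias-correction statistic is the ratio of means over a spatial scope:

    SF(scope, species) = mean(O_i) / mean(P_i),  i = 1..n pairs in scope

where ``P_i`` is the model's annual-mean concentration in a grid cell and
``O_i`` an observation paired with that cell (a ground monitor's annual
mean, or the satellite product averaged onto the cell).  The SF is applied
multiplicatively to every cell in its scope, per species, and — because
the underlying model is linear — identically to every emission sector's
field, so sector totals keep summing to the scaled total.

Five scopes are supported:

- ``nationwide``: one SF per species over all pairs;
- ``state``: one SF per state polygon (with a donor-state fallback for
  states lacking a monitor, e.g. a neighbour's SF);
- ``knn_monitors``: one SF per grid cell from its k nearest monitors
  (monitor observations only, default k=5);
- ``grid_cell``: one SF per cell from the satellite value in that cell;
- ``city_boundary``: one SF per urbanized-area polygon with population
  above a cutoff (default 350,000), satellite observations; cells outside
  every city stay unscaled and are flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fields import SpeciesField, TOTAL_SECTOR
from .regions import RegionSet

__all__ = [
    "ScalingScheme",
    "ScalingFactorSet",
    "compute_scaling_factors",
    "compute_knn_scaling_factors",
    "apply_scaling_factors",
    "nearest_donor_fallback",
    "UndefinedScalingFactor",
    "MissingObservations",
]

log = logging.getLogger(__name__)

KINDS = ("nationwide", "state", "knn_monitors", "grid_cell", "city_boundary")
SOURCES = ("monitor", "satellite")

NATION_SCOPE = "nation"


class UndefinedScalingFactor(ValueError):
    """Sum of predictions in a scope is zero; the ratio is undefined."""


class MissingObservations(ValueError):
    """A scope has no observation pairs and no fallback donor."""


@dataclass(frozen=True)
class ScalingScheme:
    """Which scope partition and observation source to scale with."""

    kind: str
    observation_source: str
    k: int = 5
    city_pop_min: float = 350_000.0
    #: scope_id -> donor scope_id used when a region has no observations.
    fallback_map: dict = field(default_factory=dict)
    #: Relax the paper's source pairing (knn=monitor, grid_cell/city=satellite).
    allow_any_source: bool = False

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown scheme kind {self.kind!r}; expected one of {KINDS}")
        if self.observation_source not in SOURCES:
            raise ValueError(f"unknown observation source {self.observation_source!r}")
        if not self.allow_any_source:
            if self.kind == "knn_monitors" and self.observation_source != "monitor":
                raise ValueError("knn_monitors scaling requires monitor observations")
            if self.kind in ("grid_cell", "city_boundary") and self.observation_source != "satellite":
                raise ValueError(f"{self.kind} scaling requires satellite observations")
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class ScalingFactorSet:
    """SFs per (scope, species) with pair counts and provenance.

    ``table`` columns: scope_id, species, sf, n_pairs, scheme, source,
    provenance (free text, e.g. ``"fallback from <donor>"``).
    """

    table: pd.DataFrame
    scheme: ScalingScheme

    def __post_init__(self) -> None:
        t = self.table
        if len(t):
            if not np.all(np.isfinite(t["sf"])) or np.any(t["sf"] <= 0):
                bad = t[~np.isfinite(t["sf"]) | (t["sf"] <= 0)]
                raise ValueError(f"non-positive or non-finite SF entries:\n{bad}")
            if np.any(t["n_pairs"] < 1):
                raise ValueError("every SF entry needs n_pairs >= 1")

    def lookup(self, scope_id: str, species: str) -> float:
        t = self.table
        row = t[(t["scope_id"] == scope_id) & (t["species"] == species)]
        if len(row) != 1:
            raise KeyError(f"no unique SF for scope {scope_id!r}, species {species!r}")
        return float(row["sf"].iloc[0])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Pair assembly


def _pairs_from_monitors(model_total: SpeciesField, monitors: pd.DataFrame) -> pd.DataFrame:
    """One row per monitor: cell_id, species, P (cell prediction), O."""
    need = {"cell_id", "species", "annual_mean"}
    if not need.issubset(monitors.columns):
        raise ValueError("monitors must be co-located first (need cell_id column)")
    pred = model_total.total().data.rename(columns={"value": "P"})[["cell_id", "species", "P"]]
    pairs = monitors.merge(pred, on=["cell_id", "species"], how="inner")
    return pairs.rename(columns={"annual_mean": "O"})


def _pairs_from_satellite(model_total: SpeciesField, satellite: SpeciesField) -> pd.DataFrame:
    """One row per cell and species with both a prediction and a valid
    satellite value."""
    pred = model_total.total().data.rename(columns={"value": "P"})[["cell_id", "species", "P"]]
    obs = satellite.total().data.rename(columns={"value": "O"})[["cell_id", "species", "O"]]
    pairs = pred.merge(obs, on=["cell_id", "species"], how="inner")
    return pairs.dropna(subset=["O", "P"]).reset_index(drop=True)


def build_pairs(model_total: SpeciesField, observations, scheme: ScalingScheme) -> pd.DataFrame:
    if scheme.observation_source == "monitor":
        return _pairs_from_monitors(model_total, observations)
    return _pairs_from_satellite(model_total, observations)


# ---------------------------------------------------------------------------
# SF computation


def _ratio_of_means(pairs: pd.DataFrame, scope_id: str, species: str) -> tuple[float, int]:
    n = len(pairs)
    sum_p = float(pairs["P"].sum())
    sum_o = float(pairs["O"].sum())
    if sum_p == 0:
        raise UndefinedScalingFactor(
            f"sum of predictions is zero for scope {scope_id!r}, species {species!r}"
        )
    return sum_o / sum_p, n


def compute_scaling_factors(
    model: SpeciesField,
    observations,
    scheme: ScalingScheme,
    regions: RegionSet | None = None,
    grid=None,
    auto_fallback: bool = False,
) -> ScalingFactorSet:
    """Eq.-style ratio-of-means SFs for every scope of the scheme.

    Parameters
    ----------
    model:
        Model concentrations (any sector breakdown; totals are formed
        internally).
    observations:
        Co-located monitor annual means (DataFrame) when the scheme uses
        monitors, or a satellite :class:`SpeciesField` on the grid when it
        uses the satellite product.
    scheme:
        Scope partition, observation source and fallback map.
    regions:
        Required for ``state`` and ``city_boundary``.
    grid:
        Required for region schemes (cell-centroid membership) and for
        ``knn_monitors`` (delegated to
        :func:`compute_knn_scaling_factors`).
    auto_fallback:
        For region schemes: when a region has no observations of a
        species and no explicit donor in ``scheme.fallback_map``, borrow
        the SF of the nearest region (centroid distance) that does — the
        neighbouring-state rule used when a state lacks a monitor for one
        species.
    """
    if scheme.kind == "knn_monitors":
        if grid is None:
            raise ValueError("knn_monitors scaling needs the grid")
        return compute_knn_scaling_factors(model, observations, grid, k=scheme.k, scheme=scheme)

    pairs = build_pairs(model.total(), observations, scheme)
    rows: list[dict] = []

    if scheme.kind == "nationwide":
        for sp, group in pairs.groupby("species", sort=True):
            sf, n = _ratio_of_means(group, NATION_SCOPE, sp)
            rows.append(dict(scope_id=NATION_SCOPE, species=sp, sf=sf, n_pairs=n, provenance=""))

    elif scheme.kind == "grid_cell":
        for (cid, sp), group in pairs.groupby(["cell_id", "species"], sort=True):
            sf, n = _ratio_of_means(group, cid, sp)
            rows.append(dict(scope_id=cid, species=sp, sf=sf, n_pairs=n, provenance=""))

    elif scheme.kind in ("state", "city_boundary"):
        if regions is None or grid is None:
            raise ValueError(f"{scheme.kind} scaling needs regions and the grid")
        use_regions = regions
        if scheme.kind == "city_boundary":
            use_regions = RegionSet(
                [r for r in regions if r.population >= scheme.city_pop_min]
            )
        membership = use_regions.assign_cells(grid)  # cell_id -> region or None
        pairs = pairs.assign(scope_id=pairs["cell_id"].map(membership))
        in_scope = pairs.dropna(subset=["scope_id"])
        species_list = sorted(pairs["species"].unique())
        computed: dict[tuple[str, str], tuple[float, int]] = {}
        for (scope, sp), group in in_scope.groupby(["scope_id", "species"], sort=True):
            computed[(scope, sp)] = _ratio_of_means(group, scope, sp)
        centroids = {
            r.region_id: (r.geometry.centroid.x, r.geometry.centroid.y)
            for r in use_regions
        }
        for region in use_regions:
            for sp in species_list:
                key = (region.region_id, sp)
                if key in computed:
                    sf, n = computed[key]
                    prov = ""
                else:
                    donor = scheme.fallback_map.get(region.region_id)
                    if (donor is None or (donor, sp) not in computed) and auto_fallback:
                        cx, cy = centroids[region.region_id]
                        candidates = sorted(
                            scope
                            for (scope, s) in computed
                            if s == sp and scope != region.region_id
                        )
                        donor = min(
                            candidates,
                            default=None,
                            key=lambda d: (
                                (centroids[d][0] - cx) ** 2 + (centroids[d][1] - cy) ** 2,
                                d,
                            ),
                        )
                    if donor is None or (donor, sp) not in computed:
                        raise MissingObservations(
                            f"region {region.region_id!r} has no {sp} observations "
                            "and no fallback donor with data"
                        )
                    sf, n = computed[(donor, sp)]
                    prov = f"fallback from {donor}"
                    log.info(
                        "region %s species %s: no observations, using donor %s",
                        region.region_id, sp, donor,
                    )
                rows.append(dict(scope_id=region.region_id, species=sp, sf=sf, n_pairs=n, provenance=prov))
    else:  # pragma: no cover - guarded in ScalingScheme
        raise ValueError(scheme.kind)

    table = pd.DataFrame(rows).assign(scheme=scheme.kind, source=scheme.observation_source)
    return ScalingFactorSet(table=table, scheme=scheme)


def compute_knn_scaling_factors(
    model: SpeciesField,
    monitors: pd.DataFrame,
    grid,
    k: int = 5,
    scheme: ScalingScheme | None = None,
) -> ScalingFactorSet:
    """One SF per grid cell from the k monitors nearest its centroid.

    For each cell and species the k nearest monitors (planar Euclidean
    distance to the cell centroid) form the pair set; the SF is the ratio
    of mean observation to mean co-located prediction over those k pairs.
    Ties at the k-th distance break by ascending monitor id.
    """
    if scheme is None:
        scheme = ScalingScheme(kind="knn_monitors", observation_source="monitor", k=k)
    pairs_all = _pairs_from_monitors(model.total(), monitors)
    cent = grid.centroids()
    rows: list[dict] = []
    for sp, group in pairs_all.groupby("species", sort=True):
        group = group.sort_values("monitor_id", kind="stable").reset_index(drop=True)
        m = len(group)
        if m < k:
            raise ValueError(f"species {sp}: only {m} monitors available, k={k} requested")
        mon_xy = group[["x_km", "y_km"]].to_numpy(dtype=float)
        obs = group["O"].to_numpy(dtype=float)
        prd = group["P"].to_numpy(dtype=float)
        # distances: (n_cells, n_monitors); monitors already id-ordered so a
        # stable argsort on distance realises the distance-then-id tie-break
        d2 = (
            (cent[:, 0:1] - mon_xy[None, :, 0]) ** 2
            + (cent[:, 1:2] - mon_xy[None, :, 1]) ** 2
        )
        nearest = np.argsort(d2, axis=1, kind="stable")[:, :k]
        sum_o = obs[nearest].sum(axis=1)
        sum_p = prd[nearest].sum(axis=1)
        if np.any(sum_p == 0):
            bad = np.array(grid.cell_ids)[sum_p == 0]
            raise UndefinedScalingFactor(
                f"zero summed prediction among nearest monitors for cells {bad[:5]} species {sp}"
            )
        for cid, sf in zip(grid.cell_ids, sum_o / sum_p):
            rows.append(dict(scope_id=cid, species=sp, sf=float(sf), n_pairs=k, provenance=""))
    table = pd.DataFrame(rows).assign(scheme="knn_monitors", source="monitor")
    return ScalingFactorSet(table=table, scheme=scheme)


# ---------------------------------------------------------------------------
# Application


@dataclass
class ScaledField:
    """Scaled concentrations plus which cells actually received an SF."""

    field: SpeciesField
    cell_scaled: pd.Series  # bool per cell_id

    @property
    def unscaled_cell_ids(self) -> list[str]:
        return list(self.cell_scaled.index[~self.cell_scaled])


def apply_scaling_factors(
    model: SpeciesField,
    sfs: ScalingFactorSet,
    grid=None,
    regions: RegionSet | None = None,
) -> ScaledField:
    """Multiply each cell's concentrations by its scope's SF, per species.

    Every sector of a cell-species is scaled by the same factor, so the
    scaled sector fields still sum to the scaled total.  Under the
    city-boundary scheme, cells outside every (sufficiently large) city
    keep their unscaled values and are flagged via ``cell_scaled``.
    """
    scheme = sfs.scheme
    df = model.data.copy()
    cell_ids = pd.Index(sorted(df["cell_id"].unique()))

    if scheme.kind == "nationwide":
        scope_of_cell = pd.Series(NATION_SCOPE, index=cell_ids)
    elif scheme.kind in ("grid_cell", "knn_monitors"):
        scope_of_cell = pd.Series(cell_ids, index=cell_ids)
    elif scheme.kind in ("state", "city_boundary"):
        if regions is None or grid is None:
            raise ValueError(f"{scheme.kind} application needs regions and the grid")
        use_regions = regions
        if scheme.kind == "city_boundary":
            use_regions = RegionSet([r for r in regions if r.population >= scheme.city_pop_min])
        scope_of_cell = use_regions.assign_cells(grid).reindex(cell_ids)
    else:  # pragma: no cover
        raise ValueError(scheme.kind)

    sf_lookup = sfs.table.set_index(["scope_id", "species"])["sf"]
    df["_scope"] = df["cell_id"].map(scope_of_cell)
    keys = pd.MultiIndex.from_frame(df[["_scope", "species"]])
    factors = pd.Series(sf_lookup.reindex(keys).to_numpy(), index=df.index)

    in_scope = df["_scope"].notna()
    missing_sf = in_scope & factors.isna()
    if scheme.kind != "city_boundary" and missing_sf.any():
        bad = df.loc[missing_sf, ["cell_id", "species"]].drop_duplicates()
        raise KeyError(f"no SF for in-scope cells, e.g.\n{bad.head()}")

    factors = factors.fillna(1.0)
    out = df.drop(columns=["_scope"])
    out["value"] = out["value"] * factors.to_numpy()

    cell_scaled = (
        pd.Series(in_scope.to_numpy() & ~missing_sf.to_numpy(), index=df["cell_id"].to_numpy())
        .groupby(level=0)
        .any()
        .reindex(cell_ids, fill_value=False)
    )
    cell_scaled.index.name = "cell_id"
    return ScaledField(field=SpeciesField(out), cell_scaled=cell_scaled)


def nearest_donor_fallback(regions: RegionSet, scopes_with_data: set[str]) -> dict[str, str]:
    """Map each data-less region to the nearest region that has data.

    Distance is between region centroids — the synthetic analogue of using
    a neighbouring state's monitor when a state lacks one.
    """
    have = [r for r in regions if r.region_id in scopes_with_data]
    out: dict[str, str] = {}
    for r in regions:
        if r.region_id in scopes_with_data or not have:
            continue
        c = r.geometry.centroid
        donor = min(
            have,
            key=lambda d: ((d.geometry.centroid.x - c.x) ** 2 + (d.geometry.centroid.y - c.y) ** 2, d.region_id),
        )
        out[r.region_id] = donor.region_id
    return out
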