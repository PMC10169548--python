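"""Source-contribution analysis under scaling.

Because the underlying air-quality model is linear, running each emission
sector's file alone decomposes the concentration field, and a per-cell,
per-species multiplicative scaling commutes with that decomposition.  The
percent contribution of each sector to a region's pollution is then

    contribution%(sector) = W(sector) / sum_s W(s) * 100

where W is the area- (or population-) weighted mean over the region's
cells of the sector's concentration summed over species.  Comparing
contributions from unscaled and scaled fields shows how bias correction
reallocates apparent source responsibility (e.g. toward sulfate-heavy
power-plant sectors when sulfate was underestimated).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fields import SpeciesField
from .regions import RegionSet

__all__ = [
    "sector_percent_contributions",
    "contribution_change",
    "total_field_change",
    "NATION_REGION",
]

NATION_REGION = "nation"


def _cell_weights(grid, weight: str) -> pd.Series:
    if weight == "area":
        w = {c.cell_id: c.area_km2 for c in grid.cells}
    elif weight == "population":
        w = {c.cell_id: c.population for c in grid.cells}
    else:
        raise ValueError("weight must be 'area' or 'population'")
    return pd.Series(w, name="weight")


def sector_percent_contributions(
    fields: SpeciesField,
    grid,
    regions: RegionSet | None = None,
    weight: str = "area",
    variant: str = "unscaled",
) -> pd.DataFrame:
    """Percent contribution of each sector per region.

    ``fields`` must carry a real sector breakdown.  Regions are evaluated
    by cell-centroid membership; the nationwide row (region_id 'nation')
    covers every cell.  Returns columns region_id, sector, variant, pct,
    weighted_total.
    """
    sectors = [s for s in fields.sectors if s != "total"]
    if not sectors:
        raise ValueError("fields carry no sector breakdown")
    weights = _cell_weights(grid, weight)

    # per-cell, per-sector concentration summed over species
    per_cell = (
        fields.data[fields.data["sector"] != "total"]
        .groupby(["cell_id", "sector"], sort=False)["value"]
        .sum()
        .reset_index()
    )
    per_cell["weight"] = per_cell["cell_id"].map(weights)

    memberships: dict[str, pd.Index] = {NATION_REGION: pd.Index(weights.index)}
    if regions is not None:
        assign = regions.assign_cells(grid)
        for rid in regions.ids:
            memberships[rid] = assign.index[assign == rid]

    rows = []
    for rid, cell_idx in memberships.items():
        sub = per_cell[per_cell["cell_id"].isin(set(cell_idx))]
        wsum = sub["weight"].sum()
        if wsum <= 0:
            raise ValueError(f"region {rid!r} has zero total weight")
        totals = (
            (sub["value"] * sub["weight"]).groupby(sub["sector"]).sum() / wsum
        ).reindex(sectors, fill_value=0.0)
        grand = totals.sum()
        if grand <= 0:
            raise ValueError(f"region {rid!r} has all-zero sector totals; contributions undefined")
        for sector, tot in totals.items():
            rows.append(
                dict(
                    region_id=rid,
                    sector=sector,
                    variant=variant,
                    weighted_total=float(tot),
                    pct=100.0 * float(tot) / float(grand),
                )
            )
    return pd.DataFrame(rows)


def contribution_change(unscaled: pd.DataFrame, scaled: pd.DataFrame) -> pd.DataFrame:
    """Percentage-point change in contribution, scaled minus unscaled.

    Changes sum to zero over sectors within each region, since both
    variants sum to 100%.
    """
    u = unscaled.set_index(["region_id", "sector"])["pct"]
    s = scaled.set_index(["region_id", "sector"])["pct"]
    if not u.index.equals(s.index):
        s = s.reindex(u.index)
        if s.isna().any():
            raise ValueError("scaled and unscaled tables cover different regions/sectors")
    out = pd.DataFrame(
        {
            "unscaled_pct": u,
            "scaled_pct": s,
            "change_pts": s - u,
        }
    ).reset_index()
    return out


def total_field_change(
    unscaled_total: SpeciesField,
    scaled_total: SpeciesField,
    grid,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-cell percent change in total concentration, plus domain summary.

    The per-cell change is 100*(scaled - unscaled)/unscaled (NaN where the
    unscaled value is zero).  The summary reports area-weighted mean total
    concentrations of both variants and their percent difference.
    """
    u = unscaled_total.total_over_species()
    s = scaled_total.total_over_species().reindex(u.index)
    pct = pd.Series(np.nan, index=u.index, name="pct_change")
    nz = u != 0
    pct[nz] = 100.0 * (s[nz] - u[nz]) / u[nz]
    per_cell = pd.DataFrame({"cell_id": u.index, "unscaled": u.values, "scaled": s.values, "pct_change": pct.values})

    area = _cell_weights(grid, "area").reindex(u.index)
    mean_u = float((u * area).sum() / area.sum())
    mean_s = float((s * area).sum() / area.sum())
    summary = dict(
        mean_unscaled_ugm3=mean_u,
        mean_scaled_ugm3=mean_s,
        pct_change=100.0 * (mean_s - mean_u) / mean_u if mean_u != 0 else np.nan,
    )
    return per_cell, summary
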