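"""Ground-monitor records: annual averaging and grid co-location.

Daily speciation records (one row per monitor, species and day) are
reduced to annual means, subject to a completeness minimum, then each
monitor is assigned the unique grid cell whose half-open bounds contain
its location.  Each retained monitor contributes one (prediction,
observation) pair downstream; several monitors in one cell all keep their
own pair and share the cell's prediction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = ["annualize_daily_records", "colocate_monitors_with_cells"]

log = logging.getLogger(__name__)

#: Default completeness rule: 75% of a 365-day schedule.
DEFAULT_MIN_DAYS = 274

DAILY_COLUMNS = ["monitor_id", "x_km", "y_km", "species", "date", "value_ugm3"]


def annualize_daily_records(records: pd.DataFrame, min_days: int = DEFAULT_MIN_DAYS) -> pd.DataFrame:
    """Annual mean per monitor and species from a daily table.

    Parameters
    ----------
    records:
        Daily table with columns monitor_id, x_km, y_km, species, date,
        value_ugm3.  Values must be non-negative; dates must fall within a
        single calendar year.
    min_days:
        Minimum count of valid daily values for the annual mean to be
        retained; monitor-species series below it are dropped with a
        logged reason.

    Returns
    -------
    DataFrame with one row per retained monitor-species: monitor_id, x_km,
    y_km, species, annual_mean, n_days.
    """
    missing = [c for c in DAILY_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"daily records lack columns {missing}")
    vals = records["value_ugm3"].to_numpy(dtype=float)
    if np.any(vals[~np.isnan(vals)] < 0):
        raise ValueError("negative daily concentration value")
    years = pd.to_datetime(records["date"]).dt.year
    if years.nunique() > 1:
        raise ValueError(f"daily records span multiple years: {sorted(years.unique())}")

    valid = records.dropna(subset=["value_ugm3"])
    grouped = valid.groupby(["monitor_id", "species"], sort=True)
    out = grouped.agg(
        x_km=("x_km", "first"),
        y_km=("y_km", "first"),
        annual_mean=("value_ugm3", "mean"),
        n_days=("value_ugm3", "size"),
    ).reset_index()

    short = out[out["n_days"] < min_days]
    for _, row in short.iterrows():
        log.warning(
            "dropping monitor %s species %s: %d valid days < %d required",
            row["monitor_id"], row["species"], row["n_days"], min_days,
        )
    return out[out["n_days"] >= min_days].reset_index(drop=True)


def colocate_monitors_with_cells(monitors: pd.DataFrame, grid) -> pd.DataFrame:
    """Attach the containing grid cell's id (and stratum) to each monitor.

    Monitors outside the domain are excluded with a warning.  Assignment
    uses the grid's half-open cell bounds, so a monitor sitting exactly on
    a shared edge belongs to the cell owning that edge.
    """
    idx = grid.cell_index_of_points(
        monitors["x_km"].to_numpy(dtype=float), monitors["y_km"].to_numpy(dtype=float)
    )
    out = monitors.copy()
    cell_ids = np.array(grid.cell_ids, dtype=object)
    inside = idx >= 0
    for _, row in out[~inside].iterrows():
        log.warning(
            "monitor %s at (%.1f, %.1f) km lies outside the grid domain; excluded",
            row["monitor_id"], row["x_km"], row["y_km"],
        )
    out = out[inside].reset_index(drop=True)
    out["cell_id"] = cell_ids[idx[inside]]
    classes = {c.cell_id: c.location_class for c in grid.cells}
    out["location_class"] = out["cell_id"].map(classes)
    return out
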