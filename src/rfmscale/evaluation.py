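"""Model-performance statistics, benchmark classification, Improvement Ratio.

Predictions are compared to observations with the five statistics most
used for PM2.5 model evaluation:

- NMB = 100 * sum(P - O) / sum(O)      (normalized mean bias, %)
- NME = 100 * sum|P - O| / sum(O)      (normalized mean error, %)
- MB  = sum(P - O) / n                 (mean bias, ug/m3)
- ME  = sum|P - O| / n                 (mean error, ug/m3)
- R2  = squared Pearson correlation

NMB ranges from -100% upward; NME is non-negative.  Statistics are
reported overall and per urbanicity stratum.  NMB/NME are classified
against the Emery et al. daily-PM2.5 benchmarks: NMB goal < +/-10%,
criteria < +/-30%; NME goal < 35%, criteria < 50% (strict inequalities,
so an NME of exactly 35% only meets the criteria benchmark).

The per-cell Improvement Ratio |scaled - observed| / |unscaled - observed|
quantifies whether scaling moved a cell toward the observations: a value
in [0, 1) means it did.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fields import SpeciesField

__all__ = [
    "compute_metrics",
    "classify_against_benchmarks",
    "improvement_ratio",
    "summarize_improvement",
    "pairs_from_monitors",
    "pairs_from_field",
    "OVERALL",
]

log = logging.getLogger(__name__)

OVERALL = "overall"

NMB_GOAL, NMB_CRITERIA = 10.0, 30.0
NME_GOAL, NME_CRITERIA = 35.0, 50.0


# ---------------------------------------------------------------------------
# Paired samples


def pairs_from_monitors(model_total: SpeciesField, monitors: pd.DataFrame) -> pd.DataFrame:
    """PairedSample rows (cell_id, species, P, O, stratum) from co-located
    monitor annual means; one pair per monitor."""
    pred = model_total.total().data.rename(columns={"value": "P"})[["cell_id", "species", "P"]]
    pairs = monitors.merge(pred, on=["cell_id", "species"], how="inner")
    pairs = pairs.rename(columns={"annual_mean": "O", "location_class": "stratum"})
    return pairs[["cell_id", "species", "P", "O", "stratum"]]


def pairs_from_field(
    model_total: SpeciesField,
    obs_field: SpeciesField,
    grid,
    cell_ids=None,
) -> pd.DataFrame:
    """PairedSample rows pairing two fields cell-by-cell (e.g. model vs the
    satellite product on the grid); optionally restricted to ``cell_ids``."""
    pred = model_total.total().data.rename(columns={"value": "P"})[["cell_id", "species", "P"]]
    obs = obs_field.total().data.rename(columns={"value": "O"})[["cell_id", "species", "O"]]
    pairs = pred.merge(obs, on=["cell_id", "species"], how="inner").dropna(subset=["P", "O"])
    classes = {c.cell_id: c.location_class for c in grid.cells}
    pairs["stratum"] = pairs["cell_id"].map(classes)
    if cell_ids is not None:
        pairs = pairs[pairs["cell_id"].isin(set(cell_ids))]
    return pairs.reset_index(drop=True)[["cell_id", "species", "P", "O", "stratum"]]


# ---------------------------------------------------------------------------
# Metrics


def _metrics_one(p: np.ndarray, o: np.ndarray) -> dict[str, float]:
    n = p.size
    diff = p - o
    sum_o = o.sum()
    mb = diff.sum() / n
    me = np.abs(diff).sum() / n
    if sum_o > 0:
        nmb = 100.0 * diff.sum() / sum_o
        nme = 100.0 * np.abs(diff).sum() / sum_o
    else:
        nmb = np.nan
        nme = np.nan
    if n >= 2 and np.std(p) > 0 and np.std(o) > 0:
        r = np.corrcoef(p, o)[0, 1]
        r2 = r * r
    else:
        r2 = np.nan  # undefined, not zero
    return dict(n=n, NMB=nmb, NME=nme, MB=mb, ME=me, R2=r2)


def compute_metrics(pairs: pd.DataFrame, strata: bool = True) -> pd.DataFrame:
    """MetricReport: one row per species x stratum (plus 'overall').

    ``pairs`` needs columns species, P, O and (if ``strata``) stratum.
    Observations must be non-negative and finite.
    """
    if not len(pairs):
        raise ValueError("no pairs to evaluate")
    p_all = pairs["P"].to_numpy(dtype=float)
    o_all = pairs["O"].to_numpy(dtype=float)
    if not (np.all(np.isfinite(p_all)) and np.all(np.isfinite(o_all))):
        raise ValueError("non-finite values in paired sample")
    if np.any(o_all < 0):
        raise ValueError("negative observations in paired sample")

    rows = []
    for sp, g in pairs.groupby("species", sort=True):
        rows.append(
            dict(species=sp, stratum=OVERALL)
            | _metrics_one(g["P"].to_numpy(float), g["O"].to_numpy(float))
        )
        if strata and "stratum" in pairs.columns:
            for st, gg in g.groupby("stratum", sort=True):
                rows.append(
                    dict(species=sp, stratum=st)
                    | _metrics_one(gg["P"].to_numpy(float), gg["O"].to_numpy(float))
                )
    return pd.DataFrame(rows)


def _status(value: float, goal: float, criteria: float) -> str:
    if np.isnan(value):
        return "undefined"
    if abs(value) < goal:
        return "meets_goal"
    if abs(value) < criteria:
        return "meets_criteria"
    return "fails"


def classify_against_benchmarks(report: pd.DataFrame) -> pd.DataFrame:
    """Attach nmb_status / nme_status columns using the Emery benchmarks."""
    out = report.copy()
    out["nmb_status"] = [_status(v, NMB_GOAL, NMB_CRITERIA) for v in out["NMB"]]
    out["nme_status"] = [_status(v, NME_GOAL, NME_CRITERIA) for v in out["NME"]]
    return out


# ---------------------------------------------------------------------------
# Improvement Ratio


def improvement_ratio(
    unscaled: pd.Series | np.ndarray,
    scaled: pd.Series | np.ndarray,
    observed: pd.Series | np.ndarray,
) -> np.ndarray:
    """Per-cell ratio |scaled - observed| / |unscaled - observed|.

    Where the unscaled prediction already equals the observation the ratio
    is undefined; such cells get 0 if the scaled value also matches and
    +inf otherwise, and are excluded from the percent-improved summary.
    """
    u = np.asarray(unscaled, dtype=float)
    s = np.asarray(scaled, dtype=float)
    o = np.asarray(observed, dtype=float)
    num = np.abs(s - o)
    den = np.abs(u - o)
    out = np.full(u.shape, np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    out[~ok] = np.where(num[~ok] == 0, 0.0, np.inf)
    return out


def summarize_improvement(ratios: np.ndarray, undefined_mask=None) -> dict[str, float]:
    """Percent of defined cells with ratio < 1, plus bookkeeping counts.

    ``undefined_mask`` marks cells whose denominator was zero (the caller
    knows; the 0-sentinel is indistinguishable from a genuine 0 here);
    they and the +inf sentinels are excluded from the percentage.
    """
    r = np.asarray(ratios, dtype=float)
    excluded = np.isinf(r)
    if undefined_mask is not None:
        excluded = excluded | np.asarray(undefined_mask, dtype=bool)
    usable = r[~excluded & np.isfinite(r)]
    n_excluded = int(excluded.sum())
    if n_excluded:
        log.info("improvement summary: %d cells with undefined ratio excluded", n_excluded)
    if usable.size == 0:
        return dict(pct_improved=np.nan, n=0, n_excluded=n_excluded)
    return dict(
        pct_improved=100.0 * float((usable < 1).sum()) / usable.size,
        n=int(usable.size),
        n_excluded=n_excluded,
    )
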