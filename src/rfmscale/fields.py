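"""Per-cell, per-species (optionally per-sector) concentration fields.

A :class:`SpeciesField` is a thin wrapper around a long-format DataFrame
with columns ``cell_id, species, sector, value`` (value in ug/m3).  The
sector column carries ``"total"`` for fields without a sector breakdown.
The wrapper exists to keep the linearity bookkeeping honest: summing the
per-sector fields of a linear model must reproduce its total field, and a
multiplicative scaling applied per cell-and-species must commute with that
sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SpeciesField", "TOTAL_SECTOR"]

TOTAL_SECTOR = "total"

_COLUMNS = ["cell_id", "species", "sector", "value"]


@dataclass
class SpeciesField:
    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in _COLUMNS if c not in df.columns]
        if "sector" in missing:
            df = df.assign(sector=TOTAL_SECTOR)
            missing.remove("sector")
        if missing:
            raise ValueError(f"SpeciesField frame lacks columns {missing}")
        self.data = df.loc[:, _COLUMNS].reset_index(drop=True)

    # --- constructors -------------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        cell_ids,
        species: str,
        values,
        sector: str = TOTAL_SECTOR,
    ) -> "SpeciesField":
        return cls(
            pd.DataFrame(
                dict(
                    cell_id=np.asarray(cell_ids),
                    species=species,
                    sector=sector,
                    value=np.asarray(values, dtype=float),
                )
            )
        )

    @classmethod
    def concat(cls, fields) -> "SpeciesField":
        return cls(pd.concat([f.data for f in fields], ignore_index=True))

    # --- views --------------------------------------------------------------

    @property
    def species(self) -> list[str]:
        return sorted(self.data["species"].unique())

    @property
    def sectors(self) -> list[str]:
        return sorted(self.data["sector"].unique())

    def select(self, species: str | None = None, sector: str | None = None) -> "SpeciesField":
        df = self.data
        if species is not None:
            df = df[df["species"] == species]
        if sector is not None:
            df = df[df["sector"] == sector]
        return SpeciesField(df.copy())

    def series(self, species: str, sector: str = TOTAL_SECTOR) -> pd.Series:
        """Values indexed by cell_id for one species and sector."""
        df = self.select(species, sector).data
        return df.set_index("cell_id")["value"]

    def total(self) -> "SpeciesField":
        """Sum over sectors; a linear model's total field."""
        agg = (
            self.data.groupby(["cell_id", "species"], as_index=False, sort=False)["value"]
            .sum()
            .assign(sector=TOTAL_SECTOR)
        )
        return SpeciesField(agg)

    def total_over_species(self) -> pd.Series:
        """Per-cell total concentration summed over species (and sectors)."""
        return self.data.groupby("cell_id", sort=False)["value"].sum()

    def scale(self, factors: pd.Series | float) -> "SpeciesField":
        """Multiply values by per-row factors (aligned on the frame index)."""
        out = self.data.copy()
        out["value"] = out["value"] * factors
        return SpeciesField(out)

    # --- IO -------------------------------------------------------------------

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "SpeciesField":
        return cls(pd.read_csv(path, dtype={"cell_id": str}))
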