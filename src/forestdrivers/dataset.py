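"""The spatial dataset container: observations at projected coordinates.

One row per analysis-grid cell centroid (or arbitrary point), with one
dependent variable and named covariates. Backed by a pandas DataFrame with
reserved columns ``id``, ``x`` and ``y``; every other column is a variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from forestdrivers.errors import ValidationError

RESERVED = ("id", "x", "y")

__all__ = ["SpatialDataset"]


@dataclass
class SpatialDataset:
    """Point observations with projected coordinates and named variables.

    Parameters
    ----------
    table:
        DataFrame with columns ``id`` (unique), ``x``, ``y`` (projected
        meters) plus one column per variable.
    crs:
        Coordinate reference system tag; must describe projected meters.
    """

    table: pd.DataFrame
    crs: str = "local-meters"

    def __post_init__(self) -> None:
        missing = [c for c in RESERVED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"spatial dataset missing columns: {missing}")
        ids = self.table["id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValidationError(f"duplicate observation id: {dup!r}")
        coords = self.table[["x", "y"]].to_numpy(dtype=float)
        if not np.isfinite(coords).all():
            bad = self.table.loc[~np.isfinite(coords).all(axis=1), "id"].iloc[0]
            raise ValidationError(f"non-finite coordinate for observation id {bad!r}")
        self.table = self.table.reset_index(drop=True)

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()

    @property
    def coords(self) -> np.ndarray:
        return self.table[["x", "y"]].to_numpy(dtype=float)

    @property
    def variables(self) -> list[str]:
        return [c for c in self.table.columns if c not in RESERVED]

    def covariates(self, dep: str) -> list[str]:
        """All variable names except the dependent one."""
        if dep not in self.variables:
            raise ValidationError(f"dependent variable {dep!r} not in dataset")
        return [v for v in self.variables if v != dep]

    def values(self, names: list[str] | str) -> np.ndarray:
        return self.table[names].to_numpy()

    def non_finite_report(self) -> pd.Series:
        """Count of non-finite entries per variable column."""
        num = self.table[self.variables].apply(pd.to_numeric, errors="coerce")
        return (~np.isfinite(num)).sum()

    # -- transforms ------------------------------------------------------
    def normalize_inverted(self, names: list[str]) -> "SpatialDataset":
        """Min-max normalize the named columns to 0-1 and invert them.

        Used for accessibility/distance covariates where large raw values
        mean *remote*: after this transform values near 1 mean *accessible*.
        """
        table = self.table.copy()
        for name in names:
            if name not in self.variables:
                raise ValidationError(f"cannot normalize unknown variable {name!r}")
            col = table[name].to_numpy(dtype=float)
            lo, hi = np.nanmin(col), np.nanmax(col)
            if hi == lo:
                table[name] = 0.0
            else:
                table[name] = 1.0 - (col - lo) / (hi - lo)
        return SpatialDataset(table, crs=self.crs)

    def subset(self, index: np.ndarray) -> pd.DataFrame:
        """Positional row subset of the raw table (keeps all columns)."""
        return self.table.iloc[np.asarray(index)].reset_index(drop=True)
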