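"""Forest-change products on the analysis grid.

Implements the FAO compound annual change rate q = (A2/A1)^(1/(t2-t1)) - 1
per grid cell, minimum-patch filtering of change maps, land-cover frequency
metrics around change events, pixel-wise linear trends of annual raster
stacks, and extraction of raster layers into analysis-grid cells.

Sign convention: forest loss gives q < 0. Reporting layers may take
absolute values for map readability; the sign is always retained in stored
data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from forestdrivers.errors import ValidationError
from forestdrivers.grid import AnalysisGrid, Raster

logger = logging.getLogger(__name__)

__all__ = [
    "LandCoverStack",
    "annual_change_rate",
    "filter_min_patch",
    "landcover_frequency",
    "frequency_surface",
    "pixelwise_trend",
    "grid_extract",
    "validate_reforestation_persistence",
]


@dataclass
class LandCoverStack:
    """Ordered multi-date categorical raster stack.

    ``data`` has shape (n_dates, rows, cols); ``dates`` are the acquisition
    years in ascending order.
    """

    data: np.ndarray
    dates: list[int]
    x_origin: float = 0.0
    y_origin: float = 0.0
    cell_size: float = 100.0
    crs: str = "local-meters"
    nodata: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError("stack data must be (n_dates, rows, cols)")
        if len(self.dates) != self.data.shape[0]:
            raise ValidationError("dates must match the stack's first axis")
        if list(self.dates) != sorted(self.dates):
            raise ValidationError("dates must be ascending")

    @property
    def n_dates(self) -> int:
        return self.data.shape[0]

    def band(self, index: int) -> Raster:
        return Raster(
            self.data[index],
            x_origin=self.x_origin,
            y_origin=self.y_origin,
            cell_size=self.cell_size,
            crs=self.crs,
            nodata=self.nodata,
        )


def annual_change_rate(A1, A2, t1, t2):
    """FAO compound annual change rate q = (A2/A1)^(1/(t2-t1)) - 1.

    Vectorized over areas. Cells with A1 = 0 are undefined and returned as
    NaN; the count of such cells is logged.
    """
    A1 = np.asarray(A1, dtype=float)
    A2 = np.asarray(A2, dtype=float)
    if t2 <= t1:
        raise ValidationError(f"t2 must exceed t1 (got {t1}, {t2})")
    if (A2 < 0).any() if A2.ndim else A2 < 0:
        raise ValidationError("A2 must be nonnegative")
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(A1 > 0, (A2 / np.where(A1 > 0, A1, np.nan)) ** (1.0 / (t2 - t1)) - 1.0, np.nan)
    n_undef = int(np.sum(~(A1 > 0)))
    if n_undef:
        logger.info("annual_change_rate: %d cells with A1=0 returned as missing", n_undef)
    return q if q.ndim else float(q)


def filter_min_patch(
    raster: Raster, min_area_ha: float = 1.0, connectivity: int = 8
) -> tuple[Raster, int]:
    """Clear connected change patches smaller than ``min_area_ha``.

    Small isolated patches in change maps frequently represent
    misclassified pixels and are removed before rate calculation. Patches
    are connected components of equal nonzero class value (8-neighbor by
    default); cleared pixels are set to 0 (background). Returns the
    filtered raster and the number of removed patches. Idempotent.
    """
    if connectivity not in (4, 8):
        raise ValidationError("connectivity must be 4 or 8")
    if raster.cell_size is None or raster.cell_size <= 0:
        raise ValidationError("pixel area unknown: raster needs a positive cell_size")
    structure = np.ones((3, 3)) if connectivity == 8 else ndimage.generate_binary_structure(2, 1)
    pixel_ha = raster.pixel_area_ha
    min_pixels = int(np.ceil(min_area_ha / pixel_ha))
    data = raster.data.copy()
    background = 0
    removed = 0
    for cls in np.unique(data):
        if cls == background or (raster.nodata is not None and cls == raster.nodata):
            continue
        labeled, n = ndimage.label(data == cls, structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(labeled.ravel())[1:]
        small = np.flatnonzero(sizes < min_pixels) + 1
        if small.size:
            data[np.isin(labeled, small)] = background
            removed += int(small.size)
    return raster.with_data(data), removed


def landcover_frequency(
    stack: LandCoverStack, event_date: int, cls, direction: str
):
    """Percent of dates a class occupies pixels around a change event.

    With a (1-based) event date i in a stack of n dates, the segment is
    M_a = dates i..n for ``direction='after'`` (deforestation: what the
    land became) and M_b = dates 1..i-1 for ``direction='before'``
    (reforestation: what the land was). The frequency is
    100 * (occurrences of ``cls`` in the segment) / (segment length),
    computed per pixel. A 'before' segment at the first date is empty and
    rejected.
    """
    if direction not in ("after", "before"):
        raise ValidationError("direction must be 'after' or 'before'")
    n = stack.n_dates
    if not (1 <= event_date <= n):
        raise ValidationError(f"event date {event_date} outside stack dates 1..{n}")
    if direction == "after":
        segment = stack.data[event_date - 1 :]
    else:
        if event_date == 1:
            raise ValidationError(
                "empty 'before' segment: event at the first stack date"
            )
        segment = stack.data[: event_date - 1]
    return 100.0 * (segment == cls).sum(axis=0) / segment.shape[0]


def frequency_surface(
    stack: LandCoverStack, event_dates: Raster, cls, direction: str
) -> Raster:
    """Per-pixel land-cover frequency using each pixel's own event date.

    ``event_dates`` holds the 1-based event date per pixel, with values < 1
    (or nodata) marking pixels without an event; those come back NaN, as do
    pixels whose segment would be empty.
    """
    if event_dates.data.shape != stack.data.shape[1:]:
        raise ValidationError("event-date raster does not match stack shape")
    out = np.full(event_dates.data.shape, np.nan)
    dates = np.unique(event_dates.data)
    for d in dates:
        d = int(d)
        if d < 1 or (direction == "before" and d == 1):
            continue
        if d > stack.n_dates:
            continue
        mask = event_dates.data == d
        freq = landcover_frequency(stack, d, cls, direction)
        out[mask] = freq[mask]
    return Raster(
        out,
        x_origin=stack.x_origin,
        y_origin=stack.y_origin,
        cell_size=stack.cell_size,
        crs=stack.crs,
    )


def pixelwise_trend(stack: np.ndarray, years: np.ndarray) -> np.ndarray:
    """Per-pixel OLS slope of value against year.

    ``stack`` is (n_dates, rows, cols) with NaN for missing observations;
    pixels with fewer than 2 finite values come back NaN. At least 3 dates
    are required for a trend to be meaningful.
    """
    stack = np.asarray(stack, dtype=float)
    years = np.asarray(years, dtype=float)
    if stack.ndim != 3 or stack.shape[0] != years.size:
        raise ValidationError("stack must be (n_dates, rows, cols) matching years")
    if years.size < 3:
        raise ValidationError("at least 3 dates required for a trend")
    finite = np.isfinite(stack)
    n = finite.sum(axis=0)
    yr = years[:, None, None]
    x_masked = np.where(finite, yr, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        x_mean = np.nanmean(x_masked, axis=0)
        y_mean = np.nanmean(stack, axis=0)
        dx = x_masked - x_mean
        dy = stack - y_mean
        sxy = np.nansum(np.where(finite, dx * dy, 0.0), axis=0)
        sxx = np.nansum(np.where(finite, dx * dx, 0.0), axis=0)
        slope = sxy / sxx
    slope[(n < 2) | (sxx == 0)] = np.nan
    return slope


def grid_extract(
    raster: Raster,
    grid: AnalysisGrid,
    stat: str = "mean",
) -> pd.DataFrame:
    """Aggregate a raster into analysis-grid cells.

    Pixels are assigned to the cell containing their center. ``stat`` is
    ``'mean'`` for continuous layers or ``'area_by_class'`` for categorical
    layers (hectares of each class value per cell). The raster and grid
    must share a CRS; there is no silent reprojection.
    """
    if raster.crs != grid.crs:
        raise ValidationError(
            f"CRS mismatch: raster {raster.crs!r} vs grid {grid.crs!r} "
            "(reproject explicitly before extraction)"
        )
    px, py = raster.pixel_centers()
    cell = grid.cell_index_of(px.ravel(), py.ravel())
    values = raster.data.ravel()
    inside = cell >= 0
    valid = inside & raster.mask_valid().ravel()
    cell, values = cell[valid], values[valid]

    if stat == "mean":
        sums = np.bincount(cell, weights=values.astype(float), minlength=grid.n_cells)
        counts = np.bincount(cell, minlength=grid.n_cells)
        with np.errstate(invalid="ignore"):
            means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        return pd.DataFrame(
            {"cell_id": grid.cell_ids(), "mean": means, "n_pixels": counts}
        )
    if stat == "area_by_class":
        out = pd.DataFrame({"cell_id": grid.cell_ids()})
        pixel_ha = raster.pixel_area_ha
        for cls in np.unique(values):
            counts = np.bincount(cell[values == cls], minlength=grid.n_cells)
            out[f"area_ha_{cls}"] = counts * pixel_ha
        return out
    raise ValidationError(f"unknown stat {stat!r}")


def validate_reforestation_persistence(
    stack: LandCoverStack,
    event_dates: Raster,
    forest_class,
    min_years: int = 4,
) -> pd.DataFrame:
    """Check that flagged reforestation pixels stay forest long enough.

    Reforestation events are only credible when the pixel remains forest
    from its event date through the end of the series and for at least
    ``min_years`` years. This validates event rasters produced upstream;
    it does not detect events itself. Returns a per-violation report.
    """
    step = (stack.dates[-1] - stack.dates[0]) / max(stack.n_dates - 1, 1)
    bad = []
    rows, cols = event_dates.data.shape
    for r in range(rows):
        for c in range(cols):
            d = int(event_dates.data[r, c])
            if d < 1:
                continue
            series = stack.data[d - 1 :, r, c]
            years_spanned = (series.size - 1) * step
            if (series != forest_class).any():
                bad.append((r, c, d, "not forest until series end"))
            elif years_spanned < min_years:
                bad.append((r, c, d, f"persists {years_spanned:g}y < {min_years}y"))
    return pd.DataFrame(bad, columns=["row", "col", "event_date", "reason"])
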