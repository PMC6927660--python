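"""In-memory raster and analysis-grid containers.

Rasters are plain numpy arrays with a north-up, square-pixel georeference
(top-left origin, pixel-center coordinate convention) and a CRS tag that is
carried through every operation — layers with different CRS tags never
combine silently.  The analysis grid is the coarse regular lattice of square
cells (400 ha by default) onto which rates and covariates are aggregated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from forestdrivers.errors import AlignmentError, CrsMismatchError, ValidationError

__all__ = ["Raster", "AnalysisGrid"]


@dataclass
class Raster:
    """A single-band raster: 2-D array + square-pixel georeference.

    Parameters
    ----------
    data:
        2-D array (rows run north to south).
    x_origin, y_origin:
        Projected coordinates (m) of the top-left corner of the top-left
        pixel.
    cell_size:
        Pixel edge length in meters (square pixels; 100 m = 1 ha pixels).
    crs:
        Free-form CRS tag (e.g. an EPSG string). Compared verbatim.
    nodata:
        Value marking missing pixels, or None.
    """

    data: np.ndarray
    x_origin: float = 0.0
    y_origin: float = 0.0
    cell_size: float = 100.0
    crs: str = "local-meters"
    nodata: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValidationError(f"raster data must be 2-D, got {self.data.ndim}-D")
        if self.cell_size <= 0:
            raise ValidationError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def pixel_area_ha(self) -> float:
        return self.cell_size**2 / 10_000.0

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of every pixel center, matching shape."""
        rows, cols = self.shape
        xs = self.x_origin + (np.arange(cols) + 0.5) * self.cell_size
        ys = self.y_origin - (np.arange(rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def mask_valid(self) -> np.ndarray:
        valid = np.isfinite(self.data.astype(float))
        if self.nodata is not None:
            valid &= self.data != self.nodata
        return valid

    def aligned_with(self, other: "Raster") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.x_origin, other.x_origin)
            and np.isclose(self.y_origin, other.y_origin)
            and np.isclose(self.cell_size, other.cell_size)
            and self.crs == other.crs
        )

    def require_aligned(self, other: "Raster", what: str = "rasters") -> None:
        if self.crs != other.crs:
            raise CrsMismatchError(f"{what}: CRS {self.crs!r} != {other.crs!r}")
        if not self.aligned_with(other):
            raise AlignmentError(
                f"{what}: grids differ "
                f"(shape {self.shape} vs {other.shape}, "
                f"origin ({self.x_origin},{self.y_origin}) vs "
                f"({other.x_origin},{other.y_origin}), "
                f"cell {self.cell_size} vs {other.cell_size})"
            )

    def with_data(self, data: np.ndarray) -> "Raster":
        return replace(self, data=np.asarray(data))


@dataclass
class AnalysisGrid:
    """Regular lattice of square analysis cells (row-major cell ids).

    The default cell size of 2000 m gives 400-ha cells.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 2000.0
    x_origin: float = 0.0
    y_origin: float | None = None
    crs: str = "local-meters"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValidationError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ValidationError("cell_size must be positive")
        if self.y_origin is None:
            # default: place the grid so the bottom-left corner sits at (0, 0)
            self.y_origin = self.n_rows * self.cell_size

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_area_ha(self) -> float:
        return self.cell_size**2 / 10_000.0

    def cell_ids(self) -> np.ndarray:
        return np.arange(self.n_cells)

    def centroids(self) -> np.ndarray:
        """(n_cells, 2) array of cell-centroid coordinates, row-major."""
        rows, cols = np.divmod(np.arange(self.n_cells), self.n_cols)
        x = self.x_origin + (cols + 0.5) * self.cell_size
        y = self.y_origin - (rows + 0.5) * self.cell_size
        return np.column_stack([x, y])

    def cell_index_of(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Row-major cell id containing each (x, y) point; -1 if outside."""
        col = np.floor((np.asarray(x) - self.x_origin) / self.cell_size).astype(int)
        row = np.floor((self.y_origin - np.asarray(y)) / self.cell_size).astype(int)
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        out = np.where(inside, row * self.n_cols + col, -1)
        return out

    def cell_bounds(self, cell_id: int) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of one cell."""
        row, col = divmod(int(cell_id), self.n_cols)
        xmin = self.x_origin + col * self.cell_size
        ymax = self.y_origin - row * self.cell_size
        return (xmin, ymax - self.cell_size, xmin + self.cell_size, ymax)
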