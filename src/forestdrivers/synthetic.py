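"""Synthetic inputs with known ground truth for every pipeline stage.

No deposited study data accompany the methodology, so each stage is
exercised on generated landscapes whose generating process is fully known:

- spatial datasets on a square analysis grid of 400-ha cells whose
  covariate-response relationship varies by region (each region has its
  own active covariates and effect sizes), with the active-region map
  returned as ground truth;
- categorical land-cover stacks with planted change events whose dates
  are emitted alongside, so land-cover frequencies have closed-form
  expected values;
- census blocks overlapping three rural density classes, with the true
  per-class cell count of every block recorded for allocation checks.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box

from forestdrivers.change import LandCoverStack
from forestdrivers.dasymetric import CensusBlockSet
from forestdrivers.dataset import SpatialDataset
from forestdrivers.errors import ValidationError
from forestdrivers.grid import AnalysisGrid, Raster

__all__ = [
    "Region",
    "SyntheticSpec",
    "two_region_spec",
    "generate_spatial_dataset",
    "generate_landcover_stack",
    "generate_census_fixture",
]

# land-cover class codes used by the synthetic stacks
FOREST, BAMBOO, BARE, PASTURE = 1, 2, 3, 4


@dataclass(frozen=True)
class Region:
    """A rectangular sub-extent with its own active covariates.

    ``x_range`` / ``y_range`` are fractions of the grid extent in [0, 1];
    ``effects`` maps covariate names to linear effect sizes.
    """

    name: str
    x_range: tuple[float, float]
    y_range: tuple[float, float]
    effects: dict[str, float]


@dataclass(frozen=True)
class SyntheticSpec:
    """Specification of one synthetic spatial dataset.

    ``n_cells`` must be a perfect square (the grid is square);
    ``cell_size`` defaults to 2000 m so each cell covers 400 ha. Regions
    must tile the grid without overlap, and every active covariate must be
    one of the ``n_covariates`` generated columns (named x1..xp).
    """

    seed: int
    n_cells: int
    regions: tuple[Region, ...]
    n_covariates: int
    noise_sd: float = 0.5
    cell_size: float = 2000.0
    class_breaks: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        side = int(round(np.sqrt(self.n_cells)))
        if side * side != self.n_cells:
            raise ValidationError(f"n_cells={self.n_cells} is not a perfect square")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")
        if self.n_covariates < 1:
            raise ValidationError("need at least one covariate")
        names = set(self.covariate_names)
        for region in self.regions:
            unknown = set(region.effects) - names
            if unknown:
                raise ValidationError(
                    f"region {region.name!r} activates unknown covariates {sorted(unknown)}"
                )
        # regions must tile the grid without overlap
        counts = np.zeros(self.n_cells, dtype=int)
        for region in self.regions:
            counts += self._region_mask(region)
        if (counts > 1).any():
            raise ValidationError("regions overlap")
        if (counts == 0).any():
            raise ValidationError("regions do not cover the whole grid")

    @property
    def side(self) -> int:
        return int(round(np.sqrt(self.n_cells)))

    @property
    def covariate_names(self) -> list[str]:
        return [f"x{k + 1}" for k in range(self.n_covariates)]

    def grid(self) -> AnalysisGrid:
        return AnalysisGrid(self.side, self.side, cell_size=self.cell_size)

    def _region_mask(self, region: Region) -> np.ndarray:
        # half-open membership [lo, hi) except at the top edge, so abutting
        # regions never double-claim a cell
        rows, cols = np.divmod(np.arange(self.n_cells), self.side)
        fx = (cols + 0.5) / self.side
        fy = (rows + 0.5) / self.side
        x0, x1 = region.x_range
        y0, y1 = region.y_range
        return (
            (fx >= x0) & ((fx < x1) | (x1 >= 1.0))
            & (fy >= y0) & ((fy < y1) | (y1 >= 1.0))
        ).astype(int)

    def region_of_cells(self) -> np.ndarray:
        out = np.full(self.n_cells, "", dtype=object)
        for region in self.regions:
            out[self._region_mask(region).astype(bool)] = region.name
        return out


def two_region_spec(
    n_cells: int = 900,
    effect: float = 2.0,
    noise_sd: float = 0.5,
    n_covariates: int = 6,
    seed: int = 7,
) -> SyntheticSpec:
    """The canonical two-region benchmark: west driven by x1, east by x2."""
    return SyntheticSpec(
        seed=seed,
        n_cells=n_cells,
        regions=(
            Region("west", (0.0, 0.5), (0.0, 1.0), {"x1": effect}),
            Region("east", (0.5, 1.0), (0.0, 1.0), {"x2": effect}),
        ),
        n_covariates=n_covariates,
        noise_sd=noise_sd,
    )


def generate_spatial_dataset(
    spec: SyntheticSpec, dep_name: str = "rate"
) -> tuple[SpatialDataset, pd.DataFrame]:
    """Draw a spatial dataset with regionally varying drivers.

    Covariates are i.i.d. standard normal; within region r the response is
    ``sum(effect_k * x_k for active k) + N(0, noise_sd)``. Returns the
    dataset and the ground truth: per cell, its region and the active
    covariate of largest absolute effect.
    """
    rng = np.random.default_rng(spec.seed)
    grid = spec.grid()
    coords = grid.centroids()
    X = rng.standard_normal((spec.n_cells, spec.n_covariates))
    y = rng.normal(0.0, spec.noise_sd, size=spec.n_cells) if spec.noise_sd > 0 else np.zeros(spec.n_cells)
    names = spec.covariate_names
    col = {name: j for j, name in enumerate(names)}

    region_names = spec.region_of_cells()
    active_primary = np.full(spec.n_cells, "", dtype=object)
    for region in spec.regions:
        mask = spec._region_mask(region).astype(bool)
        for name, effect in region.effects.items():
            y[mask] += effect * X[mask, col[name]]
        if region.effects:
            active_primary[mask] = max(region.effects, key=lambda k: abs(region.effects[k]))

    table = pd.DataFrame({"id": grid.cell_ids(), "x": coords[:, 0], "y": coords[:, 1]})
    table[dep_name] = y
    for j, name in enumerate(names):
        table[name] = X[:, j]
    truth = pd.DataFrame(
        {
            "id": grid.cell_ids(),
            "region": region_names,
            "active_covariate": active_primary,
        }
    )
    return SpatialDataset(table, crs="local-meters"), truth


def generate_landcover_stack(
    n_dates: int,
    extent: tuple[int, int],
    event_fraction: float,
    seed: int,
    event_to: int = PASTURE,
    cell_size: float = 100.0,
) -> tuple[LandCoverStack, Raster]:
    """A categorical stack with planted deforestation-style events.

    Each pixel keeps a constant class; pixels flagged as events start as
    forest and switch to ``event_to`` at a known date (uniform over dates
    2..n). Returns the stack and the 1-based event-date raster (0 where no
    event), which makes every land-cover frequency computable in closed
    form from the planted schedule.
    """
    if n_dates < 3:
        raise ValidationError("need at least 3 dates in a stack")
    if not (0.0 <= event_fraction <= 1.0):
        raise ValidationError(f"event_fraction {event_fraction} outside [0, 1]")
    rng = np.random.default_rng(seed)
    rows, cols = extent
    base = rng.choice([FOREST, BAMBOO, BARE, PASTURE], size=(rows, cols))
    is_event = rng.random((rows, cols)) < event_fraction
    event_date = np.where(is_event, rng.integers(2, n_dates + 1, size=(rows, cols)), 0)

    data = np.repeat(base[None, :, :], n_dates, axis=0)
    data[:, is_event] = FOREST
    for d in range(2, n_dates + 1):
        switched = (event_date > 0) & (event_date <= d)
        data[d - 1][switched] = event_to
    dates = list(range(2000, 2000 + n_dates))
    stack = LandCoverStack(
        data=data, dates=dates, cell_size=cell_size, y_origin=rows * cell_size
    )
    events = Raster(
        event_date.astype(np.int16),
        cell_size=cell_size,
        y_origin=rows * cell_size,
    )
    return stack, events


def generate_census_fixture(
    n_blocks: int,
    class_raster_shape: tuple[int, int],
    seed: int,
    densities: tuple[float, float, float] = (0.010, 0.008, 0.002),
) -> tuple[CensusBlockSet, Raster, pd.DataFrame]:
    """Census blocks over a three-band rural density class raster.

    The class raster is split into three vertical bands (high / medium /
    low, 1-ha pixels). The first three blocks sit fully inside one band
    each (so class densities are sampleable); remaining blocks are random
    rectangles that may straddle bands. Populations are drawn Poisson
    around the target class ``densities`` (persons/ha). Returns the block
    set, the class raster, and the true per-class cell counts per block.
    """
    if n_blocks < 3:
        raise ValidationError("need at least 3 blocks (one per density class)")
    rows, cols = class_raster_shape
    if cols < 9 or rows < 3:
        raise ValidationError("class raster too small for three bands of blocks")
    rng = np.random.default_rng(seed)
    cell = 100.0  # 1-ha pixels
    band = cols // 3
    classes = np.zeros((rows, cols), dtype=np.int16)
    classes[:, :band] = 1
    classes[:, band : 2 * band] = 2
    classes[:, 2 * band :] = 3
    class_raster = Raster(classes, cell_size=cell, y_origin=rows * cell)

    def cell_box(r0, r1, c0, c1):
        # pixel-aligned rectangle covering rows r0..r1-1, cols c0..c1-1
        return box(c0 * cell, (rows - r1) * cell, c1 * cell, (rows - r0) * cell)

    n_rem = n_blocks - 3
    if n_rem > cols - 1:
        raise ValidationError(
            f"too many blocks ({n_blocks}) for raster width {cols}"
        )
    geoms, records = [], []
    band_starts = (0, band, 2 * band)
    strip = max(1, rows // 3)  # top strip hosts the three pure blocks
    for u in range(3):
        # one block fully inside band u (blocks never overlap each other)
        w = max(1, band // 2)
        c0 = band_starts[u] + int(rng.integers(0, band - w + 1))
        geoms.append(cell_box(0, strip, c0, c0 + w))
    if n_rem:
        # partition the remaining strip into contiguous vertical slices,
        # which may straddle density-class bands
        if n_rem > 1:
            cuts = np.sort(rng.choice(np.arange(1, cols), size=n_rem - 1, replace=False))
        else:
            cuts = np.array([], dtype=int)
        edges = np.concatenate([[0], cuts, [cols]])
        for c0, c1 in zip(edges[:-1], edges[1:]):
            geoms.append(cell_box(strip, rows, int(c0), int(c1)))

    truth_rows = []
    for i, geom in enumerate(geoms):
        minx, miny, maxx, maxy = geom.bounds
        c0, c1 = int(minx / cell), int(maxx / cell)
        r0, r1 = rows - int(maxy / cell), rows - int(miny / cell)
        patch = classes[r0:r1, c0:c1]
        if patch.size == 0:
            raise ValidationError(f"block {i} covers zero cells")
        counts = {u: int((patch == u).sum()) for u in (1, 2, 3)}
        area_ha = patch.size  # 1-ha pixels
        density = sum(densities[u - 1] * counts[u] for u in (1, 2, 3)) / patch.size
        pop = int(rng.poisson(max(density * area_ha, 0.0)))
        records.append({"block_id": f"B{i:03d}", "pop": pop})
        truth_rows.append(
            {
                "block_id": f"B{i:03d}",
                "n_high": counts[1],
                "n_medium": counts[2],
                "n_low": counts[3],
                "n_total": patch.size,
            }
        )
    blocks = CensusBlockSet(pd.DataFrame(records), geoms)
    return blocks, class_raster, pd.DataFrame(truth_rows)
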