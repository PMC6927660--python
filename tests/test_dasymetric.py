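"""Dasymetric mapping: density classes, fractions, allocation, conservation."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from forestdrivers import dasymetric as dm
from forestdrivers.errors import AlignmentError, ValidationError
from forestdrivers.grid import Raster
from forestdrivers.synthetic import generate_census_fixture

# the reference worked example: sampled census blocks of the three rural
# density classes (persons, hectares) in two census years
SAMPLE_2001 = pd.DataFrame(
    {
        "class": ["high", "medium", "low"],
        "population": [36, 34, 23],
        "area_ha": [4293, 3195, 10420],
    }
)
SAMPLE_2010 = pd.DataFrame(
    {
        "class": ["high", "medium", "low"],
        "population": [68, 42, 18],
        "area_ha": [4297, 3269, 10389],
    }
)


def _raster(data, cell=100.0):
    data = np.asarray(data)
    return Raster(data, cell_size=cell, y_origin=data.shape[0] * cell)


class TestDensityClasses:
    def test_travel_time_breaks(self):
        tt = _raster(np.array([[0.5, 2.0, 5.0]]))
        mask = _raster(np.array([[1, 1, 1]]))
        classes = dm.build_density_classes(tt, mask)
        assert list(classes.data[0]) == [1, 2, 3]  # high, medium, low

    def test_boundary_values_left_closed(self):
        tt = _raster(np.array([[0.0, 1.0, 3.0]]))
        mask = _raster(np.array([[1, 1, 1]]))
        classes = dm.build_density_classes(tt, mask)
        assert list(classes.data[0]) == [1, 2, 3]

    def test_forest_pixel_excluded_regardless_of_travel_time(self):
        tt = _raster(np.array([[0.2, 0.2]]))
        mask = _raster(np.array([[1, 0]]))
        classes = dm.build_density_classes(tt, mask)
        assert list(classes.data[0]) == [1, 0]

    def test_misaligned_rasters_rejected(self):
        tt = _raster(np.zeros((2, 2)))
        mask = Raster(np.ones((2, 2)), cell_size=100.0, y_origin=200.0, x_origin=50.0)
        with pytest.raises(AlignmentError):
            dm.build_density_classes(tt, mask)


class TestClassDensities:
    def test_worked_example_2001(self):
        # the sampled block populations/areas reproduce the documented density
        # fractions at their 3-decimal display precision
        table = dm.sample_class_densities(SAMPLE_2001, year=2001)
        fr = table.fractions()
        assert fr[1] == pytest.approx(0.394, abs=1e-3)
        assert fr[2] == pytest.approx(0.501, abs=1e-3)
        assert fr[3] == pytest.approx(0.103, abs=1e-3)
        assert sum(fr.values()) == pytest.approx(1.0)

    def test_equal_densities_give_equal_thirds(self):
        samples = pd.DataFrame(
            {"class": [1, 2, 3], "population": [10, 20, 30], "area_ha": [100, 200, 300]}
        )
        fr = dm.sample_class_densities(samples, 2001).fractions()
        assert all(f == pytest.approx(1 / 3) for f in fr.values())

    def test_zero_density_class_renormalizes(self):
        samples = pd.DataFrame(
            {"class": [1, 2, 3], "population": [10, 10, 0], "area_ha": [100, 100, 100]}
        )
        fr = dm.sample_class_densities(samples, 2001).fractions()
        assert fr[3] == 0.0
        assert fr[1] == pytest.approx(0.5) and fr[2] == pytest.approx(0.5)

    def test_missing_class_rejected_with_found_list(self):
        samples = SAMPLE_2001[SAMPLE_2001["class"] != "low"]
        with pytest.raises(ValidationError, match="low"):
            dm.sample_class_densities(samples, 2001)

    def test_average_year_fractions_reproduces_reference_values(self):
        # averaging the printed per-year fractions gives the final
        # allocation fractions 0.570 / 0.553 / 0.092
        t1 = dm.ClassDensityTable(
            2001,
            pd.DataFrame({"class": [1, 2, 3], "fraction": [0.394, 0.501, 0.103]}),
        )
        t2 = dm.ClassDensityTable(
            2010,
            pd.DataFrame({"class": [1, 2, 3], "fraction": [0.745, 0.604, 0.081]}),
        )
        avg = dm.average_year_fractions([t1, t2])
        assert avg[1] == pytest.approx(0.570, abs=1e-3)
        assert avg[2] == pytest.approx(0.553, abs=1e-3)
        assert avg[3] == pytest.approx(0.092, abs=1e-3)

    def test_identical_years_unchanged(self):
        t = dm.sample_class_densities(SAMPLE_2001, 2001)
        avg = dm.average_year_fractions([t, t])
        assert avg == pytest.approx(t.fractions())


class TestAreaRatioAndFractions:
    def test_area_ratio_definition(self):
        assert dm.area_ratio(33, 100) == pytest.approx(1.0, abs=1e-12)
        assert dm.area_ratio(100, 100) == pytest.approx(1 / 0.33)
        assert dm.area_ratio(0, 100) == 0.0

    def test_area_ratio_zero_block_rejected(self):
        with pytest.raises(ValidationError):
            dm.area_ratio(0, 0)

    def test_total_fraction_hand_example(self):
        d = {1: 0.5, 2: 0.5, 3: 0.0}
        a = {1: 1.0, 2: 3.0, 3: 0.0}
        f = dm.total_fraction(d, a)
        assert f[1] == pytest.approx(0.25)
        assert f[2] == pytest.approx(0.75)
        assert f[3] == 0.0

    def test_single_class_gets_everything(self):
        f = dm.total_fraction({1: 0.6, 2: 0.3, 3: 0.1}, {1: 2.0, 2: 0.0, 3: 0.0})
        assert f[1] == 1.0

    def test_fractions_normalize(self, rng):
        for _ in range(20):
            d = dict(zip((1, 2, 3), rng.random(3)))
            a = dict(zip((1, 2, 3), rng.random(3)))
            assert sum(dm.total_fraction(d, a).values()) == pytest.approx(1.0)

    def test_all_zero_products_unallocatable(self):
        with pytest.raises(ValidationError, match="unallocatable"):
            dm.total_fraction({1: 0.0, 2: 0.0, 3: 1.0}, {1: 1.0, 2: 1.0, 3: 0.0})


def _single_class_fixture(pop=30.0, n_cells=10):
    """One block fully inside the high class covering n_cells 1-ha cells."""
    classes = _raster(np.full((2, 5), 1, dtype=int))
    blocks = dm.CensusBlockSet(
        pd.DataFrame({"block_id": ["b1"], "pop": [pop]}),
        [box(0, 0, 500, 200)],
    )
    return blocks, classes


class TestAllocation:
    def test_single_class_block_spreads_evenly(self):
        blocks, classes = _single_class_fixture(pop=30.0)
        surface = dm.allocate_population(blocks, classes, {1: 0.5, 2: 0.4, 3: 0.1})
        assert np.allclose(surface.raster.data, 3.0)

    def test_per_cell_equation_with_given_total_fractions(self):
        # pop 30, total fractions f = (0.5, 0.5, 0), class cells (10, 5, 0):
        # f * pop / n_u gives 1.5 and 3.0 persons per cell
        f = {1: 0.5, 2: 0.5, 3: 0.0}
        n_u = {1: 10, 2: 5, 3: 0}
        per_cell = {u: f[u] * 30.0 / n_u[u] for u in (1, 2) }
        assert per_cell[1] == pytest.approx(1.5)
        assert per_cell[2] == pytest.approx(3.0)

    def test_two_class_full_chain_hand_example(self):
        # d = (0.6, 0.3, 0), cells (10, 5): a = (2/3, 1/3)/0.33, products
        # d*a -> f = (0.8, 0.2); per-cell 0.8*30/10 = 2.4 and 0.2*30/5 = 1.2
        data = np.concatenate([np.full(10, 1), np.full(5, 2)])[None, :]
        classes = _raster(data.astype(int))
        blocks = dm.CensusBlockSet(
            pd.DataFrame({"block_id": ["b1"], "pop": [30.0]}),
            [box(0, 0, 1500, 100)],
        )
        surface = dm.allocate_population(blocks, classes, {1: 0.6, 2: 0.3, 3: 0.1})
        assert np.allclose(surface.raster.data[0, :10], 2.4)
        assert np.allclose(surface.raster.data[0, 10:], 1.2)

    def test_conservation_on_synthetic_fixture(self):
        blocks, classes, truth = generate_census_fixture(8, (12, 18), seed=5)
        surface = dm.allocate_population(blocks, classes, {1: 0.57, 2: 0.553, 3: 0.092})
        total_alloc = surface.raster.data.sum()
        allocatable = surface.report.loc[surface.report["status"] == "ok", "population"]
        assert total_alloc == pytest.approx(allocatable.sum(), abs=1e-9)

    def test_scaling_invariance(self):
        blocks, classes, _ = generate_census_fixture(6, (12, 18), seed=9)
        d = {1: 0.57, 2: 0.553, 3: 0.092}
        s1 = dm.allocate_population(blocks, classes, d)
        scaled = dm.CensusBlockSet(
            blocks.table.assign(pop=blocks.table["pop"] * 3.0), blocks.geometries
        )
        s3 = dm.allocate_population(scaled, classes, d)
        assert np.allclose(s3.raster.data, 3.0 * s1.raster.data)

    def test_populated_block_without_cells_reported(self):
        classes = _raster(np.full((2, 5), 1, dtype=int))
        blocks = dm.CensusBlockSet(
            pd.DataFrame({"block_id": ["in", "out"], "pop": [10.0, 7.0]}),
            [box(0, 0, 500, 200), box(10_000, 10_000, 10_100, 10_100)],
        )
        surface = dm.allocate_population(blocks, classes, {1: 1.0, 2: 0.0, 3: 0.0})
        row = surface.report.set_index("block_id").loc["out"]
        assert row["status"] != "ok"
        assert row["allocated"] == 0.0


class TestPycnophylacticCheck:
    def test_fresh_allocation_conserves(self):
        blocks, classes, _ = generate_census_fixture(8, (12, 18), seed=5)
        surface = dm.allocate_population(blocks, classes, {1: 0.57, 2: 0.553, 3: 0.092})
        report = dm.pycnophylactic_check(surface, blocks)
        ok_ids = surface.report.loc[surface.report["status"] == "ok", "block_id"]
        checked = report.set_index("block_id").loc[ok_ids]
        assert (checked["deviation"] < 1e-6).all()
        assert checked["ok"].all()

    def test_tampered_surface_flagged(self):
        blocks, classes = _single_class_fixture(pop=30.0)
        surface = dm.allocate_population(blocks, classes, {1: 1.0, 2: 0.0, 3: 0.0})
        surface.raster.data[0, 0] = 0.0
        report = dm.pycnophylactic_check(surface, blocks)
        assert not report["ok"].iloc[0]

    def test_clipped_block_passes_after_proportional_rescale(self):
        # block clipped to half area with counts halved passes the check
        blocks, classes = _single_class_fixture(pop=30.0)
        table = blocks.table.assign(original_area_ha=20.0)  # current area 10 ha
        clipped = dm.CensusBlockSet(table, blocks.geometries)
        surface = dm.allocate_population(clipped, classes, {1: 1.0, 2: 0.0, 3: 0.0})
        # allocation spreads the full count; emulate the upstream halving
        surface.raster.data[:] = surface.raster.data / 2.0
        report = dm.pycnophylactic_check(surface, clipped)
        assert report["ok"].iloc[0]


class TestIntercensalChange:
    def test_identical_surfaces_zero(self):
        r = _raster(np.full((3, 3), 5.0))
        out = dm.intercensal_change(r, r)
        assert np.allclose(out.data, 0.0)

    def test_constant_increase(self):
        r1 = _raster(np.full((3, 3), 5.0))
        r2 = _raster(np.full((3, 3), 6.0))
        assert np.allclose(dm.intercensal_change(r1, r2).data, 1.0)

    def test_planted_decline_located(self):
        r1 = _raster(np.full((3, 3), 5.0))
        data2 = np.full((3, 3), 5.0)
        data2[1, 2] = 3.0
        out = dm.intercensal_change(r1, _raster(data2))
        assert out.data[1, 2] == pytest.approx(-2.0)
        assert (out.data < 0).sum() == 1

    def test_misalignment_rejected(self):
        r1 = _raster(np.zeros((3, 3)))
        r2 = _raster(np.zeros((4, 3)))
        with pytest.raises(AlignmentError):
            dm.intercensal_change(r1, r2)
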