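"""GWRF: reclassification, local cleaning, local fits, surfaces, sweep."""

import numpy as np
import pandas as pd
import pytest

from forestdrivers import gwrf, synthetic
from forestdrivers.errors import UnfittableLocationError, ValidationError
from forestdrivers.gwrf import GwrfConfig, clean_local_dataset, reclassify_rates
from forestdrivers.weights import KernelSpec


class TestReclassifyRates:
    def test_quantile_balanced_classes(self):
        rates = np.arange(1.0, 101.0)
        classes, table = reclassify_rates(rates, n_classes=5, scheme="quantile")
        counts = np.bincount(classes)[1:]
        assert list(counts) == [20] * 5
        assert len(table) == 5

    def test_fixed_breaks_interval_lookup(self):
        classes, _ = reclassify_rates(
            np.array([0.5, 2.0, 3.0, 6.0]),
            scheme="fixed",
            breaks=[0.0, 1.0, 2.5, 5.0],
        )
        assert list(classes) == [1, 2, 3, 4]

    def test_values_inside_single_interval_occupy_one_class(self):
        classes, _ = reclassify_rates(
            np.array([1.1, 1.5, 1.9]), scheme="fixed", breaks=[0, 1, 2.5, 5]
        )
        assert set(classes) == {2}

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValidationError, match="fewer"):
            reclassify_rates(np.array([1.0, 1.0, 2.0, 2.0]), n_classes=5)

    def test_breaks_recorded_are_reproducible(self):
        rng = np.random.default_rng(3)
        rates = rng.normal(size=200)
        c1, t1 = reclassify_rates(rates, n_classes=5)
        c2, t2 = reclassify_rates(rates, n_classes=5)
        assert (c1 == c2).all()
        pd.testing.assert_frame_equal(t1, t2)


class TestCleanLocalDataset:
    def _local(self, n=12):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(
            {"a": rng.normal(size=n), "b": np.ones(n), "c": rng.normal(size=n)}
        )
        w = np.linspace(1.0, 0.1, n)
        return X, w

    def test_zero_variance_covariate_dropped(self):
        X, w = self._local()
        y = np.repeat(["u", "v"], 6)
        Xc, _, _, dropped, _ = clean_local_dataset(
            X, y, w, "classification", upsample=False
        )
        assert dropped == ["b"]
        assert list(Xc.columns) == ["a", "c"]

    def test_upsampling_balances_to_majority(self):
        X, w = self._local()
        y = np.array(["u"] * 10 + ["v"] * 2)
        rng = np.random.default_rng(1)
        Xc, yc, wc, _, order = clean_local_dataset(
            X, y, w, "classification", upsample=True, rng=rng
        )
        labels, counts = np.unique(yc, return_counts=True)
        assert list(counts) == [10, 10]
        # resampled rows carry their source row's kernel weight
        assert np.allclose(wc, w[order])

    def test_upsampling_deterministic_under_seed(self):
        X, w = self._local()
        y = np.array(["u"] * 9 + ["v"] * 3)
        runs = [
            clean_local_dataset(
                X, y, w, "classification", rng=np.random.default_rng(42)
            )[4]
            for _ in range(2)
        ]
        assert (runs[0] == runs[1]).all()

    def test_single_valued_response_unfittable(self):
        X, w = self._local()
        with pytest.raises(UnfittableLocationError):
            clean_local_dataset(X, np.repeat("u", 12), w, "classification")

    def test_regression_untouched_by_upsampling(self):
        X, w = self._local()
        y = np.arange(12.0)
        Xc, yc, wc, _, order = clean_local_dataset(X, y, w, "regression")
        assert (order == np.arange(12)).all()
        assert (yc == y).all()


def _fit_small(task="regression", n_trees=40, bandwidth=30, seed=11, n_cells=100):
    spec = synthetic.two_region_spec(n_cells=n_cells, seed=3)
    dataset, truth = synthetic.generate_spatial_dataset(spec)
    if task == "classification":
        classes, _ = reclassify_rates(
            np.abs(dataset.table["rate"]), n_classes=3, scheme="quantile"
        )
        dataset.table["rate"] = classes.astype(str)
    cfg = GwrfConfig(
        dep="rate",
        kernel=KernelSpec("adaptive", bandwidth),
        task=task,
        n_trees=n_trees,
        seed=seed,
    )
    return gwrf.fit_gwrf(dataset, cfg), truth


class TestFitLocalModel:
    def test_planted_local_signal_tops_lvi(self):
        # noiseless neighborhood where the response is sign(x1)
        rng = np.random.default_rng(5)
        n = 60
        table = pd.DataFrame(
            {
                "id": np.arange(n),
                "x": rng.uniform(0, 1000, n),
                "y": rng.uniform(0, 1000, n),
                "dep": "",
                "x1": rng.normal(size=n),
                "x2": rng.normal(size=n),
                "x3": rng.normal(size=n),
            }
        )
        table["dep"] = np.where(table["x1"] > 0, "pos", "neg")
        from forestdrivers.dataset import SpatialDataset

        ds = SpatialDataset(table)
        cfg = GwrfConfig(
            dep="dep", kernel=KernelSpec("adaptive", 40), task="classification",
            n_trees=60, seed=2,
        )
        res = gwrf.fit_local_model(0, ds, cfg)
        assert not res.skipped
        assert res.lvi["x1"] == max(res.lvi.values())

    def test_probabilities_sum_to_one_and_kappa_bounded(self):
        result, _ = _fit_small(task="classification", n_cells=100)
        fitted = result.table[~result.table["skipped"]]
        prob_cols = [c for c in result.table.columns if c.startswith("prob_")]
        sums = fitted[prob_cols].sum(axis=1)
        assert np.allclose(sums[sums.notna()], 1.0)
        kappas = fitted["kappa"].dropna()
        assert ((kappas >= -1) & (kappas <= 1)).all()

    def test_removed_variables_present_with_zero(self):
        result, _ = _fit_small()
        lvi = result.lvi_matrix()
        # every covariate column exists at every location
        assert list(lvi.columns) == [f"x{k}" for k in range(1, 7)]
        assert lvi.notna().all().all()
        removed_somewhere = result.table["n_removed"] > 0
        assert removed_somewhere.any()
        assert (lvi.to_numpy() >= 0).all()  # final LVI never negative


class TestFitGwrf:
    def test_regional_driver_recovery(self):
        result, truth = _fit_small()
        lvi = result.lvi_matrix()
        west = (truth["region"] == "west").to_numpy()
        assert lvi.loc[west, "x1"].mean() > lvi.loc[west, "x2"].mean()
        assert lvi.loc[~west, "x2"].mean() > lvi.loc[~west, "x1"].mean()

    def test_deterministic_under_master_seed(self):
        r1, _ = _fit_small(n_trees=25)
        r2, _ = _fit_small(n_trees=25)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_global_bandwidth_limit_constant_surfaces(self):
        # K_bw = n: every location trains on the full dataset, so the LVI
        # surface of the dominant covariate is constant up to bootstrap
        # noise (pairwise coefficient of variation < 0.1)
        spec = synthetic.SyntheticSpec(
            seed=4,
            n_cells=144,
            regions=(
                synthetic.Region("all", (0.0, 1.0), (0.0, 1.0), {"x1": 3.0}),
            ),
            n_covariates=3,
            noise_sd=0.2,
        )
        dataset, _ = synthetic.generate_spatial_dataset(spec)
        cfg = GwrfConfig(
            dep="rate", kernel=KernelSpec("adaptive", 144), task="regression",
            n_trees=100, seed=6, importance_repeats=2,
        )
        result = gwrf.fit_gwrf(dataset, cfg)
        vals = result.lvi_matrix()["x1"]
        assert vals.std(ddof=1) / vals.mean() < 0.1

    def test_oversized_bandwidth_rejected(self):
        spec = synthetic.two_region_spec(n_cells=100, seed=3)
        dataset, _ = synthetic.generate_spatial_dataset(spec)
        cfg = GwrfConfig(dep="rate", kernel=KernelSpec("adaptive", 101))
        with pytest.raises(ValidationError):
            gwrf.fit_gwrf(dataset, cfg)


class TestBandwidthSweep:
    def test_report_rows_match_grid(self):
        spec = synthetic.two_region_spec(n_cells=100, seed=3)
        dataset, _ = synthetic.generate_spatial_dataset(spec)
        cfg = GwrfConfig(
            dep="rate", kernel=KernelSpec("adaptive", 20), task="regression",
            n_trees=15, seed=1,
        )
        out = gwrf.bandwidth_sweep(dataset, cfg, bw_grid=[20, 40, 60])
        assert len(out) == 3
        assert out["recommended"].sum() == 1

    def test_single_value_grid_equals_single_fit(self):
        spec = synthetic.two_region_spec(n_cells=100, seed=3)
        dataset, _ = synthetic.generate_spatial_dataset(spec)
        cfg = GwrfConfig(
            dep="rate", kernel=KernelSpec("adaptive", 30), task="regression",
            n_trees=15, seed=1,
        )
        sweep = gwrf.bandwidth_sweep(dataset, cfg, bw_grid=[30])
        single = gwrf.fit_gwrf(dataset, cfg)
        vals = single.table.loc[~single.table["skipped"], "r_squared"].dropna()
        assert sweep["mean"].iloc[0] == pytest.approx(vals.mean())

    def test_empty_grid_rejected(self):
        spec = synthetic.two_region_spec(n_cells=100, seed=3)
        dataset, _ = synthetic.generate_spatial_dataset(spec)
        cfg = GwrfConfig(dep="rate")
        with pytest.raises(ValidationError):
            gwrf.bandwidth_sweep(dataset, cfg, bw_grid=[])


class TestResultRasterization:
    def test_lvi_column_maps_onto_grid(self):
        from forestdrivers.grid import AnalysisGrid

        result, _ = _fit_small(n_trees=10)
        grid = AnalysisGrid(10, 10, cell_size=2000.0)
        raster = result.rasterize(grid, "LVI_x1")
        assert raster.shape == (10, 10)
        # row-major ids: raster values equal the table column in order
        flat = raster.data.ravel()
        assert np.allclose(flat, result.table["LVI_x1"].to_numpy())
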