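"""Geographically weighted random forest (GWRF).

For every observation i in a spatial dataset, a local random forest is
trained on i's kernel-selected neighborhood with the kernel weights used as
bootstrap sampling probabilities. Each local model yields a local variable
importance (LVI) vector, a prediction (class probabilities or value) and
OOB accuracy metrics; merged over locations these form LVI / YHAT / ACC
surfaces.

The local fitting loop per location:

1. select neighbors within the adaptive/fixed kernel bandwidth;
2. drop zero-variance covariates; for classification, upsample minority
   classes to the local majority count (resampled rows keep their kernel
   weights);
3. compute exponential kernel weights;
4. train a case-weighted forest; compute permutation importance;
5. remove covariates with negative importance and, if any were removed,
   retrain once and remove negatives again;
6. re-enter every removed covariate with importance 0 so all locations
   share a complete LVI vector;
7. extract the OOB prediction at i and neighborhood-level OOB accuracy.

Per-location RNG substreams are derived from the master seed and the
location index, so serial and parallel execution orders agree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from forestdrivers import rf
from forestdrivers.dataset import SpatialDataset
from forestdrivers.errors import UnfittableLocationError, ValidationError
from forestdrivers.weights import KernelSpec, pairwise_distances, weight_vector

logger = logging.getLogger(__name__)

__all__ = [
    "GwrfConfig",
    "LocalModelResult",
    "GwrfResult",
    "reclassify_rates",
    "clean_local_dataset",
    "fit_local_model",
    "fit_gwrf",
    "bandwidth_sweep",
]


@dataclass(frozen=True)
class GwrfConfig:
    """Configuration of one GWRF run."""

    dep: str
    kernel: KernelSpec = field(default_factory=KernelSpec)
    task: str = "classification"
    n_trees: int = 500
    mtry: int | None = None
    upsample: bool = True
    seed: int = 0
    normalize_inverted: tuple[str, ...] = ()
    importance_repeats: int = 1

    def __post_init__(self) -> None:
        if self.task not in ("classification", "regression"):
            raise ValidationError(f"unknown task {self.task!r}")
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")


@dataclass
class LocalModelResult:
    """Outputs of one location's local forest."""

    location: int
    lvi: dict[str, float]
    prediction: object
    probabilities: dict | None
    accuracy: rf.AccuracyMetrics | None
    variables_removed: list[str]
    skipped: bool = False
    skip_reason: str | None = None


@dataclass
class GwrfResult:
    """Merged LVI / YHAT / ACC surfaces, one row per location."""

    table: pd.DataFrame
    config: GwrfConfig
    covariates: list[str]
    n_skipped: int

    def lvi_columns(self) -> list[str]:
        return [f"LVI_{v}" for v in self.covariates]

    def lvi_matrix(self) -> pd.DataFrame:
        """Locations x covariates LVI table (complete: zeros for removed)."""
        out = self.table[self.lvi_columns()].copy()
        out.columns = self.covariates
        return out

    def rasterize(self, grid, column: str):
        """One output column as a raster on the analysis grid.

        Location ids must be the grid's row-major cell ids; cells without
        a (numeric) value come back NaN.
        """
        from forestdrivers.grid import Raster

        data = np.full(grid.n_cells, np.nan)
        ids = self.table["id"].to_numpy()
        vals = pd.to_numeric(self.table[column], errors="coerce").to_numpy()
        inside = (ids >= 0) & (ids < grid.n_cells)
        data[ids[inside].astype(int)] = vals[inside]
        return Raster(
            data.reshape(grid.n_rows, grid.n_cols),
            x_origin=grid.x_origin,
            y_origin=grid.y_origin,
            cell_size=grid.cell_size,
            crs=grid.crs,
        )


# ---------------------------------------------------------------------------
# rate reclassification
# ---------------------------------------------------------------------------

def reclassify_rates(
    rates,
    n_classes: int = 5,
    scheme: str = "quantile",
    breaks=None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Discretize continuous change rates into ordered classes 1..n.

    ``quantile`` places equal-count breaks; ``fixed`` uses caller-supplied
    left edges (half-open intervals, the last unbounded above). Returns the
    class vector and a break table recording the interval of each class.
    """
    rates = np.asarray(rates, dtype=float)
    if not np.isfinite(rates).all():
        raise ValidationError("rates must be finite")
    if n_classes < 2:
        raise ValidationError("n_classes must be >= 2")
    if scheme == "fixed":
        if breaks is None:
            raise ValidationError("fixed scheme requires explicit breaks")
        edges = np.asarray(sorted(breaks), dtype=float)
        classes = np.searchsorted(edges, rates, side="right")
        if (classes == 0).any():
            raise ValidationError("rate below the lowest fixed break")
        uppers = np.append(edges[1:], np.inf)
        table = pd.DataFrame(
            {"class": np.arange(1, edges.size + 1), "lower": edges, "upper": uppers}
        )
        return classes.astype(int), table
    if scheme != "quantile":
        raise ValidationError(f"unknown reclassification scheme {scheme!r}")
    if np.unique(rates).size < n_classes:
        raise ValidationError(
            f"only {np.unique(rates).size} distinct rate values; "
            f"use fewer than {n_classes} classes"
        )
    qs = np.quantile(rates, np.linspace(0, 1, n_classes + 1))
    if np.unique(qs).size < qs.size:
        raise ValidationError(
            "duplicate quantile breaks (heavily tied rates); use fewer classes "
            "or fixed breaks"
        )
    classes = np.clip(np.searchsorted(qs, rates, side="right"), 1, n_classes)
    table = pd.DataFrame(
        {"class": np.arange(1, n_classes + 1), "lower": qs[:-1], "upper": qs[1:]}
    )
    return classes.astype(int), table


# ---------------------------------------------------------------------------
# local data cleaning
# ---------------------------------------------------------------------------

def clean_local_dataset(
    X: pd.DataFrame,
    y: np.ndarray,
    weights: np.ndarray,
    task: str,
    upsample: bool = True,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, list[str], np.ndarray]:
    """Local preprocessing: drop zero-variance covariates, balance classes.

    For classification with ``upsample``, minority classes are resampled
    with replacement up to the local majority count (seeded through
    ``rng``); resampled rows carry their original kernel weights.

    Returns (X, y, weights, dropped covariate names, row_order) where
    ``row_order`` maps each output row back to its source row in the input
    (identity unless upsampling duplicated rows). Raises
    :class:`UnfittableLocationError` when the dependent variable is
    single-valued in a classification neighborhood.
    """
    if len(X) < 2:
        raise UnfittableLocationError("fewer than 2 local observations")
    y = np.asarray(y)
    weights = np.asarray(weights, dtype=float)
    values = X.to_numpy(dtype=float)
    keep = values.std(axis=0) > 0
    dropped = [c for c, k in zip(X.columns, keep) if not k]
    X = X.loc[:, keep.tolist()]
    order = np.arange(len(X))

    if task == "classification":
        labels, counts = np.unique(y, return_counts=True)
        if labels.size < 2:
            raise UnfittableLocationError(
                f"dependent variable single-valued ({labels[0]!r}) in neighborhood"
            )
        if upsample and counts.min() < counts.max():
            rng = np.random.default_rng() if rng is None else rng
            majority = counts.max()
            parts = []
            for lab, cnt in zip(labels, counts):
                rows = np.flatnonzero(y == lab)
                if cnt < majority:
                    extra = rng.choice(rows, size=majority - cnt, replace=True)
                    rows = np.concatenate([rows, extra])
                parts.append(rows)
            order = np.concatenate(parts)
            X = X.iloc[order].reset_index(drop=True)
            y = y[order]
            weights = weights[order]
    return X, y, weights, dropped, order


# ---------------------------------------------------------------------------
# local model fitting
# ---------------------------------------------------------------------------

def _location_rng(master_seed: int, location: int) -> np.random.Generator:
    # independent per-location substream: serial/parallel orders agree
    return np.random.default_rng(np.random.SeedSequence([master_seed, location]))


def fit_local_model(
    i: int,
    dataset: SpatialDataset,
    config: GwrfConfig,
    dists_from_i: np.ndarray | None = None,
) -> LocalModelResult:
    """Fit the local forest at location index ``i`` and extract outputs."""
    covariates = dataset.covariates(config.dep)
    if dists_from_i is None:
        coords = dataset.coords
        dists_from_i = np.sqrt(((coords - coords[i]) ** 2).sum(axis=1))
    wv = weight_vector(i, dists_from_i, config.kernel)
    local = dataset.subset(wv.neighbor_ids)
    # positional row of the target inside its own neighborhood
    in_nbhd = np.flatnonzero(wv.neighbor_ids == i)
    source_target = int(in_nbhd[0]) if in_nbhd.size else None

    rng = _location_rng(config.seed, i)
    y = local[config.dep].to_numpy()
    if config.task == "classification":
        y = y.astype(str) if y.dtype == object else y
    try:
        X, y, w, dropped, row_order = clean_local_dataset(
            local[covariates], y, wv.weights, config.task,
            upsample=config.upsample, rng=rng,
        )
    except UnfittableLocationError as exc:
        logger.info("location %s skipped: %s", i, exc)
        return LocalModelResult(
            location=i,
            lvi={v: 0.0 for v in covariates},
            prediction=None,
            probabilities=None,
            accuracy=None,
            variables_removed=list(covariates),
            skipped=True,
            skip_reason=str(exc),
        )

    removed = list(dropped)
    active = list(X.columns)
    lvi = {v: 0.0 for v in covariates}

    def _train(cols):
        seed_b = int(rng.integers(0, 2**31 - 1))
        model = rf.train_forest(
            X[cols].to_numpy(dtype=float),
            y,
            case_weights=w,
            n_trees=config.n_trees,
            mtry=config.mtry,
            task=config.task,
            seed=seed_b,
            feature_names=cols,
            groups=row_order,
        )
        imp = rf.permutation_importance(
            model,
            seed=int(rng.integers(0, 2**31 - 1)),
            n_repeats=config.importance_repeats,
        )
        return model, imp

    if not active:
        return LocalModelResult(
            location=i, lvi=lvi, prediction=None, probabilities=None,
            accuracy=None, variables_removed=removed, skipped=True,
            skip_reason="all covariates have zero local variance",
        )

    model, imp = _train(active)
    negative = [v for v, s in zip(active, imp) if s < 0]
    if negative:
        # at most one retraining pass after negative-importance elimination
        removed += negative
        active = [v for v in active if v not in negative]
        if active:
            model, imp = _train(active)
            negative = [v for v, s in zip(active, imp) if s < 0]
            removed += negative
            keep = [v for v in active if v not in negative]
            for v, s in zip(active, imp):
                if v in keep:
                    lvi[v] = float(s)
            active = keep
        else:
            model = None
    else:
        for v, s in zip(active, imp):
            lvi[v] = float(s)

    if model is None:
        return LocalModelResult(
            location=i, lvi={v: 0.0 for v in covariates}, prediction=None,
            probabilities=None, accuracy=None, variables_removed=removed,
            skipped=True, skip_reason="all covariates removed by importance cleaning",
        )

    oob = rf.oob_predict(model)
    acc = rf.accuracy_metrics(model, oob)

    # rows of the (possibly upsampled) training table holding the target
    target_rows = (
        np.flatnonzero(row_order == source_target)
        if source_target is not None
        else np.array([], dtype=int)
    )
    prediction, probabilities = None, None
    valid_targets = target_rows[oob.valid[target_rows]] if target_rows.size else target_rows
    if valid_targets.size:
        r = int(valid_targets[0])
        prediction = oob.predictions[r]
        if model.task == "classification":
            probabilities = {
                str(c): float(p)
                for c, p in zip(model.classes, oob.probabilities[r])
            }
    elif target_rows.size:
        # target never OOB in any tree: fall back to the full-forest vote/mean
        x_i = X.iloc[[int(target_rows[0])]][model.feature_names].to_numpy(dtype=float)
        if model.task == "classification":
            votes = np.zeros(len(model.classes), dtype=float)
            for tree in model.trees:
                votes[np.searchsorted(model.classes, tree.predict(x_i))[0]] += 1
            votes /= votes.sum()
            prediction = model.classes[int(np.argmax(votes))]
            probabilities = {str(c): float(p) for c, p in zip(model.classes, votes)}
        else:
            prediction = float(np.mean([tree.predict(x_i)[0] for tree in model.trees]))
    return LocalModelResult(
        location=i,
        lvi=lvi,
        prediction=prediction,
        probabilities=probabilities,
        accuracy=acc,
        variables_removed=removed,
    )


# ---------------------------------------------------------------------------
# whole-surface fitting
# ---------------------------------------------------------------------------

def fit_gwrf(dataset: SpatialDataset, config: GwrfConfig) -> GwrfResult:
    """Fit one local forest per location and merge the output surfaces."""
    n = len(dataset)
    if config.kernel.kernel_type == "adaptive" and config.kernel.bandwidth > n:
        raise ValidationError(
            f"adaptive bandwidth {config.kernel.bandwidth} exceeds dataset size {n}"
        )
    if config.normalize_inverted:
        dataset = dataset.normalize_inverted(list(config.normalize_inverted))
    covariates = dataset.covariates(config.dep)
    dists = pairwise_distances(dataset.coords, dataset.ids)

    records = []
    classes_seen: list = []
    n_skipped = 0
    for i in range(n):
        res = fit_local_model(i, dataset, config, dists_from_i=dists[i])
        if res.skipped:
            n_skipped += 1
        rec = {
            "id": dataset.ids[i],
            "x": dataset.coords[i, 0],
            "y": dataset.coords[i, 1],
            "skipped": res.skipped,
            "skip_reason": res.skip_reason,
            "n_removed": len(res.variables_removed),
        }
        for v in covariates:
            rec[f"LVI_{v}"] = res.lvi[v]
        rec["prediction"] = res.prediction
        if res.probabilities:
            for c, p in res.probabilities.items():
                rec[f"prob_{c}"] = p
            classes_seen.extend(res.probabilities)
        if res.accuracy is not None:
            if config.task == "classification":
                rec["kappa"] = res.accuracy.kappa
                rec["prediction_failure"] = res.accuracy.prediction_failure
            else:
                rec["r_squared"] = res.accuracy.r_squared
                rec["residual_standard_error"] = res.accuracy.residual_standard_error
        records.append(rec)

    table = pd.DataFrame.from_records(records)
    prob_cols = sorted(c for c in table.columns if c.startswith("prob_"))
    ordered = [c for c in table.columns if not c.startswith("prob_")] + prob_cols
    return GwrfResult(
        table=table[ordered], config=config, covariates=covariates,
        n_skipped=n_skipped,
    )


def bandwidth_sweep(
    dataset: SpatialDataset,
    config: GwrfConfig,
    bw_grid=(100, 200, 300, 400, 500, 600, 700, 800),
) -> pd.DataFrame:
    """Refit the GWRF over a grid of adaptive bandwidths.

    Summarizes the location-level primary accuracy metric (kappa for
    classification, R-squared for regression) per bandwidth, and marks the
    recommended bandwidth: the smallest whose mean metric lies within one
    standard deviation of the best mean.
    """
    bw_grid = list(bw_grid)
    if not bw_grid:
        raise ValidationError("bandwidth grid is empty")
    if max(bw_grid) > len(dataset):
        raise ValidationError(
            f"largest bandwidth {max(bw_grid)} exceeds dataset size {len(dataset)}"
        )
    metric = "kappa" if config.task == "classification" else "r_squared"
    rows = []
    for bw in bw_grid:
        cfg = replace(config, kernel=replace(config.kernel, bandwidth=bw))
        result = fit_gwrf(dataset, cfg)
        vals = result.table.loc[~result.table["skipped"], metric].dropna()
        rows.append(
            {
                "bw": bw,
                "metric": metric,
                "mean": float(vals.mean()) if len(vals) else np.nan,
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                "n_locations": int(len(vals)),
            }
        )
    out = pd.DataFrame(rows).sort_values("bw").reset_index(drop=True)
    best = out["mean"].max()
    best_sd = out.loc[out["mean"].idxmax(), "sd"]
    threshold = best - (best_sd if np.isfinite(best_sd) else 0.0)
    out["recommended"] = False
    ok = out.index[out["mean"] >= threshold]
    if len(ok):
        out.loc[ok[0], "recommended"] = True
    return out
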