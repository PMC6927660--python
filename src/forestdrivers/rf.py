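"""Random forest with case-weighted bootstrap sampling.

A bagged CART ensemble (classification or regression) whose bootstrap draws
obey externally supplied per-observation selection probabilities — the hook
that turns spatial kernel weights into sampling probabilities for local
forests. Tree induction is delegated to scikit-learn CART (Gini /
variance-reduction splits, per-node feature subsampling); the weighted
bootstrap, out-of-bag (OOB) aggregation, permutation importance and the
kappa statistic are implemented here and verified independently by the test
suite.

Defaults follow the common ranger-style calibration: 500 trees, mtry =
floor(sqrt(p)) features tried per node, trees grown to full depth
(min leaf 1 for classification, 5 for regression).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from forestdrivers.errors import ValidationError

__all__ = [
    "ForestModel",
    "OobPrediction",
    "AccuracyMetrics",
    "train_forest",
    "oob_predict",
    "accuracy_metrics",
    "permutation_importance",
    "kappa_statistic",
]


@dataclass
class ForestModel:
    """A fitted case-weighted bagged ensemble.

    ``inbag_counts[b, j]`` is how many times observation j was drawn into
    tree b's bootstrap (row sums equal n: sampling with replacement keeps
    the bootstrap size at n). ``oob_mask[b, j]`` is True where no member of
    observation j's source group was drawn for tree b — when rows are
    duplicated upstream (e.g. minority-class upsampling), ``groups`` ties
    the duplicates together so a row is never scored out-of-bag while its
    twin sits in the bag.
    """

    task: str
    trees: list
    inbag_counts: np.ndarray
    oob_mask: np.ndarray
    mtry: int
    X: np.ndarray
    y: np.ndarray
    classes: np.ndarray | None = None
    feature_names: list[str] | None = None
    case_weights: np.ndarray | None = None

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    def summary(self, include_oob_indices: bool = False) -> dict:
        """JSON-serializable model summary."""
        out = {
            "task": self.task,
            "n_trees": self.n_trees,
            "n_obs": self.n_obs,
            "mtry": self.mtry,
            "feature_names": self.feature_names,
        }
        if self.classes is not None:
            out["classes"] = [str(c) for c in self.classes]
        if include_oob_indices:
            out["oob_indices"] = [
                np.flatnonzero(row).tolist() for row in self.oob_mask
            ]
        return out


@dataclass
class OobPrediction:
    """Out-of-bag predictions for every training observation.

    ``valid`` flags observations that were OOB in at least one tree; the
    rest carry NaN predictions and are excluded from accuracy metrics.
    """

    predictions: np.ndarray
    probabilities: np.ndarray | None
    valid: np.ndarray
    n_never_oob: int


@dataclass
class AccuracyMetrics:
    """OOB accuracy summary: kappa + prediction failure for classification,
    R-squared + residual standard error for regression."""

    kappa: float | None = None
    prediction_failure: float | None = None
    r_squared: float | None = None
    residual_standard_error: float | None = None

    def primary(self, task: str) -> float:
        return self.kappa if task == "classification" else self.r_squared


def _validate_inputs(X, y, case_weights, task):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValidationError("X must be a 2-D covariate table")
    n = X.shape[0]
    if n != y.shape[0]:
        raise ValidationError(f"X has {n} rows but y has {y.shape[0]}")
    if n < 2:
        raise ValidationError("at least 2 observations are required")
    if task not in ("classification", "regression"):
        raise ValidationError(f"unknown task {task!r}")
    if task == "regression":
        y = y.astype(float)
        if np.ptp(y) == 0:
            raise ValidationError("constant response: regression forest undefined")
    if case_weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(case_weights, dtype=float)
        if w.shape[0] != n:
            raise ValidationError("case_weights length must match observations")
        if (w < 0).any():
            raise ValidationError("case_weights must be nonnegative")
        total = w.sum()
        if total <= 0:
            raise ValidationError("case_weights must not be all zero")
        w = w / total
    return X, y, w


def train_forest(
    X,
    y,
    case_weights=None,
    n_trees: int = 500,
    mtry: int | None = None,
    task: str = "classification",
    seed: int | None = None,
    feature_names: list[str] | None = None,
    groups: np.ndarray | None = None,
) -> ForestModel:
    """Fit a bagged CART ensemble with case-weighted bootstrap sampling.

    Each tree's bootstrap of size n is drawn with replacement with
    per-observation selection probability proportional to ``case_weights``
    (uniform weights recover a standard random forest). Trees are grown
    unpruned; ``mtry`` features are tried at each node. ``groups`` marks
    rows that are duplicates of a common source observation, keeping the
    out-of-bag bookkeeping honest under class upsampling.
    """
    X, y, w = _validate_inputs(X, y, case_weights, task)
    n, p = X.shape
    if groups is not None:
        groups = np.asarray(groups)
        if groups.shape[0] != n:
            raise ValidationError("groups length must match observations")
    if mtry is None:
        mtry = max(1, int(np.floor(np.sqrt(p))))
    mtry = min(mtry, p)
    rng = np.random.default_rng(seed)

    classes = np.unique(y) if task == "classification" else None
    trees = []
    inbag = np.zeros((n_trees, n), dtype=np.int32)
    for b in range(n_trees):
        idx = rng.choice(n, size=n, replace=True, p=w)
        inbag[b] = np.bincount(idx, minlength=n)
        rs = int(rng.integers(0, 2**31 - 1))
        if task == "classification":
            tree = DecisionTreeClassifier(
                max_features=mtry, min_samples_leaf=1, random_state=rs
            )
        else:
            tree = DecisionTreeRegressor(
                max_features=mtry, min_samples_leaf=5, random_state=rs
            )
        tree.fit(X[idx], y[idx])
        trees.append(tree)

    if groups is None:
        oob_mask = inbag == 0
    else:
        # a row is OOB only when its whole source group stayed out of the bag
        labels, inv = np.unique(groups, return_inverse=True)
        group_inbag = np.zeros((n_trees, labels.size), dtype=np.int64)
        for b in range(n_trees):
            np.add.at(group_inbag[b], inv, inbag[b])
        oob_mask = group_inbag[:, inv] == 0

    return ForestModel(
        task=task,
        trees=trees,
        inbag_counts=inbag,
        oob_mask=oob_mask,
        mtry=mtry,
        X=X,
        y=y,
        classes=classes,
        feature_names=feature_names,
        case_weights=w,
    )


def oob_predict(model: ForestModel) -> OobPrediction:
    """Out-of-bag prediction for every training observation.

    Classification: per-class vote fractions over the trees for which the
    observation was OOB (summing to 1) and the majority label. Regression:
    the mean of OOB-tree predictions. Observations never OOB are flagged
    and excluded.
    """
    n = model.n_obs
    if model.task == "classification":
        k = len(model.classes)
        votes = np.zeros((n, k))
        for tree, oob in zip(model.trees, model.oob_mask):
            rows = np.flatnonzero(oob)
            if rows.size == 0:
                continue
            pred = tree.predict(model.X[rows])
            # model.classes comes from np.unique, hence sorted
            np.add.at(votes, (rows, np.searchsorted(model.classes, pred)), 1)
        totals = votes.sum(axis=1)
        valid = totals > 0
        probs = np.full((n, k), np.nan)
        probs[valid] = votes[valid] / totals[valid, None]
        pred_idx = np.argmax(np.where(np.isnan(probs), -1, probs), axis=1)
        predictions = model.classes[pred_idx].astype(model.y.dtype)
        return OobPrediction(predictions, probs, valid, int((~valid).sum()))

    sums = np.zeros(n)
    counts = np.zeros(n)
    for tree, oob in zip(model.trees, model.oob_mask):
        rows = np.flatnonzero(oob)
        if rows.size == 0:
            continue
        sums[rows] += tree.predict(model.X[rows])
        counts[rows] += 1
    valid = counts > 0
    predictions = np.full(n, np.nan)
    predictions[valid] = sums[valid] / counts[valid]
    return OobPrediction(predictions, None, valid, int((~valid).sum()))


def accuracy_metrics(model: ForestModel, oob: OobPrediction | None = None) -> AccuracyMetrics:
    """OOB accuracy metrics. Observations never OOB are excluded."""
    if oob is None:
        oob = oob_predict(model)
    v = oob.valid
    if v.sum() == 0:
        return AccuracyMetrics()
    y, yhat = model.y[v], oob.predictions[v]
    if model.task == "classification":
        kappa = kappa_statistic(y, yhat)
        failure = float(np.mean(y != yhat))
        return AccuracyMetrics(kappa=kappa, prediction_failure=failure)
    resid = y - yhat
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    dof = max(v.sum() - 1, 1)
    rse = float(np.sqrt(ss_res / dof))
    return AccuracyMetrics(r_squared=r2, residual_standard_error=rse)


def _tree_oob_error(tree, X, y, task):
    pred = tree.predict(X)
    if task == "classification":
        return np.mean(pred != y)
    return np.mean((pred - y) ** 2)


def permutation_importance(
    model: ForestModel,
    X: np.ndarray | None = None,
    y: np.ndarray | None = None,
    seed: int | None = None,
    n_repeats: int = 1,
) -> np.ndarray:
    """OOB permutation importance per covariate.

    For each tree, the OOB error is recomputed with one covariate column
    permuted among the tree's OOB rows; the importance of a covariate is
    the mean over trees (and repeats) of the error increase. Values can be
    negative when a covariate is pure noise.
    """
    X = model.X if X is None else np.asarray(X, dtype=float)
    y = model.y if y is None else np.asarray(y)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    deltas = np.zeros((model.n_trees, p))
    used = np.zeros(model.n_trees, dtype=bool)
    for b, (tree, oob) in enumerate(zip(model.trees, model.oob_mask)):
        rows = np.flatnonzero(oob)
        m = rows.size
        if m < 2:
            continue
        used[b] = True
        X_oob, y_oob = X[rows], y[rows]
        base = _tree_oob_error(tree, X_oob, y_oob, model.task)
        for _ in range(n_repeats):
            # one stacked predict call covering all p permuted versions
            stacked = np.repeat(X_oob[None, :, :], p, axis=0)
            for k in range(p):
                stacked[k, :, k] = X_oob[rng.permutation(m), k]
            preds = tree.predict(stacked.reshape(p * m, p)).reshape(p, m)
            if model.task == "classification":
                errs = (preds != y_oob[None, :]).mean(axis=1)
            else:
                errs = ((preds - y_oob[None, :]) ** 2).mean(axis=1)
            deltas[b] += (errs - base) / n_repeats
    if not used.any():
        raise ValidationError("no tree has enough OOB rows for importance")
    return deltas[used].mean(axis=0)


def kappa_statistic(y_true, y_pred) -> float:
    """Cohen's kappa: chance-corrected agreement between two labelings.

    kappa = (p_o - p_e) / (1 - p_e), with expected agreement p_e from the
    product of the marginal label frequencies. When both labelings place
    everything in one shared class (p_e = 1, perfect agreement) kappa is
    defined as 1.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred must have equal length")
    labels = np.unique(np.concatenate([y_true, y_pred]))
    pos = {c: j for j, c in enumerate(labels)}
    k = len(labels)
    conf = np.zeros((k, k))
    for t, pr in zip(y_true, y_pred):
        conf[pos[t], pos[pr]] += 1
    conf /= conf.sum()
    p_o = np.trace(conf)
    p_e = float(conf.sum(axis=1) @ conf.sum(axis=0))
    if np.isclose(p_e, 1.0):
        return 1.0
    return float((p_o - p_e) / (1.0 - p_e))
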