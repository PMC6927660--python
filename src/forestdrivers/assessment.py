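"""Cluster-and-test assessment of forest-dynamics drivers.

The LVI surfaces from two GWRF runs (a deforestation-like and a
reforestation-like dependent variable) are each clustered with a Gaussian
mixture fitted by expectation-maximization; the number of clusters is
chosen by the gap statistic against uniform reference draws, and the
cluster with the highest mean dependent rate is selected as the active
forest-change front. Per variable, the two selected clusters are then
compared with the two-sided Wilcoxon rank-sum test and Cliff's delta
effect size, and categorized as *equal* (no significant difference),
*greater* or *lower* (by the sign of the median difference).

Cliff's delta magnitude labels use the published Romano cut-offs:
negligible |d| < 0.147, small < 0.33, medium < 0.474, large otherwise.
No multiple-testing correction is applied by default (a documented
limitation); Holm correction is selectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from forestdrivers.errors import ValidationError

__all__ = [
    "ClusterResult",
    "cluster_lvi",
    "wilcoxon_rank_sum",
    "cliffs_delta",
    "delta_magnitude",
    "categorize_variables",
    "hypothesis_table",
    "split_hypothesis_table",
]

ROMANO_THRESHOLDS = (0.147, 0.33, 0.474)
MAGNITUDES = ("negligible", "small", "medium", "large")


@dataclass
class ClusterResult:
    """EM clustering of an LVI surface with gap-statistic model selection."""

    labels: np.ndarray
    k: int
    gap_curve: pd.DataFrame
    selected_cluster: int
    cluster_summary: pd.DataFrame

    def selected_mask(self) -> np.ndarray:
        return self.labels == self.selected_cluster


def _within_dispersion(X: np.ndarray, labels: np.ndarray) -> float:
    """Total within-cluster sum of squared distances to cluster means."""
    w = 0.0
    for lab in np.unique(labels):
        block = X[labels == lab]
        w += float(((block - block.mean(axis=0)) ** 2).sum())
    return w


def _fit_gmm(X: np.ndarray, k: int, seed: int, max_restarts: int = 5) -> GaussianMixture:
    last_exc = None
    for attempt in range(max_restarts):
        gmm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            reg_covar=1e-6,
            random_state=seed + attempt,
            n_init=1,
            max_iter=500,
        )
        try:
            gmm.fit(X)
        except Exception as exc:  # numerical failure counts as non-convergence
            last_exc = exc
            continue
        if gmm.converged_:
            return gmm
    raise ValidationError(
        f"EM did not converge for k={k} after {max_restarts} restarts"
        + (f" (last error: {last_exc})" if last_exc else "")
    )


def gap_statistic(
    X: np.ndarray,
    k_max: int = 6,
    n_ref: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Gap statistic over k = 1..k_max with uniform reference draws.

    Gap(k) = E*[log W_k] - log W_k, where W_k is the within-cluster
    dispersion and the expectation is over ``n_ref`` datasets drawn
    uniformly over the observed feature ranges. ``sk`` carries the
    simulation-corrected standard error.
    """
    rng = np.random.default_rng(seed)
    n, p = X.shape
    lo, hi = X.min(axis=0), X.max(axis=0)
    eps = 1e-12
    rows = []
    refs = [rng.uniform(lo, hi, size=(n, p)) for _ in range(n_ref)]
    for k in range(1, k_max + 1):
        gmm = _fit_gmm(X, k, seed=int(rng.integers(0, 2**31 - 1)))
        log_w = np.log(_within_dispersion(X, gmm.predict(X)) + eps)
        log_w_ref = []
        for ref in refs:
            gmm_ref = _fit_gmm(ref, k, seed=int(rng.integers(0, 2**31 - 1)))
            log_w_ref.append(np.log(_within_dispersion(ref, gmm_ref.predict(ref)) + eps))
        log_w_ref = np.asarray(log_w_ref)
        gap = float(log_w_ref.mean() - log_w)
        sk = float(log_w_ref.std(ddof=0) * np.sqrt(1.0 + 1.0 / n_ref))
        rows.append({"k": k, "gap": gap, "sk": sk, "log_w": float(log_w)})
    return pd.DataFrame(rows)


def _choose_k(gap_curve: pd.DataFrame) -> int:
    """Smallest k with Gap(k) >= Gap(k+1) - s(k+1) (first local maximum)."""
    gaps = gap_curve["gap"].to_numpy()
    sks = gap_curve["sk"].to_numpy()
    for j in range(len(gaps) - 1):
        if gaps[j] >= gaps[j + 1] - sks[j + 1]:
            return int(gap_curve["k"].iloc[j])
    return int(gap_curve["k"].iloc[-1])


def cluster_lvi(
    lvi: pd.DataFrame,
    rates: np.ndarray,
    k: int | None = None,
    k_max: int = 6,
    n_ref: int = 50,
    seed: int = 0,
    standardize: bool = False,
    cell_area_ha: float = 400.0,
) -> ClusterResult:
    """Cluster LVI vectors with EM and select the active-front cluster.

    LVI vectors must be complete (removed variables present as zeros).
    With ``k`` unspecified, the gap statistic picks it over 1..``k_max``.
    The cluster with the highest mean dependent rate is marked selected;
    rates of deforestation-style variables should be passed as absolute
    values by the caller when that is the reporting convention.
    """
    X = np.asarray(lvi, dtype=float)
    if not np.isfinite(X).all():
        raise ValidationError("LVI matrix contains non-finite values")
    rates = np.asarray(rates, dtype=float)
    if rates.shape[0] != X.shape[0]:
        raise ValidationError("rates must align with LVI rows")
    if standardize:
        sd = X.std(axis=0)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)

    degenerate = bool((X.std(axis=0) == 0).all())
    if degenerate:
        # identical rows: a single cluster, no meaningful gap curve
        gap_curve = pd.DataFrame({"k": [1], "gap": [0.0], "sk": [0.0], "log_w": [-np.inf]})
        chosen = 1
        labels = np.zeros(X.shape[0], dtype=int)
    else:
        gap_curve = gap_statistic(X, k_max=k_max, n_ref=n_ref, seed=seed)
        chosen = int(k) if k is not None else _choose_k(gap_curve)
        labels = _fit_gmm(X, chosen, seed=seed).predict(X)

    rows = []
    for lab in np.unique(labels):
        sel = labels == lab
        rows.append(
            {
                "cluster": int(lab),
                "n_cells": int(sel.sum()),
                "area_ha": float(sel.sum() * cell_area_ha),
                "rate_mean": float(np.nanmean(rates[sel])),
                "rate_sd": float(np.nanstd(rates[sel], ddof=1)) if sel.sum() > 1 else np.nan,
            }
        )
    summary = pd.DataFrame(rows)
    selected = int(summary.loc[summary["rate_mean"].idxmax(), "cluster"])
    return ClusterResult(
        labels=labels,
        k=chosen,
        gap_curve=gap_curve,
        selected_cluster=selected,
        cluster_summary=summary,
    )


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact distribution for n + m <= 20 without ties; normal approximation
    with continuity and tie correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be nonempty")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    small = x.size + y.size <= 20
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(min(res.pvalue, 1.0))


def cliffs_delta(x, y) -> tuple[float, str]:
    """Cliff's delta d = (#{x>y} - #{x<y}) / (n m), with Romano magnitude.

    The dominance statistic of two samples: +1 when every x exceeds every
    y, -1 in the opposite case, 0 under complete overlap. Invariant under
    strictly monotone transforms of both samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be nonempty")
    ys = np.sort(y)
    # for each x: #(y < x) and #(y <= x) via binary search on sorted y
    n_less = np.searchsorted(ys, x, side="left")
    n_less_eq = np.searchsorted(ys, x, side="right")
    greater = int(n_less.sum())
    lower = int((ys.size - n_less_eq).sum())
    d = (greater - lower) / (x.size * y.size)
    return float(d), delta_magnitude(d)


def delta_magnitude(d: float) -> str:
    """Romano magnitude label of |d|: 0.147 / 0.33 / 0.474 cut-offs."""
    a = abs(d)
    for thr, label in zip(ROMANO_THRESHOLDS, MAGNITUDES):
        if a < thr:
            return label
    return MAGNITUDES[-1]


def _stars(p: float) -> str:
    # reporting convention of the driver tables: *** significant (p < 0.05),
    # ** marginal (p < 0.1), * not significant
    if p < 0.05:
        return "***"
    if p < 0.1:
        return "**"
    return "*"


def categorize_variables(group1, group2, alpha: float = 0.05) -> dict:
    """Compare one variable between two clusters and categorize it.

    Null hypothesis: the two clusters share a distribution. p >= alpha (or
    a zero median difference) gives *equal*; otherwise the sign of
    (median1 - median2) gives *greater* or *lower*.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    p = wilcoxon_rank_sum(g1, g2)
    med1, med2 = float(np.median(g1)), float(np.median(g2))
    diff = med1 - med2
    d, magnitude = cliffs_delta(g1, g2)
    if p >= alpha or diff == 0:
        category = "equal"
    elif diff > 0:
        category = "greater"
    else:
        category = "lower"
    return {
        "median_1": med1,
        "median_2": med2,
        "diff": diff,
        "p": p,
        "stars": _stars(p),
        "delta": d,
        "magnitude": magnitude,
        "category": category,
    }


def hypothesis_table(
    group1: pd.DataFrame,
    group2: pd.DataFrame,
    variables: list[str] | None = None,
    alpha: float = 0.05,
    holm: bool = False,
) -> pd.DataFrame:
    """Per-variable cluster comparison table.

    ``group1`` / ``group2`` hold the variable values of the two selected
    clusters (rows = cells). With ``holm`` the p-values are Holm-adjusted
    before categorization (off by default).
    """
    if variables is None:
        variables = [v for v in group1.columns if v in group2.columns]
    if not variables:
        raise ValidationError("no shared variables to compare")
    rows = [
        {"variable": v, **categorize_variables(group1[v], group2[v], alpha=alpha)}
        for v in variables
    ]
    out = pd.DataFrame(rows)
    if holm:
        order = np.argsort(out["p"].to_numpy())
        m = len(out)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * out["p"].iloc[idx])
            adj[idx] = min(running, 1.0)
        out["p_holm"] = adj
        recat = []
        for _, rec in out.iterrows():
            if rec["p_holm"] >= alpha or rec["diff"] == 0:
                recat.append("equal")
            else:
                recat.append("greater" if rec["diff"] > 0 else "lower")
        out["category"] = recat
    return out


def split_hypothesis_table(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Split the comparison table into equal / greater / lower tables."""
    return {
        cat: table[table["category"] == cat].reset_index(drop=True)
        for cat in ("equal", "greater", "lower")
    }
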