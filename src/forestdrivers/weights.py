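"""Spatial kernel weights for geographically weighted models.

Distances are Euclidean on projected coordinates. The kernel is exponential,
``w = exp(-d / bw)``, with either an *adaptive* bandwidth (a neighbor count:
each location uses its K nearest observations, and the kernel's distance
scale is the distance to the K-th nearest neighbor, the GWmodel convention)
or a *fixed* bandwidth (a constant distance in meters).

The target observation is always part of its own neighborhood with weight 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from forestdrivers.errors import ValidationError

__all__ = [
    "KernelSpec",
    "WeightVector",
    "pairwise_distances",
    "select_neighbors",
    "exponential_weights",
    "weight_vector",
]


@dataclass(frozen=True)
class KernelSpec:
    """Kernel configuration.

    ``bandwidth`` is a neighbor count (integer >= 2) for the adaptive
    kernel, or a distance in meters (> 0) for the fixed kernel.
    """

    kernel_type: str = "adaptive"
    bandwidth: float = 100
    kernel_function: str = "exponential"

    def __post_init__(self) -> None:
        if self.kernel_type not in ("adaptive", "fixed"):
            raise ValidationError(
                f"kernel_type must be 'adaptive' or 'fixed', got {self.kernel_type!r}"
            )
        if self.kernel_function != "exponential":
            raise ValidationError(
                "only the exponential kernel is implemented "
                f"(got {self.kernel_function!r})"
            )
        if self.kernel_type == "adaptive":
            if self.bandwidth != int(self.bandwidth) or self.bandwidth < 2:
                raise ValidationError(
                    "adaptive bandwidth is a neighbor count and must be an "
                    f"integer >= 2 (got {self.bandwidth})"
                )
        elif self.bandwidth <= 0:
            raise ValidationError("fixed bandwidth must be a positive distance")


@dataclass
class WeightVector:
    """Kernel weights of one location's neighborhood."""

    target: int
    neighbor_ids: np.ndarray
    distances: np.ndarray
    weights: np.ndarray
    local_bandwidth: float

    def to_frame(self) -> pd.DataFrame:
        """Audit table with one row per (target, neighbor) pair."""
        return pd.DataFrame(
            {
                "i": self.target,
                "j": self.neighbor_ids,
                "distance": self.distances,
                "weight": self.weights,
            }
        )


def pairwise_distances(points: np.ndarray, ids: np.ndarray | None = None) -> np.ndarray:
    """Symmetric Euclidean distance matrix over projected coordinates.

    Raises a validation error naming the offending observation if any
    coordinate is non-finite.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError(f"expected (n, 2) coordinates, got shape {pts.shape}")
    finite = np.isfinite(pts).all(axis=1)
    if not finite.all():
        bad = int(np.flatnonzero(~finite)[0])
        label = ids[bad] if ids is not None else bad
        raise ValidationError(f"non-finite coordinate for observation id {label!r}")
    return cdist(pts, pts)


def select_neighbors(
    dists_from_i: np.ndarray, spec: KernelSpec
) -> tuple[np.ndarray, float]:
    """Select the neighborhood of one location and its bandwidth distance.

    Adaptive kernel: the ``K_bw`` nearest observations (the target itself
    included at distance 0); the local bandwidth is the distance to the
    farthest selected neighbor. Distance ties at the cutoff are broken by
    ascending observation index, so the result is deterministic.

    Fixed kernel: all observations within the bandwidth distance; the local
    bandwidth is the configured distance itself.

    Returns (neighbor positional indices, local bandwidth distance).
    """
    d = np.asarray(dists_from_i, dtype=float)
    n = d.size
    if spec.kernel_type == "adaptive":
        k = int(spec.bandwidth)
        if k > n:
            raise ValidationError(
                f"adaptive bandwidth K_bw={k} exceeds the {n} available "
                "observations; lower the bandwidth"
            )
        # stable sort on (distance, index): ties resolved by ascending index
        order = np.lexsort((np.arange(n), d))
        selected = np.sort(order[:k])
        local_bw = float(d[selected].max())
        return selected, local_bw
    selected = np.flatnonzero(d <= spec.bandwidth)
    return selected, float(spec.bandwidth)


def exponential_weights(distances: np.ndarray, local_bandwidth: float) -> np.ndarray:
    """Exponential decay weights ``w_j = exp(-d_ij / bw)``."""
    if local_bandwidth <= 0:
        raise ValidationError("bandwidth must be positive for the exponential kernel")
    return np.exp(-np.abs(np.asarray(distances, dtype=float)) / local_bandwidth)


def weight_vector(
    i: int, dists_from_i: np.ndarray, spec: KernelSpec
) -> WeightVector:
    """Full kernel-weighting step for one location: select + weight."""
    selected, local_bw = select_neighbors(dists_from_i, spec)
    d = np.asarray(dists_from_i, dtype=float)[selected]
    if local_bw <= 0:
        # all selected neighbors are coincident with the target; uniform weights
        w = np.ones_like(d)
    else:
        w = exponential_weights(d, local_bw)
    return WeightVector(
        target=i,
        neighbor_ids=selected,
        distances=d,
        weights=w,
        local_bandwidth=local_bw,
    )
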