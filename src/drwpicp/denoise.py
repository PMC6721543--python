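"""Statistical outlier removal.

Each point's mean distance to its k nearest neighbours is computed; points
whose mean distance exceeds d_max = mu + alpha * sigma — where mu, sigma are
the mean and (population) standard deviation of those per-point means — are
removed. This assumes the per-point mean distances of surface points are
roughly Gaussian, so isolated outliers land far in the upper tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DegenerateError, PointCloud, build_neighbor_index


@dataclass(frozen=True)
class DenoiseParams:
    """k: neighbour count; alpha: scale factor on the standard deviation.

    Defaults (k=50, alpha=1.0) follow common statistical-outlier-removal
    practice; both are exposed in every config surface.

    ``passes`` is the number of filter applications the fusion pipeline
    performs (:func:`drwpicp.resample.fuse_and_resample`). A single pass is
    blind to heavy contamination — when outliers dominate, they inflate the
    threshold statistics and shield each other — while re-estimating the
    threshold on the survivors peels them off layer by layer.
    :func:`remove_outliers` itself is always one pass.
    """

    k: int = 50
    alpha: float = 1.0
    passes: int = 3

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.passes < 1:
            raise ValueError("passes must be >= 1")


def mean_knn_distance(cloud: PointCloud, k: int) -> np.ndarray:
    """Per-point mean Euclidean distance to the k nearest neighbours,
    excluding the point itself."""
    if k >= len(cloud):
        raise DegenerateError(f"k too large: k={k} with {len(cloud)} points")
    index = build_neighbor_index(cloud)
    d, _ = index.query_knn(cloud.points, k=k + 1)  # first neighbour is self
    return d[:, 1:].mean(axis=1)


def distance_threshold(dbar: np.ndarray, alpha: float) -> float:
    """d_max = mu + alpha * sigma over the per-point mean distances
    (population sigma, divisor N)."""
    dbar = np.asarray(dbar, float)
    if dbar.size == 0:
        raise ValueError("empty distance array")
    return float(dbar.mean() + alpha * dbar.std())


def remove_outliers(cloud: PointCloud,
                    params: DenoiseParams) -> tuple[PointCloud, np.ndarray]:
    """Remove points whose mean-kNN distance is strictly greater than d_max.

    Points exactly at the threshold are kept. Returns the surviving subcloud
    (ids unchanged) and the ids of removed points.
    """
    dbar = mean_knn_distance(cloud, params.k)
    dmax = distance_threshold(dbar, params.alpha)
    keep = dbar <= dmax
    if not keep.any():
        raise DegenerateError("all points removed: pathological alpha")
    return cloud.subset(keep), cloud.ids[~keep]
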