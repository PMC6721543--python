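"""Normal estimation and moving-least-squares (MLS) smoothing/resampling.

The floating surface captured by a depth sensor is noisy; MLS replaces each
point by its projection onto a local weighted polynomial fit of its
neighbourhood, yielding a smoother, more uniform floating set. Two captures
of the same surface can be fused: both are denoised, pooled, smoothed, and
subsampled to a target size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import PointCloud, build_neighbor_index
from .denoise import DenoiseParams, remove_outliers


@dataclass(frozen=True)
class MlsParams:
    """Parameters of the MLS projection.

    search_radius: neighbourhood radius (length units). ``None`` means
        4x the median nearest-neighbour spacing of the input, computed per
        call — a density-adaptive default.
    poly_order: degree of the local bivariate polynomial (1-3).
    knn_for_normals: neighbourhood size for PCA normal estimation.
    viewpoint: point toward which normals are oriented (sensor position).
    """

    search_radius: float | None = None
    poly_order: int = 2
    knn_for_normals: int = 30
    viewpoint: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.search_radius is not None and self.search_radius <= 0:
            raise ValueError("search_radius must be positive")
        if self.poly_order not in (1, 2, 3):
            raise ValueError("poly_order must be 1, 2 or 3")
        if self.knn_for_normals < 3:
            raise ValueError("knn_for_normals must be >= 3")


def median_nn_spacing(cloud: PointCloud) -> float:
    """Median distance from each point to its single nearest neighbour."""
    index = build_neighbor_index(cloud)
    d, _ = index.query_knn(cloud.points, k=2)
    return float(np.median(d[:, 1]))


def estimate_normals(cloud: PointCloud, knn: int,
                     viewpoint=(0.0, 0.0, 0.0)) -> tuple[PointCloud, np.ndarray]:
    """Per-point unit normals from local PCA.

    The normal is the eigenvector of the local covariance matrix with the
    smallest eigenvalue, sign-flipped so it points toward the viewpoint
    (normal . (viewpoint - point) >= 0). Points whose neighbourhood is
    degenerate (all neighbours coincident) get a placeholder normal toward
    the viewpoint and are reported in the returned flagged-id array.
    """
    if knn < 3:
        raise ValueError("knn must be >= 3")
    if len(cloud) <= knn:
        raise ValueError("cloud must have more than knn points")
    viewpoint = np.asarray(viewpoint, float)
    index = build_neighbor_index(cloud)
    _, nbr = index.query_knn(cloud.points, k=knn + 1)

    normals = np.empty_like(cloud.points)
    flagged = []
    for i in range(len(cloud)):
        nbrs = cloud.points[nbr[i]]
        centered = nbrs - nbrs.mean(axis=0)
        cov = centered.T @ centered
        evals, evecs = np.linalg.eigh(cov)
        if evals[-1] <= 1e-24:
            flagged.append(cloud.ids[i])
            direction = viewpoint - cloud.points[i]
            n = np.linalg.norm(direction)
            normals[i] = direction / n if n > 0 else (0.0, 0.0, 1.0)
            continue
        n = evecs[:, 0]  # smallest eigenvalue
        if np.dot(n, viewpoint - cloud.points[i]) < 0:
            n = -n
        normals[i] = n / np.linalg.norm(n)
    out = PointCloud(points=cloud.points.copy(), normals=normals,
                     ids=cloud.ids.copy())
    return out, np.asarray(flagged, dtype=int)


def _poly_terms(u: np.ndarray, v: np.ndarray, order: int) -> np.ndarray:
    """Bivariate monomial design matrix up to total degree ``order``."""
    cols = [np.ones_like(u)]
    for total in range(1, order + 1):
        for j in range(total + 1):
            cols.append(u ** (total - j) * v ** j)
    return np.column_stack(cols)


def mls_project(cloud: PointCloud,
                params: MlsParams) -> tuple[PointCloud, np.ndarray]:
    """Project each point onto the local Gaussian-weighted polynomial fit.

    Neighbours inside ``search_radius`` are expressed in the point's local
    frame (its normal is the height axis); a degree-``poly_order`` bivariate
    polynomial is fitted by least squares with weights exp(-d^2 / r^2), and
    the point moves to the fitted height at its own footprint. Points with
    too few neighbours for the polynomial are passed through unmodified and
    their ids returned as flagged.
    """
    if cloud.normals is None:
        raise ValueError("mls_project requires normals; run estimate_normals")
    radius = params.search_radius
    if radius is None:
        radius = 4.0 * median_nn_spacing(cloud)
    n_terms = (params.poly_order + 1) * (params.poly_order + 2) // 2

    index = build_neighbor_index(cloud)
    neighbor_lists = index._tree.query_ball_point(cloud.points, radius)

    new_points = cloud.points.copy()
    flagged = []
    for i in range(len(cloud)):
        nbrs = np.asarray(neighbor_lists[i], dtype=int)
        if len(nbrs) < n_terms:
            flagged.append(cloud.ids[i])
            continue
        p = cloud.points[i]
        n = cloud.normals[i]
        # local orthonormal frame with n as the height axis
        a = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(a, n)) > 0.9:
            a = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(n, a)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(n, e1)

        rel = cloud.points[nbrs] - p
        u = rel @ e1
        v = rel @ e2
        h = rel @ n
        d2 = np.einsum("ij,ij->i", rel, rel)
        w = np.exp(-d2 / radius ** 2)
        design = _poly_terms(u, v, params.poly_order)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(design * sw[:, None], h * sw, rcond=None)
        new_points[i] = p + coef[0] * n  # fitted height at the footprint
    out = PointCloud(points=new_points, normals=cloud.normals.copy(),
                     ids=cloud.ids.copy())
    return out, np.asarray(flagged, dtype=int)


def fuse_and_resample(f1: PointCloud,
                      f2: PointCloud | None = None,
                      denoise: DenoiseParams = DenoiseParams(),
                      mls: MlsParams = MlsParams(),
                      target_size: int | None = None,
                      rng: np.random.Generator | None = None) -> PointCloud:
    """Fuse one or two captures of a surface into one clean floating set.

    Each capture is denoised, the survivors pooled, normals estimated, MLS
    projection applied, and the result uniformly subsampled to
    ``target_size`` (default: the mean of the input sizes). With ``f2=None``
    this reduces to denoise + MLS of the single capture.
    """
    if rng is None:
        rng = np.random.default_rng(0)

    def _denoise(cloud: PointCloud) -> PointCloud:
        for _ in range(denoise.passes):
            cloud, _ = remove_outliers(cloud, denoise)
        return cloud

    clean1 = _denoise(f1)
    if f2 is not None and len(f2) > 0:
        clean2 = _denoise(f2)
        # re-id the second capture so pooled ids stay unique
        offset = int(clean1.ids.max()) + 1
        pooled = PointCloud(
            points=np.vstack([clean1.points, clean2.points]),
            ids=np.concatenate([clean1.ids, clean2.ids + offset]),
        )
        default_target = (len(f1) + len(f2)) // 2
    else:
        pooled = clean1
        default_target = len(f1)

    with_normals, _ = estimate_normals(pooled, mls.knn_for_normals,
                                       mls.viewpoint)
    smoothed, _ = mls_project(with_normals, mls)

    target = default_target if target_size is None else target_size
    if target < len(smoothed):
        keep = rng.choice(len(smoothed), size=target, replace=False)
        smoothed = smoothed.subset(np.sort(keep))
    return smoothed
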