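"""Geometry primitives: point clouds, rigid transforms, nearest-neighbour
search, closed-form rigid fitting, and the RMS metrics shared by all stages.

Coordinates are unitless lengths (typically read as millimetres). Transforms
are strictly rigid: rotation plus translation, no scaling, no reflection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree


class DegenerateError(ValueError):
    """Raised when a geometric operation has no well-defined answer
    (empty input, collinear correspondences, zero total weight)."""


class RmsTrace:
    """Sequence of RMS values, one per accepted iteration.

    Appending a value larger than the current last is a programming error in
    the optimizer (accepted updates must be monotone), so it raises.
    """

    def __init__(self, values=()):
        self.values: list[float] = []
        for v in values:
            self.append(v)

    def append(self, value: float) -> None:
        if value < 0:
            raise ValueError("RMS values must be nonnegative")
        if self.values and value > self.values[-1]:
            raise ValueError("accepted-RMS trace must be non-increasing")
        self.values.append(float(value))

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, i):
        return self.values[i]

    def __iter__(self):
        return iter(self.values)


# ---------------------------------------------------------------------------
# Point clouds
# ---------------------------------------------------------------------------

@dataclass
class PointCloud:
    """An ordered set of 3D points with optional per-point unit normals.

    ``ids`` are stable integer labels preserved across filtering, so a point
    removed by denoising can be reported and a fiducial marker can be matched
    by identity rather than by position.
    """

    points: np.ndarray
    normals: np.ndarray | None = None
    ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("points contain non-finite coordinates")
        if self.ids is None:
            self.ids = np.arange(len(self.points))
        else:
            self.ids = np.asarray(self.ids, dtype=int)
            if len(self.ids) != len(self.points):
                raise ValueError("ids length must match point count")
            if len(np.unique(self.ids)) != len(self.ids):
                raise ValueError("ids must be unique")
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=float)
            if self.normals.shape != self.points.shape:
                raise ValueError("normals shape must match points shape")
            norms = np.linalg.norm(self.normals, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-9):
                raise ValueError("normals must be unit length")

    def __len__(self) -> int:
        return len(self.points)

    def subset(self, mask_or_indices: np.ndarray) -> "PointCloud":
        """Select points by boolean mask or integer positions; ids survive."""
        idx = np.asarray(mask_or_indices)
        return PointCloud(
            points=self.points[idx],
            normals=None if self.normals is None else self.normals[idx],
            ids=self.ids[idx],
        )

    def copy(self) -> "PointCloud":
        return PointCloud(
            points=self.points.copy(),
            normals=None if self.normals is None else self.normals.copy(),
            ids=self.ids.copy(),
        )

    def bounding_box_diagonal(self) -> float:
        span = self.points.max(axis=0) - self.points.min(axis=0)
        return float(np.linalg.norm(span))


# ---------------------------------------------------------------------------
# Rigid transforms
# ---------------------------------------------------------------------------

def _project_to_rotation(m: np.ndarray) -> np.ndarray:
    """Nearest proper rotation (Frobenius) to a 3x3 matrix, via SVD."""
    u, _, vt = np.linalg.svd(m)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, 1.0, d]) @ vt


@dataclass(frozen=True)
class RigidTransform:
    """A 4x4 homogeneous rigid-body map: orthonormal rotation block with
    determinant +1, translation column, bottom row (0, 0, 0, 1)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("matrix must be 4x4")
        r = m[:3, :3]
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-9):
            raise ValueError("rotation block is not orthonormal")
        if not np.isclose(np.linalg.det(r), 1.0, atol=1e-9):
            raise ValueError("rotation block is not proper (det != +1)")
        if not np.array_equal(m[3], [0.0, 0.0, 0.0, 1.0]):
            m = m.copy()
            m[3] = (0.0, 0.0, 0.0, 1.0)
        object.__setattr__(self, "matrix", m)

    # -- constructors -------------------------------------------------------

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(4))

    @staticmethod
    def from_rotation_translation(rotation: np.ndarray,
                                  translation: np.ndarray) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = rotation
        m[:3, 3] = translation
        return RigidTransform(m)

    @staticmethod
    def from_axis_angle(axis: np.ndarray, angle: float,
                        translation: np.ndarray | None = None) -> "RigidTransform":
        axis = np.asarray(axis, dtype=float)
        n = np.linalg.norm(axis)
        if n == 0:
            rot = np.eye(3)
        else:
            rot = _rotation_from_axis_angle(axis / n * angle)
        t = np.zeros(3) if translation is None else np.asarray(translation, float)
        return RigidTransform.from_rotation_translation(rot, t)

    # -- accessors ----------------------------------------------------------

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def rotation_angle(self) -> float:
        """Magnitude of the rotation, in radians.

        atan2 of the antisymmetric part's norm against the trace: accurate
        for tiny angles, where arccos of the trace loses half the digits.
        """
        r = self.rotation
        s = 0.5 * np.linalg.norm([r[2, 1] - r[1, 2], r[0, 2] - r[2, 0],
                                  r[1, 0] - r[0, 1]])
        c = (np.trace(r) - 1.0) / 2.0
        return float(np.arctan2(s, c))

    # -- algebra ------------------------------------------------------------

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self ∘ other (apply ``other`` first)."""
        m = self.matrix @ other.matrix
        return RigidTransform.from_rotation_translation(
            _project_to_rotation(m[:3, :3]), m[:3, 3])

    def inverse(self) -> "RigidTransform":
        r = self.rotation.T
        return RigidTransform.from_rotation_translation(r, -r @ self.translation)

    def transform_points(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation

    # -- serialization ------------------------------------------------------

    def to_text(self) -> str:
        return "\n".join(" ".join(f"{v:.17g}" for v in row) for row in self.matrix)

    @staticmethod
    def from_text(text: str) -> "RigidTransform":
        rows = [[float(v) for v in line.split()] for line in text.strip().splitlines()]
        return RigidTransform(np.array(rows))

    def to_json(self) -> str:
        return json.dumps({"matrix": self.matrix.tolist()})

    @staticmethod
    def from_json(text: str) -> "RigidTransform":
        return RigidTransform(np.array(json.loads(text)["matrix"]))


def _rotation_from_axis_angle(rotvec: np.ndarray) -> np.ndarray:
    """Rodrigues' formula for a rotation vector (axis * angle)."""
    angle = np.linalg.norm(rotvec)
    if angle < 1e-300:
        return np.eye(3)
    k = rotvec / angle
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle) * kx + (1 - np.cos(angle)) * (kx @ kx)


def rotation_to_axis_angle(rotation: np.ndarray) -> np.ndarray:
    """Inverse of Rodrigues: rotation vector (axis * angle) of a rotation."""
    c = (np.trace(rotation) - 1.0) / 2.0
    angle = float(np.arccos(np.clip(c, -1.0, 1.0)))
    if angle < 1e-12:
        return np.zeros(3)
    if np.pi - angle < 1e-6:
        # near-pi: extract axis from R + I, whose columns are parallel to k
        m = rotation + np.eye(3)
        k = m[:, np.argmax(np.diag(m))]
        k = k / np.linalg.norm(k)
        return k * angle
    axis = np.array([
        rotation[2, 1] - rotation[1, 2],
        rotation[0, 2] - rotation[2, 0],
        rotation[1, 0] - rotation[0, 1],
    ]) / (2.0 * np.sin(angle))
    return axis * angle


def apply_transform(cloud: PointCloud, t: RigidTransform) -> PointCloud:
    """Map every point by the homogeneous transform; normals, if present,
    are rotated only. Ids are preserved."""
    normals = None
    if cloud.normals is not None:
        normals = cloud.normals @ t.rotation.T
    return PointCloud(points=t.transform_points(cloud.points),
                      normals=normals, ids=cloud.ids.copy())


# ---------------------------------------------------------------------------
# Nearest-neighbour search
# ---------------------------------------------------------------------------

class NeighborIndex:
    """KD-tree over a cloud answering exact k-NN and nearest-point queries.

    Ties in the nearest-point query are broken toward the lowest reference id
    so that correspondence search is deterministic.
    """

    def __init__(self, cloud: PointCloud):
        if len(cloud) == 0:
            raise DegenerateError("empty input: cannot index an empty cloud")
        self.cloud = cloud
        self._tree = cKDTree(cloud.points)

    def __len__(self) -> int:
        return len(self.cloud)

    def query_knn(self, points: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
        """Distances and positional indices of the k nearest points."""
        if k < 1 or k > len(self):
            raise ValueError(f"k must be in [1, {len(self)}]")
        d, i = self._tree.query(np.atleast_2d(points), k=k)
        return np.atleast_2d(d), np.atleast_2d(i)

    def nearest(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Nearest point per query: (distances, positional indices),
        lowest-id tie-break."""
        points = np.atleast_2d(points)
        d, i = self._tree.query(points, k=1)
        if len(self) > 1:
            d2, i2 = self._tree.query(points, k=2)
            tol = 1e-9 * np.maximum(1.0, d2[:, 0])
            tied = (d2[:, 1] - d2[:, 0]) <= tol
            for q in np.nonzero(tied)[0]:
                cands = self._tree.query_ball_point(points[q], d[q] + tol[q])
                cands = [c for c in cands
                         if abs(np.linalg.norm(self.cloud.points[c] - points[q])
                                - d[q]) <= tol[q]]
                if cands:
                    i[q] = min(cands, key=lambda c: self.cloud.ids[c])
        return d, i


def build_neighbor_index(cloud: PointCloud) -> NeighborIndex:
    return NeighborIndex(cloud)


# ---------------------------------------------------------------------------
# Rigid fitting and error metrics
# ---------------------------------------------------------------------------

def estimate_rigid_transform(src: np.ndarray, dst: np.ndarray,
                             weights: np.ndarray | None = None) -> RigidTransform:
    """Weighted least-squares rigid transform minimizing
    sum_i w_i * ||T(src_i) - dst_i||^2, in closed form (Kabsch SVD).

    Reflections are excluded by sign-correcting the smallest singular vector.
    Raises :class:`DegenerateError` on < 3 pairs, zero total weight, or a
    collinear configuration.
    """
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("src and dst must be matching (n, 3) arrays")
    n = len(src)
    if n < 3:
        raise DegenerateError("degenerate correspondence: need >= 3 pairs")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, float)
        if w.shape != (n,) or np.any(w < 0):
            raise ValueError("weights must be nonnegative, one per pair")
        total = w.sum()
        if total <= 0:
            raise DegenerateError("zero total weight")
        w = w / total

    mu_src = w @ src
    mu_dst = w @ dst
    p = src - mu_src
    q = dst - mu_dst
    h = (p * w[:, None]).T @ q
    u, s, vt = np.linalg.svd(h)
    if s[1] <= 1e-12 * max(s[0], 1e-300):
        raise DegenerateError("degenerate correspondence: collinear points")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = mu_dst - rot @ mu_src
    return RigidTransform.from_rotation_translation(_project_to_rotation(rot), trans)


def rms_error(src: PointCloud, dst_index: NeighborIndex,
              t: RigidTransform) -> float:
    """Root mean square of distances from each transformed source point to
    its nearest reference point — the registration objective."""
    if len(src) == 0:
        raise DegenerateError("empty input: RMS of an empty cloud")
    mapped = t.transform_points(src.points)
    d, _ = dst_index._tree.query(mapped, k=1)
    return float(np.sqrt(np.mean(d ** 2)))


def fiducial_rms(markers_true: PointCloud,
                 markers_mapped: PointCloud) -> tuple[np.ndarray, float]:
    """Per-marker Euclidean errors and their mean, matching markers by id
    (known correspondence — no nearest-neighbour search).

    This is the five-reference-point evaluation metric of the benchmark.
    """
    if len(markers_true) != len(markers_mapped):
        raise ValueError("marker count mismatch")
    order_true = np.argsort(markers_true.ids)
    order_map = np.argsort(markers_mapped.ids)
    if not np.array_equal(markers_true.ids[order_true],
                          markers_mapped.ids[order_map]):
        raise ValueError("marker ids do not match")
    diffs = markers_true.points[order_true] - markers_mapped.points[order_map]
    errors = np.linalg.norm(diffs, axis=1)
    return errors, float(errors.mean())
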