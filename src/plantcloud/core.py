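"""Domain types and shared geometry: labeled point clouds, camera model,
rigid transforms, k-d tree spatial index and PCA normal estimation.

Coordinates are metres throughout. The camera convention is x right, y up,
z along the optical axis (depth); configuration files may declare other
units, which are converted on load (see :mod:`plantcloud.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    InvalidInputError,
    InvalidTransformError,
)

__all__ = [
    "Label",
    "LabeledCloud",
    "CameraModel",
    "RigidTransform",
    "SpatialIndex",
    "estimate_normals",
    "transform",
]

_ORTHO_TOL = 1e-8


class Label(IntEnum):
    """Ground-truth point classes.

    PLANT is the target; BN (background), ON (outliers) and FPN (flying
    pixels) are the three noise classes a TOF capture of a potted plant
    contains.
    """

    PLANT = 0
    BN = 1
    ON = 2
    FPN = 3


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InvalidInputError(f"points must be (N, 3), got {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise InvalidInputError("points contain non-finite coordinates")
    return pts


@dataclass
class LabeledCloud:
    """A point cloud with optional unit normals and ground-truth labels.

    Normals flagged invalid (degenerate estimation neighborhood) are stored
    as NaN rows; every finite normal is unit length.
    """

    points: np.ndarray
    normals: Optional[np.ndarray] = None
    labels: Optional[np.ndarray] = None
    frame_id: int = 0

    def __post_init__(self):
        self.points = _as_points(self.points)
        n = len(self.points)
        if self.normals is not None:
            nm = np.asarray(self.normals, dtype=np.float64)
            if nm.shape != (n, 3):
                raise InvalidInputError(f"normals must be ({n}, 3), got {nm.shape}")
            finite = np.all(np.isfinite(nm), axis=1)
            norms = np.linalg.norm(nm[finite], axis=1)
            if norms.size and np.any(np.abs(norms - 1.0) > 1e-9):
                raise InvalidInputError("normals must be unit length within 1e-9")
            self.normals = nm
        if self.labels is not None:
            lb = np.asarray(self.labels)
            if lb.shape != (n,):
                raise InvalidInputError(f"labels must be ({n},), got {lb.shape}")
            self.labels = lb.astype(np.int16)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def n(self) -> int:
        return len(self.points)

    def select(self, mask) -> "LabeledCloud":
        """Sub-cloud of the points where ``mask`` is true (order preserved)."""
        mask = np.asarray(mask)
        return LabeledCloud(
            points=self.points[mask],
            normals=None if self.normals is None else self.normals[mask],
            labels=None if self.labels is None else self.labels[mask],
            frame_id=self.frame_id,
        )

    def with_(self, **kw) -> "LabeledCloud":
        return replace(self, **kw)

    def label_counts(self) -> dict:
        if self.labels is None:
            return {}
        vals, cnt = np.unique(self.labels, return_counts=True)
        return {Label(int(v)).name: int(c) for v, c in zip(vals, cnt)}


def _check_orthonormal(m: np.ndarray, what: str, require_det_plus: bool = False):
    m = np.asarray(m, dtype=np.float64)
    if m.shape != (3, 3):
        raise InvalidTransformError(f"{what} must be 3x3")
    if not np.allclose(m.T @ m, np.eye(3), atol=_ORTHO_TOL):
        raise InvalidTransformError(f"{what} is not orthonormal")
    if require_det_plus and np.linalg.det(m) < 0:
        raise InvalidTransformError(f"{what} must have determinant +1")
    return m


@dataclass
class CameraModel:
    """Depth-camera pose: viewpoint, downward tilt and orthonormal axes.

    ``axes`` columns are the camera x (right), y (up) and z (optical axis)
    directions expressed in the cloud's coordinate system.
    """

    viewpoint: np.ndarray
    tilt_theta: float = 0.0
    axes: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.viewpoint = np.asarray(self.viewpoint, dtype=np.float64).reshape(3)
        self.axes = _check_orthonormal(self.axes, "camera axes")
        if not (0.0 <= self.tilt_theta < np.pi / 2):
            raise InvalidInputError("tilt_theta must lie in [0, pi/2)")

    @property
    def x(self) -> np.ndarray:
        return self.axes[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.axes[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.axes[:, 2]

    def to_camera(self, points: np.ndarray) -> np.ndarray:
        """World -> camera coordinates."""
        return (np.asarray(points) - self.viewpoint) @ self.axes

    def to_world(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.axes.T + self.viewpoint

    def rotated(self, R: np.ndarray, pivot: np.ndarray) -> "CameraModel":
        """Camera pose after rotating the whole world by R about ``pivot``."""
        vp = R @ (self.viewpoint - pivot) + pivot
        return CameraModel(viewpoint=vp, tilt_theta=self.tilt_theta, axes=R @ self.axes)


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.rotation = _check_orthonormal(
            np.asarray(self.rotation, dtype=np.float64), "rotation", require_det_plus=True
        )
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def about_axis(cls, axis, angle: float, center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Rotation by ``angle`` (radians) about a line through ``center``."""
        axis = np.asarray(axis, dtype=np.float64)
        axis = axis / np.linalg.norm(axis)
        K = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
        center = np.asarray(center, dtype=np.float64)
        return cls(rotation=R, translation=center - R @ center)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def apply_normals(self, normals: np.ndarray) -> np.ndarray:
        return np.asarray(normals) @ self.rotation.T

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(rotation=Rt, translation=-Rt @ self.translation)

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def angle(self) -> float:
        """Rotation angle in radians."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.arccos(np.clip(c, -1.0, 1.0)))


class SpatialIndex:
    """k-d tree over a cloud supporting k-nearest and fixed-radius queries.

    Results match an exhaustive scan; k-nearest ties are resolved
    deterministically (smallest index first at equal distance).
    """

    def __init__(self, cloud_or_points):
        pts = cloud_or_points.points if isinstance(cloud_or_points, LabeledCloud) else cloud_or_points
        self.points = _as_points(pts)
        self.tree = cKDTree(self.points)

    def knn(self, query, k: int):
        """Distances and indices of the k nearest points (self included if
        the query is a cloud point)."""
        d, i = self.tree.query(np.asarray(query), k=min(k, len(self.points)))
        return d, i

    def radius(self, query, r: float):
        """Indices of points within distance r (sorted)."""
        idx = self.tree.query_ball_point(np.asarray(query), r)
        if isinstance(idx, list) and idx and isinstance(idx[0], list):
            return [sorted(j) for j in idx]
        return sorted(idx)

    def radius_all(self, r: float):
        """Per-point radius neighborhoods of the indexed cloud itself."""
        return self.tree.query_ball_tree(self.tree, r)


def transform(cloud: LabeledCloud, T: RigidTransform) -> LabeledCloud:
    """Apply a rigid transform: points -> R p + t, normals -> R n, labels kept."""
    if not isinstance(T, RigidTransform):
        raise InvalidTransformError("T must be a RigidTransform")
    return LabeledCloud(
        points=T.apply(cloud.points),
        normals=None if cloud.normals is None else T.apply_normals(cloud.normals),
        labels=None if cloud.labels is None else cloud.labels.copy(),
        frame_id=cloud.frame_id,
    )


def pca_normals(points: np.ndarray, k: int) -> np.ndarray:
    """Unoriented PCA normals: per point, the eigenvector of the
    k-neighborhood covariance with the smallest eigenvalue.

    Degenerate neighborhoods (zero covariance) yield NaN normals.
    """
    pts = _as_points(points)
    n = len(pts)
    if n < 3:
        raise InvalidInputError("need at least 3 points to estimate normals")
    if k < 3:
        raise InvalidInputError("neighborhood size k must be >= 3")
    k = min(k, n)
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=k)
    nbrs = pts[idx]  # (n, k, 3)
    centered = nbrs - nbrs.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered) / k
    w, v = np.linalg.eigh(cov)
    normals = v[:, :, 0]
    trace = np.einsum("nii->n", cov)
    degenerate = trace < 1e-24
    norms = np.linalg.norm(normals, axis=1)
    normals = normals / np.where(norms > 0, norms, 1.0)[:, None]
    normals[degenerate] = np.nan
    return normals


def estimate_normals(cloud: LabeledCloud, k: int = 30, camera: Optional[CameraModel] = None) -> LabeledCloud:
    """PCA normal estimation with viewpoint-consistent orientation.

    Each normal is the smallest-eigenvalue eigenvector of its k-neighborhood
    covariance, sign-flipped so it points toward the camera viewpoint
    (⟨n, viewpoint − p⟩ ≥ 0).  k defaults to 30.  Degenerate neighborhoods
    produce NaN (invalid) normals.
    """
    normals = pca_normals(cloud.points, k)
    if camera is not None:
        to_view = camera.viewpoint[None, :] - cloud.points
        flip = np.einsum("ij,ij->i", normals, to_view) < 0
        normals[flip] *= -1.0
    return cloud.with_(normals=normals)
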