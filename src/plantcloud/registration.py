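"""Multi-frame registration and layered-point elimination.

Adjacent turntable frames are registered (turntable prior + point-to-point
ICP), triangulated into local surface meshes, and pairs of neighboring
triangle patches from the two frames are classified as intersecting,
plane-intersecting or parallel.  Misaligned (layered) patches are collapsed
by projecting vertices onto the median plane of each patch pair; frames are
then merged and voxel down-sampled, and the procedure folds over the whole
sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import Delaunay, QhullError, cKDTree

from .core import LabeledCloud, RigidTransform, pca_normals, transform
from .errors import (
    DegenerateBisectorError,
    DegenerateGeometryError,
    DegenerateProjectionError,
    InvalidInputError,
    InvalidParameterError,
    MissingInitializerError,
    RegistrationError,
    StageError,
)

__all__ = [
    "TriPatch",
    "PatchRelation",
    "RelationKind",
    "OptimizeParams",
    "FrameSequence",
    "TriangleMesh",
    "Plane",
    "ICPResult",
    "TurntablePrior",
    "icp_register",
    "rough_register",
    "greedy_triangulate",
    "classify_patch_pair",
    "median_plane",
    "project_patch",
    "optimize_pair",
    "merge_downsample",
    "incremental_pipeline",
]

_AREA_FLOOR = 1e-12


class RelationKind:
    INTERSECTING = "INTERSECTING"
    PLANE_INTERSECTING = "PLANE_INTERSECTING"
    PARALLEL = "PARALLEL"
    DISJOINT = "DISJOINT"


def _tri_area(v: np.ndarray) -> float:
    return 0.5 * float(np.linalg.norm(np.cross(v[1] - v[0], v[2] - v[0])))


def _tri_normal(v: np.ndarray) -> np.ndarray:
    n = np.cross(v[1] - v[0], v[2] - v[0])
    norm = np.linalg.norm(n)
    if norm < 1e-300:
        raise DegenerateGeometryError("degenerate triangle")
    return n / norm


@dataclass
class TriPatch:
    """A single mesh triangle; orientation of the normal is arbitrary."""

    vertices: np.ndarray
    source_frame: int = 0

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(3, 3)
        if self.area <= _AREA_FLOOR:
            raise DegenerateGeometryError("triangle area below floor")

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    @property
    def normal(self) -> np.ndarray:
        return _tri_normal(self.vertices)

    @property
    def area(self) -> float:
        return _tri_area(self.vertices)


@dataclass
class PatchRelation:
    kind: str
    alpha_tri: float  # inter-plane angle, folded to [0, pi/2]
    d_cen: float  # centroid-to-centroid distance
    d_tri: Optional[float] = None  # centroid-to-plane distance (parallel pairs)
    d_pro: Optional[np.ndarray] = None  # per-vertex projection distances


@dataclass
class OptimizeParams:
    """Thresholds of the patch-pair optimizer.

    alpha_min — projection trigger and stop criterion on the inter-plane
    angle (default 20°); d_min_factor — the per-pair stop distance is
    d_min_factor × centroid distance (default 2); d_pro_max / d_cen_max —
    cancellation bounds for plane-intersecting / parallel projections;
    max_neighbors — patches retrieved per source patch (default 3);
    parallel_eps — parallel test bound on sin(alpha_tri) (default 1e-6;
    discrete meshes in practice want an angular tolerance such as sin 5°).
    """

    alpha_min: float = np.deg2rad(20.0)
    d_min_factor: float = 2.0
    d_pro_max: float = 0.010
    d_cen_max: float = 0.010
    max_iterations: int = 100
    max_neighbors: int = 3
    parallel_eps: float = 1e-6

    def __post_init__(self):
        if min(self.alpha_min, self.d_min_factor, self.d_pro_max, self.d_cen_max,
               self.max_iterations, self.parallel_eps) <= 0:
            raise InvalidParameterError("all optimizer parameters must be positive")
        if self.max_neighbors < 1:
            raise InvalidParameterError("max_neighbors must be >= 1")


@dataclass
class FrameSequence:
    """Ordered frames with ground-truth and estimated frame→frame-0 transforms."""

    frames: List[LabeledCloud]
    gt_transforms: Optional[List[RigidTransform]] = None
    est_transforms: Optional[List[RigidTransform]] = None

    def __post_init__(self):
        if not self.frames:
            raise InvalidInputError("FrameSequence needs at least one frame")
        if self.est_transforms is None:
            self.est_transforms = [RigidTransform.identity()]
            self.est_transforms += [None] * (len(self.frames) - 1)


@dataclass
class TriangleMesh:
    """Shared-vertex triangle mesh (triangle soup with vertex identity)."""

    vertices: np.ndarray
    faces: np.ndarray
    source_frame: int = 0

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_vertices(self) -> np.ndarray:
        return self.vertices[self.faces]  # (F, 3, 3)

    def centroids(self) -> np.ndarray:
        return self.face_vertices().mean(axis=1)

    def normals(self) -> np.ndarray:
        fv = self.face_vertices()
        n = np.cross(fv[:, 1] - fv[:, 0], fv[:, 2] - fv[:, 0])
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        return n / np.where(norm > 0, norm, 1.0)

    def patches(self) -> List[TriPatch]:
        return [TriPatch(v, self.source_frame) for v in self.face_vertices()]

    def cloud(self, labels=None, used_only: bool = False) -> LabeledCloud:
        """Vertices as a cloud; ``used_only`` drops vertices referenced by
        no face (points the surface model does not support)."""
        if used_only and len(self.faces):
            idx = np.unique(self.faces)
            return LabeledCloud(points=self.vertices[idx].copy(),
                                labels=None if labels is None else np.asarray(labels)[idx],
                                frame_id=self.source_frame)
        return LabeledCloud(points=self.vertices.copy(), labels=labels,
                            frame_id=self.source_frame)


@dataclass
class Plane:
    """Plane <n, x> = offset with unit normal."""

    normal: np.ndarray
    offset: float

    def __post_init__(self):
        self.normal = np.asarray(self.normal, dtype=np.float64).reshape(3)
        n = np.linalg.norm(self.normal)
        if abs(n - 1.0) > 1e-9:
            self.normal = self.normal / n
        self.offset = float(self.offset)

    def signed_distance(self, points) -> np.ndarray:
        return np.asarray(points) @ self.normal - self.offset


# ---------------------------------------------------------------------------
# Registration

@dataclass
class ICPResult:
    transform: RigidTransform
    rmse: float
    n_iterations: int
    overlap_fraction: float
    converged: bool

    @property
    def low_overlap(self) -> bool:
        return self.overlap_fraction < 0.3

    def __iter__(self):
        # allow (transform, rmse) unpacking
        return iter((self.transform, self.rmse))


def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Closed-form least-squares rigid alignment src -> dst.

    A fully rank-deficient covariance (all correspondences collapse onto
    one target point, e.g. far-apart clouds) leaves the rotation
    unidentifiable; the step degrades to the translation aligning the
    centroids."""
    if not (np.isfinite(src).all() and np.isfinite(dst).all()):
        raise RegistrationError("non-finite correspondences")
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    H = (src - cs).T @ (dst - cd)
    U, S, Vt = np.linalg.svd(H)
    if S[0] < 1e-15:
        return RigidTransform(translation=cd - cs)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(rotation=R, translation=cd - R @ cs)


def icp_register(source: LabeledCloud, target: LabeledCloud,
                 init: RigidTransform = RigidTransform(),
                 max_iter: int = 50, tol: float = 1e-7,
                 max_corr_dist: Optional[float] = None) -> ICPResult:
    """Point-to-point ICP with closed-form (SVD) per-iteration alignment.

    Stops when the RMSE improvement drops below ``tol`` or after
    ``max_iter`` iterations.  ``max_corr_dist`` gates correspondences;
    the fraction of gated source points is reported as overlap_fraction.
    """
    if len(source) == 0 or len(target) == 0:
        raise InvalidInputError("icp_register needs non-empty clouds")
    src0 = source.points
    tree = cKDTree(target.points)
    T = init
    prev_rmse = np.inf
    rmse = np.inf
    overlap = 1.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        moved = T.apply(src0)
        d, idx = tree.query(moved)
        if max_corr_dist is not None:
            mask = d <= max_corr_dist
        else:
            mask = np.ones(len(d), dtype=bool)
        overlap = float(mask.mean())
        if mask.sum() < 3:
            # gate empties on non-overlapping clouds: fall back to all
            # correspondences and let the low-overlap flag carry the warning
            mask = np.ones(len(d), dtype=bool)
        rmse = float(np.sqrt(np.mean(d[mask] ** 2)))
        if prev_rmse - rmse < tol:
            converged = True
            break
        prev_rmse = rmse
        step = _kabsch(moved[mask], target.points[idx[mask]])
        T = step @ T
    return ICPResult(transform=T, rmse=rmse, n_iterations=it,
                     overlap_fraction=overlap, converged=converged)


@dataclass
class TurntablePrior:
    """Known turntable increment: rotation by ``angle`` (radians) about the
    axis through ``center``, mapping the later frame into the earlier one."""

    angle: float
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def transform(self) -> RigidTransform:
        return RigidTransform.about_axis(self.axis, self.angle, self.center)


def rough_register(source: LabeledCloud, target: LabeledCloud,
                   prior=None, backend=None) -> RigidTransform:
    """Rough (global) registration.

    The default implementation returns the turntable prior; a feature-based
    global-registration ``backend`` callable (source, target) -> RigidTransform
    may be plugged in instead.
    """
    if backend is not None:
        return backend(source, target)
    if prior is None:
        raise MissingInitializerError("rough_register needs a turntable prior or a backend")
    if isinstance(prior, TurntablePrior):
        return prior.transform()
    if isinstance(prior, RigidTransform):
        return prior
    raise InvalidInputError(f"unsupported prior type {type(prior)!r}")


# ---------------------------------------------------------------------------
# Triangulation

def _local_frame(normal: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    a = np.array([1.0, 0.0, 0.0]) if abs(normal[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, a)
    u /= np.linalg.norm(u)
    return u, np.cross(normal, u)


def greedy_triangulate(cloud: LabeledCloud, max_edge: float = 0.005,
                       mu: float = 2.5, max_nn: int = 30) -> TriangleMesh:
    """Local-projection surface triangulation.

    Each point's radius neighborhood is projected onto the point's tangent
    plane and Delaunay-triangulated in 2D; triangles incident to the point
    are collected over all points and deduplicated.  Vertices are input
    points (no resampling).  Triangles are rejected when an edge exceeds
    ``max_edge`` or ``mu`` times the local nearest-neighbor distance, or
    when nearly degenerate.

    A deterministic sub-nanometre jitter (fixed seed, keyed to the input
    order) breaks cocircular Delaunay ties consistently across overlapping
    neighborhoods, so regular grids triangulate without duplicate or
    crossing patches.
    """
    pts = cloud.points
    n = len(pts)
    if n < 3:
        raise InvalidInputError("triangulation needs at least 3 points")
    normals = cloud.normals
    if normals is None or np.isnan(normals).any():
        normals = pca_normals(pts, k=min(max_nn, n))
        nanrow = np.isnan(normals).any(axis=1)
        normals[nanrow] = np.array([0.0, 0.0, 1.0])

    scale = float(np.ptp(pts, axis=0).max()) or 1.0
    rng = np.random.default_rng(987654321)
    jitter = rng.normal(scale=1e-9 * scale, size=pts.shape)
    ppts = pts + jitter

    tree = cKDTree(ppts)
    d1, _ = tree.query(ppts, k=min(2, n))
    nn1 = d1[:, 1] if n > 1 else np.zeros(n)
    neigh = tree.query_ball_tree(tree, max_edge)

    tris = set()
    for i in range(n):
        idx = neigh[i]
        if len(idx) > max_nn:
            local = np.asarray(idx)
            order = np.argsort(np.linalg.norm(ppts[local] - ppts[i], axis=1))
            idx = list(local[order[:max_nn]])
        if i not in idx:
            idx.append(i)
        idx = np.asarray(sorted(idx))
        if len(idx) < 3:
            continue
        u, v = _local_frame(normals[i])
        rel = ppts[idx] - ppts[i]
        uv = np.stack([rel @ u, rel @ v], axis=1)
        try:
            dela = Delaunay(uv)
        except QhullError:
            continue
        center_local = int(np.searchsorted(idx, i))
        for simplex in dela.simplices:
            if center_local in simplex:
                tris.add(tuple(sorted(int(idx[s]) for s in simplex)))

    faces = []
    for tri in sorted(tris):
        v = pts[list(tri)]
        e = np.array([np.linalg.norm(v[0] - v[1]), np.linalg.norm(v[1] - v[2]),
                      np.linalg.norm(v[2] - v[0])])
        longest = e.max()
        if longest > max_edge:
            continue
        if longest > mu * max(nn1[list(tri)].max(), 1e-300):
            continue
        area = _tri_area(v)
        if area <= _AREA_FLOOR or (2.0 * area / longest) < 1e-4 * longest:
            continue  # degenerate or sliver (height << edge)
        faces.append(tri)
    return TriangleMesh(vertices=pts.copy(), faces=np.asarray(faces, dtype=np.int64).reshape(-1, 3),
                        source_frame=cloud.frame_id)


# ---------------------------------------------------------------------------
# Patch-pair geometry

def _plane_of(vertices: np.ndarray) -> Plane:
    nrm = _tri_normal(vertices)
    return Plane(normal=nrm, offset=float(nrm @ vertices.mean(axis=0)))


_KIND_CODES = {0: RelationKind.INTERSECTING, 1: RelationKind.PLANE_INTERSECTING,
               2: RelationKind.PARALLEL, 3: RelationKind.DISJOINT}


def _tri_normals_batch(v: np.ndarray) -> np.ndarray:
    n = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    return n / np.maximum(norm, 1e-300)


def _tri_areas_batch(v: np.ndarray) -> np.ndarray:
    return 0.5 * np.linalg.norm(np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1)


def _line_triangle_intervals(v: np.ndarray, n: np.ndarray, p0: np.ndarray,
                             d: np.ndarray, eps: float = 1e-12):
    """Vectorized parameter intervals of lines p0 + t d inside triangles
    lying in the lines' planes (clipping against the three edge
    half-planes).  Returns (lo, hi, empty) arrays."""
    P = len(v)
    lo = np.full(P, -np.inf)
    hi = np.full(P, np.inf)
    empty = np.zeros(P, dtype=bool)
    for k in range(3):
        a = v[:, k]
        b = v[:, (k + 1) % 3]
        inward = np.cross(n, b - a)  # toward triangle interior
        num = np.einsum("ij,ij->i", inward, a - p0)
        den = np.einsum("ij,ij->i", inward, d)
        par = np.abs(den) < eps
        empty |= par & (np.einsum("ij,ij->i", inward, p0 - a) < -eps)
        t = num / np.where(par, 1.0, den)
        lo = np.where(~par & (den > 0), np.maximum(lo, t), lo)
        hi = np.where(~par & (den < 0), np.minimum(hi, t), hi)
    empty |= lo > hi + eps
    return lo, hi, empty


def _classify_arrays(va: np.ndarray, vb: np.ndarray, params: OptimizeParams):
    """Vectorized patch-pair classification over (P, 3, 3) vertex arrays.

    Returns dict with 'kind' (int codes per _KIND_CODES), 'alpha', 'd_cen',
    'd_tri', 'na', 'nb', 'ca', 'cb'.
    """
    na, nb = _tri_normals_batch(va), _tri_normals_batch(vb)
    cr = np.cross(na, nb)
    sin_ang = np.linalg.norm(cr, axis=1)
    cos_ang = np.abs(np.einsum("ij,ij->i", na, nb))
    alpha = np.arctan2(sin_ang, cos_ang)
    ca, cb = va.mean(axis=1), vb.mean(axis=1)
    d_cen = np.linalg.norm(ca - cb, axis=1)
    parallel = sin_ang < params.parallel_eps
    d_tri = np.abs(np.einsum("ij,ij->i", na, cb - ca))

    kind = np.full(len(va), 3, dtype=np.int8)  # DISJOINT default
    kind[parallel] = 2
    np_mask = ~parallel
    if np_mask.any():
        safe_sin = np.where(np_mask, sin_ang, 1.0)
        d_line = cr / safe_sin[:, None]
        oa = np.einsum("ij,ij->i", na, ca)
        ob = np.einsum("ij,ij->i", nb, cb)
        nanb = np.einsum("ij,ij->i", na, nb)
        det = np.where(np_mask, 1.0 - nanb ** 2, 1.0)
        c1 = (oa - ob * nanb) / det
        c2 = (ob - oa * nanb) / det
        p0 = c1[:, None] * na + c2[:, None] * nb
        lo_a, hi_a, empty_a = _line_triangle_intervals(va, na, p0, d_line)
        lo_b, hi_b, empty_b = _line_triangle_intervals(vb, nb, p0, d_line)
        tol = 1e-12
        overlap = (~empty_a & ~empty_b
                   & (np.minimum(hi_a, hi_b) - np.maximum(lo_a, lo_b) >= -tol))
        one_crossed = empty_a != empty_b
        kind[np_mask & overlap] = 0
        kind[np_mask & ~overlap & one_crossed] = 1
    return {"kind": kind, "alpha": alpha, "d_cen": d_cen, "d_tri": d_tri,
            "na": na, "nb": nb, "ca": ca, "cb": cb}


def classify_patch_pair(A: TriPatch, B: TriPatch, params: OptimizeParams = OptimizeParams()) -> PatchRelation:
    """Classify the geometric relation of two triangle patches.

    PARALLEL when sin(inter-plane angle) < parallel_eps.  Otherwise the
    planes meet in a line L: the pair is INTERSECTING when the segments
    L∩A and L∩B overlap (true triangle-triangle intersection, Möller-style
    interval test), PLANE_INTERSECTING when L crosses the interior of
    exactly one of the two triangles, and DISJOINT otherwise.

    d_tri (centroid-to-plane distance) is populated for PARALLEL pairs.
    """
    res = _classify_arrays(A.vertices[None], B.vertices[None], params)
    code = int(res["kind"][0])
    return PatchRelation(
        kind=_KIND_CODES[code],
        alpha_tri=float(res["alpha"][0]),
        d_cen=float(res["d_cen"][0]),
        d_tri=float(res["d_tri"][0]) if code == 2 else None,
    )


def median_plane(A: TriPatch, B: TriPatch) -> Plane:
    """Normal-bisector plane through the midpoint of the two centroids.

    The two plane normals are oriented to a common hemisphere (dot >= 0)
    before averaging; exactly anti-parallel normals that cannot be oriented
    raise DegenerateBisectorError.
    """
    na, nb = A.normal, B.normal
    if na @ nb < 0:
        nb = -nb
    s = na + nb
    norm = np.linalg.norm(s)
    if norm < 1e-12:
        raise DegenerateBisectorError("undefined bisector for anti-parallel patches")
    n = s / norm
    mid = 0.5 * (A.centroid + B.centroid)
    return Plane(normal=n, offset=float(n @ mid))


def project_patch(T: TriPatch, plane: Plane) -> Tuple[TriPatch, np.ndarray]:
    """Orthogonally project a patch's vertices onto a plane.

    Returns (projected patch, per-vertex displacement distances d_pro).
    A projection collapsing the triangle below the area floor is cancelled
    with DegenerateProjectionError.
    """
    sd = plane.signed_distance(T.vertices)
    new_v = T.vertices - sd[:, None] * plane.normal[None, :]
    if _tri_area(new_v) <= _AREA_FLOOR:
        raise DegenerateProjectionError("projection collapses the triangle")
    return TriPatch(new_v, T.source_frame), np.abs(sd)


# ---------------------------------------------------------------------------
# Pair optimization

def _project_vertices(vertices: np.ndarray, plane: Plane):
    sd = plane.normal @ vertices.T - plane.offset
    return vertices - sd[:, None] * plane.normal[None, :], np.abs(sd)


@dataclass
class OptimizeStats:
    iterations: int = 0
    kind_counts: dict = field(default_factory=dict)
    cancelled_parallel: int = 0
    cancelled_plane_intersecting: int = 0
    degenerate_projections: int = 0
    ave_an_trace: List[float] = field(default_factory=list)
    ave_ed_trace: List[float] = field(default_factory=list)


def _retrieve_pairs(mesh_a: TriangleMesh, mesh_b: TriangleMesh, params: OptimizeParams):
    """Neighbor retrieval shared by the optimizer and the layering metrics:
    every patch of A paired with its ≤ max_neighbors nearest B patches by
    centroid (k-d tree).  Returns flat index arrays (ii, jj)."""
    ca, cb = mesh_a.centroids(), mesh_b.centroids()
    if len(cb) == 0 or len(ca) == 0:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64)
    tree = cKDTree(cb)
    k = min(params.max_neighbors, len(cb))
    _, idx = tree.query(ca, k=k)
    idx = np.atleast_2d(idx.T).T if k == 1 else idx
    ii = np.repeat(np.arange(len(ca), dtype=np.int64), k)
    jj = idx.reshape(-1).astype(np.int64)
    return ii, jj


def _pair_relations(mesh_a: TriangleMesh, mesh_b: TriangleMesh, params: OptimizeParams):
    """Retrieval + classification as a list of (i, j, PatchRelation)."""
    ii, jj = _retrieve_pairs(mesh_a, mesh_b, params)
    if len(ii) == 0:
        return []
    fa, fb = mesh_a.face_vertices(), mesh_b.face_vertices()
    res = _classify_arrays(fa[ii], fb[jj], params)
    out = []
    for p in range(len(ii)):
        code = int(res["kind"][p])
        out.append((int(ii[p]), int(jj[p]), PatchRelation(
            kind=_KIND_CODES[code],
            alpha_tri=float(res["alpha"][p]),
            d_cen=float(res["d_cen"][p]),
            d_tri=float(res["d_tri"][p]) if code == 2 else None,
        )))
    return out


def optimize_pair(mesh_a: TriangleMesh, mesh_b: TriangleMesh,
                  params: OptimizeParams = OptimizeParams()):
    """Collapse layered patches between two registered frame meshes.

    For each patch of A and its ≤ max_neighbors nearest B patches:
    intersecting / plane-intersecting pairs with alpha_tri > alpha_min have
    the B patch projected onto the pair's median plane (cancelled for
    plane-intersecting pairs when any d_pro > d_pro_max); parallel pairs
    have BOTH patches projected (cancelled when the projected centroid
    distance exceeds d_cen_max).  Vertices shared by several patches move
    to the mean of their proposed positions.  Sweeps repeat until every
    pair satisfies alpha_tri < alpha_min or max d_pro < d_min_factor × its
    centroid distance, or max_iterations is reached.

    Returns (mesh_a', mesh_b', OptimizeStats).
    """
    if mesh_a.n_faces == 0 or mesh_b.n_faces == 0:
        raise InvalidInputError("optimize_pair needs non-empty meshes")
    va = mesh_a.vertices.copy()
    vb = mesh_b.vertices.copy()
    stats = OptimizeStats()
    completed: set = set()  # pair keys satisfying the per-pair stop criterion
    n_fb = mesh_b.n_faces

    def record_trace(cls):
        an_mask = (cls["kind"] == 0) | (cls["kind"] == 1)
        ed_mask = cls["kind"] == 2
        stats.ave_an_trace.append(
            float(np.rad2deg(cls["alpha"][an_mask].mean())) if an_mask.any() else float("nan"))
        stats.ave_ed_trace.append(
            float(cls["d_tri"][ed_mask].mean()) if ed_mask.any() else float("nan"))

    for it in range(params.max_iterations):
        ma = TriangleMesh(va, mesh_a.faces, mesh_a.source_frame)
        mb = TriangleMesh(vb, mesh_b.faces, mesh_b.source_frame)
        ii, jj = _retrieve_pairs(ma, mb, params)
        fva, fvb = ma.face_vertices(), mb.face_vertices()
        cls = _classify_arrays(fva[ii], fvb[jj], params)
        kind, alpha, d_cen = cls["kind"], cls["alpha"], cls["d_cen"]
        if it == 0:
            for code, count in zip(*np.unique(kind, return_counts=True)):
                stats.kind_counts[_KIND_CODES[int(code)]] = int(count)
        record_trace(cls)

        keys = ii * n_fb + jj
        if completed:
            done_arr = np.fromiter(completed, dtype=np.int64)
            active = ~np.isin(keys, done_arr)
        else:
            active = np.ones(len(keys), dtype=bool)

        # non-parallel pairs already below the angle trigger are completed
        shallow = active & ((kind == 0) | (kind == 1)) & (alpha <= params.alpha_min)
        completed.update(keys[shallow].tolist())

        # median planes (normals oriented to a common hemisphere)
        na, nb = cls["na"], cls["nb"]
        flip = np.einsum("ij,ij->i", na, nb) < 0
        nb_or = np.where(flip[:, None], -nb, nb)
        bis = na + nb_or
        bis_norm = np.linalg.norm(bis, axis=1)
        ok_bis = bis_norm > 1e-12
        n_mid = bis / np.maximum(bis_norm, 1e-300)[:, None]
        mid = 0.5 * (cls["ca"] + cls["cb"])
        off = np.einsum("ij,ij->i", n_mid, mid)

        def project(tri_v, sel):
            sd = np.einsum("pij,pj->pi", tri_v[sel], n_mid[sel]) - off[sel][:, None]
            return tri_v[sel] - sd[..., None] * n_mid[sel][:, None, :], np.abs(sd)

        sum_a = np.zeros_like(va)
        cnt_a = np.zeros(len(va))
        sum_b = np.zeros_like(vb)
        cnt_b = np.zeros(len(vb))
        projected = 0

        # parallel pairs: both patches onto the median plane
        par = active & (kind == 2) & ok_bis
        if par.any():
            new_a, _ = project(fva[ii], par)
            new_b, _ = project(fvb[jj], par)
            good = (_tri_areas_batch(new_a) > _AREA_FLOOR) & (_tri_areas_batch(new_b) > _AREA_FLOOR)
            stats.degenerate_projections += int((~good).sum())
            # cancel when the projected patches end up apart, or when the
            # projection itself would drag a patch centroid farther than
            # d_cen_max (patches too far apart to be the same surface)
            d_cen_new = np.linalg.norm(new_a.mean(axis=1) - new_b.mean(axis=1), axis=1)
            disp_a = np.linalg.norm(new_a.mean(axis=1) - fva[ii][par].mean(axis=1), axis=1)
            disp_b = np.linalg.norm(new_b.mean(axis=1) - fvb[jj][par].mean(axis=1), axis=1)
            cancel = good & (np.maximum(d_cen_new, np.maximum(disp_a, disp_b))
                             > params.d_cen_max)
            stats.cancelled_parallel += int(cancel.sum())
            good &= ~cancel
            if good.any():
                sel_i = ii[par][good]
                sel_j = jj[par][good]
                np.add.at(sum_a, mesh_a.faces[sel_i].reshape(-1),
                          new_a[good].reshape(-1, 3))
                np.add.at(cnt_a, mesh_a.faces[sel_i].reshape(-1), 1)
                np.add.at(sum_b, mesh_b.faces[sel_j].reshape(-1),
                          new_b[good].reshape(-1, 3))
                np.add.at(cnt_b, mesh_b.faces[sel_j].reshape(-1), 1)
                projected += int(good.sum())
                # parallel pairs trivially satisfy alpha_tri < alpha_min
                completed.update((sel_i * n_fb + sel_j).tolist())

        # steep intersecting / plane-intersecting pairs: B onto the median
        steep = active & ((kind == 0) | (kind == 1)) & (alpha > params.alpha_min) & ok_bis
        if steep.any():
            new_b, d_pro = project(fvb[jj], steep)
            good = _tri_areas_batch(new_b) > _AREA_FLOOR
            stats.degenerate_projections += int((~good).sum())
            cancel = good & (kind[steep] == 1) & (d_pro.max(axis=1) > params.d_pro_max)
            stats.cancelled_plane_intersecting += int(cancel.sum())
            good &= ~cancel
            if good.any():
                sel_j = jj[steep][good]
                np.add.at(sum_b, mesh_b.faces[sel_j].reshape(-1),
                          new_b[good].reshape(-1, 3))
                np.add.at(cnt_b, mesh_b.faces[sel_j].reshape(-1), 1)
                projected += int(good.sum())
                # projected pairs complete once d_pro < d_min = factor × d_cen
                # (the angle criterion is re-checked on the next sweep)
                fin = good & (d_pro.max(axis=1) < params.d_min_factor * d_cen[steep])
                completed.update(((ii[steep] * n_fb + jj[steep])[fin]).tolist())

        moved_a = cnt_a > 0
        moved_b = cnt_b > 0
        new_va = va.copy()
        new_vb = vb.copy()
        new_va[moved_a] = sum_a[moved_a] / cnt_a[moved_a][:, None]
        new_vb[moved_b] = sum_b[moved_b] / cnt_b[moved_b][:, None]
        delta = 0.0
        if moved_a.any():
            delta = max(delta, float(np.abs(new_va[moved_a] - va[moved_a]).max()))
        if moved_b.any():
            delta = max(delta, float(np.abs(new_vb[moved_b] - vb[moved_b]).max()))
        va, vb = new_va, new_vb
        stats.iterations = it + 1
        if projected == 0 or delta < 1e-9:
            break

    out_a = TriangleMesh(va, mesh_a.faces, mesh_a.source_frame)
    out_b = TriangleMesh(vb, mesh_b.faces, mesh_b.source_frame)
    ii, jj = _retrieve_pairs(out_a, out_b, params)
    if len(ii):
        record_trace(_classify_arrays(out_a.face_vertices()[ii],
                                      out_b.face_vertices()[jj], params))
    return out_a, out_b, stats


# ---------------------------------------------------------------------------
# Merge / pipeline

def merge_downsample(clouds: Sequence[LabeledCloud], voxel: float) -> LabeledCloud:
    """Voxel-grid down-sampling of the concatenated clouds: one centroid per
    occupied voxel.  Labels, when present on every input, are reduced by
    majority (ties toward the smaller class id)."""
    if voxel <= 0:
        raise InvalidParameterError("voxel must be > 0")
    clouds = [c for c in clouds if len(c) > 0]
    if not clouds:
        return LabeledCloud(points=np.zeros((0, 3)))
    pts = np.concatenate([c.points for c in clouds], axis=0)
    have_labels = all(c.labels is not None for c in clouds)
    labels = np.concatenate([c.labels for c in clouds]) if have_labels else None

    origin = pts.min(axis=0)
    keys = np.floor((pts - origin) / voxel + 1e-12).astype(np.int64)
    _, inverse, counts = np.unique(keys, axis=0, return_inverse=True, return_counts=True)
    n_vox = len(counts)
    sums = np.zeros((n_vox, 3))
    np.add.at(sums, inverse, pts)
    centroids = sums / counts[:, None]
    out_labels = None
    if have_labels:
        out_labels = np.zeros(n_vox, dtype=np.int16)
        n_classes = int(labels.max()) + 1
        tally = np.zeros((n_vox, n_classes), dtype=np.int64)
        np.add.at(tally, (inverse, labels.astype(np.int64)), 1)
        out_labels = tally.argmax(axis=1).astype(np.int16)
    return LabeledCloud(points=centroids, labels=out_labels, frame_id=clouds[0].frame_id)


@dataclass
class PipelineConfig:
    """Configuration for the incremental multi-frame pipeline."""

    turntable_step: float = 0.0  # radians the scene advances per frame
    turntable_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    turntable_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    voxel: float = 0.002
    max_edge: float = 0.005
    mu: float = 2.5
    max_nn: int = 30
    icp_max_iter: int = 50
    icp_tol: float = 1e-7
    icp_gate_voxels: float = 5.0


def incremental_pipeline(seq: FrameSequence, params: OptimizeParams = OptimizeParams(),
                         config: PipelineConfig = PipelineConfig()):
    """Fold a denoised, smoothed frame sequence into one cloud.

    Per frame: rough registration (turntable prior), ICP fine alignment
    updating M_glo = M_glo · M_temp, triangulation of both the accumulated
    cloud and the new frame, patch-pair optimization, merge and voxel
    down-sampling.  Returns (accumulated cloud, per-pair stats list); the
    estimated frame→frame-0 transforms are stored on ``seq.est_transforms``.
    """
    frames = seq.frames
    acc = frames[0]
    seq.est_transforms = [RigidTransform.identity()] + [None] * (len(frames) - 1)
    pair_stats = []
    m_glo = RigidTransform.identity()
    step_prior = TurntablePrior(angle=-config.turntable_step, axis=config.turntable_axis,
                                center=config.turntable_center)
    for i in range(1, len(frames)):
        try:
            rough = rough_register(frames[i], acc, prior=step_prior)
            init = m_glo @ rough
            icp = icp_register(frames[i], acc, init=init,
                               max_iter=config.icp_max_iter, tol=config.icp_tol,
                               max_corr_dist=config.icp_gate_voxels * config.voxel)
        except RegistrationError as exc:
            raise StageError(f"register_frame_{i}", exc) from exc
        t_i = icp.transform
        m_temp = m_glo.inverse() @ t_i
        m_glo = m_glo @ m_temp
        seq.est_transforms[i] = m_glo
        moved = transform(frames[i], t_i)

        mesh_acc = greedy_triangulate(acc, max_edge=config.max_edge, mu=config.mu,
                                      max_nn=config.max_nn)
        mesh_new = greedy_triangulate(moved, max_edge=config.max_edge, mu=config.mu,
                                      max_nn=config.max_nn)
        if mesh_acc.n_faces and mesh_new.n_faces:
            mesh_acc, mesh_new, st = optimize_pair(mesh_acc, mesh_new, params)
            st.icp_rmse = icp.rmse  # type: ignore[attr-defined]
            pair_stats.append(st)
            cloud_a = mesh_acc.cloud(labels=acc.labels, used_only=True)
            cloud_b = mesh_new.cloud(labels=moved.labels, used_only=True)
        else:
            cloud_a, cloud_b = acc, moved
        acc = merge_downsample([cloud_a, cloud_b], voxel=config.voxel)
    return acc, pair_stats
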