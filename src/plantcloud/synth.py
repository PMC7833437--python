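"""Synthetic TOF captures of a parametric potted plant.

The generator emulates the physical rig the pipeline targets: a plant
(stem + curved leaves) on a pot and turntable, imaged by a 512×424 depth
camera about 0.75 m from the stem axis with a 30° downward tilt.  Rendering
is a perspective z-buffer rasterization of the scene triangles (exact
planar depths per pixel ray), followed by the TOF noise taxonomy:

* axial Gaussian noise along each ray;
* a low-frequency sinusoidal depth bias (the "wiggling" error of
  continuous-wave TOF sensors);
* flying pixels: rays adjacent to depth discontinuities re-emitted at a
  uniform depth between foreground and background (label FPN);
* scattered outliers uniform in a shell around the plant (label ON).

Every point carries a ground-truth class label, so valid-point percent and
noise-reduction ratios are computed exactly, without manual segmentation.
All randomness flows from one integer seed via seed-sequence splitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .core import CameraModel, Label, LabeledCloud, RigidTransform
from .errors import EmptyFrameError, InvalidInputError
from .noise import (
    DenoiseConfig,
    FpnParams,
    OutlierParams,
    PassThroughRanges,
    alignment_rotation,
    compute_mobb,
    pass_through,
)
from .registration import FrameSequence

__all__ = [
    "PlantSpec",
    "SensorNoiseSpec",
    "Scene",
    "build_scene",
    "default_camera",
    "render_frame",
    "render_sequence",
    "sample_visible_surface",
]


@dataclass
class PlantSpec:
    """Parametric plant + pot geometry (metres)."""

    n_leaves: int = 10
    leaf_length: float = 0.17
    leaf_width: float = 0.10
    leaf_curl: Tuple[float, float] = (0.04, -0.02)  # control-point z offsets
    cross_curl: float = 0.01
    stem_height: float = 0.25
    stem_radius: float = 0.004
    pot_radius: float = 0.07
    pot_height: float = 0.08
    turntable_radius: float = 0.18
    include_pot: bool = True
    include_turntable: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_leaves < 1:
            raise InvalidInputError("n_leaves must be >= 1")
        for name in ("leaf_length", "leaf_width", "stem_height", "stem_radius",
                     "pot_radius", "pot_height", "turntable_radius"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")


@dataclass
class SensorNoiseSpec:
    """TOF noise model parameters; all lengths in metres."""

    axial_sigma: float = 0.0015
    wiggle_amplitude: float = 0.001
    wiggle_frequency: float = 20.0  # cycles per metre of range
    fpn_probability: float = 0.5
    fpn_depth_jump_min: float = 0.05
    outlier_rate: float = 0.01
    outlier_shell: float = 0.10
    background_distance: float = 1.5  # wall distance from the viewpoint; 0 = no wall

    def __post_init__(self):
        if not 0.0 <= self.fpn_probability <= 1.0:
            raise InvalidInputError("fpn_probability must be in [0, 1]")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise InvalidInputError("outlier_rate must be in [0, 1]")
        if self.axial_sigma < 0 or self.wiggle_amplitude < 0:
            raise InvalidInputError("sigmas must be >= 0")

    @classmethod
    def noiseless(cls) -> "SensorNoiseSpec":
        return cls(axial_sigma=0.0, wiggle_amplitude=0.0, fpn_probability=0.0,
                   outlier_rate=0.0, background_distance=0.0)


@dataclass
class Scene:
    """Triangulated surfaces with a per-face class label (PLANT or BN)."""

    vertices: np.ndarray
    faces: np.ndarray
    face_labels: np.ndarray
    n_leaves: int = 0
    leaf_face_ranges: List[Tuple[int, int]] = field(default_factory=list)

    def plant_vertices(self) -> np.ndarray:
        plant_faces = self.faces[self.face_labels == Label.PLANT]
        return self.vertices[np.unique(plant_faces)]

    def rotated(self, angle: float, axis=(0, 0, 1), center=(0, 0, 0)) -> "Scene":
        T = RigidTransform.about_axis(axis, angle, center)
        return Scene(vertices=T.apply(self.vertices), faces=self.faces,
                     face_labels=self.face_labels, n_leaves=self.n_leaves,
                     leaf_face_ranges=list(self.leaf_face_ranges))


def _grid_faces(nu: int, nv: int, offset: int) -> np.ndarray:
    """Triangulate an (nu+1)×(nv+1) vertex grid."""
    iu, iv = np.meshgrid(np.arange(nu), np.arange(nv), indexing="ij")
    v00 = iu * (nv + 1) + iv + offset
    v01 = v00 + 1
    v10 = v00 + (nv + 1)
    v11 = v10 + 1
    tris = np.stack([np.stack([v00, v10, v11], axis=-1),
                     np.stack([v00, v11, v01], axis=-1)], axis=-2)
    return tris.reshape(-1, 3)


def _cylinder(radius: float, z0: float, z1: float, n_seg: int = 20, n_z: int = 4,
              cap_top: bool = False):
    theta = np.linspace(0.0, 2 * np.pi, n_seg + 1)
    z = np.linspace(z0, z1, n_z + 1)
    tt, zz = np.meshgrid(theta, z, indexing="ij")
    verts = np.stack([radius * np.cos(tt), radius * np.sin(tt), zz], axis=-1).reshape(-1, 3)
    faces = _grid_faces(n_seg, n_z, 0)
    if cap_top:
        center_idx = len(verts)
        verts = np.vstack([verts, [[0.0, 0.0, z1]]])
        rim = [(i * (n_z + 1) + n_z) for i in range(n_seg + 1)]
        cap = np.array([[rim[i], rim[i + 1], center_idx] for i in range(n_seg)])
        faces = np.vstack([faces, cap])
    return verts, faces


def _disk(radius: float, z: float, n_seg: int = 24):
    theta = np.linspace(0.0, 2 * np.pi, n_seg + 1)[:-1]
    verts = np.concatenate([[[0.0, 0.0, z]],
                            np.stack([radius * np.cos(theta), radius * np.sin(theta),
                                      np.full(n_seg, z)], axis=-1)])
    faces = np.array([[0, 1 + i, 1 + (i + 1) % n_seg] for i in range(n_seg)])
    return verts, faces


def _bezier(u: np.ndarray, p0: float, p1: float, p2: float, p3: float) -> np.ndarray:
    v = 1 - u
    return v ** 3 * p0 + 3 * v ** 2 * u * p1 + 3 * v * u ** 2 * p2 + u ** 3 * p3


def _leaf_surface(attach: np.ndarray, azimuth: float, spec: PlantSpec,
                  nu: int = 20, nv: int = 10):
    """Curved quadrilateral leaf patch: a cubic arc along the length, a
    parabolic curl across the width.  With zero curl the patch is a flat
    rectangle of area leaf_length × leaf_width."""
    u = np.linspace(0.0, 1.0, nu + 1)
    v = np.linspace(-0.5, 0.5, nv + 1)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    direction = np.array([np.cos(azimuth), np.sin(azimuth), 0.0])
    side = np.array([-np.sin(azimuth), np.cos(azimuth), 0.0])
    c1, c2 = spec.leaf_curl
    lift = _bezier(uu, 0.0, c1, c1 + c2, c2)
    pts = (attach[None, None, :]
           + uu[..., None] * spec.leaf_length * direction[None, None, :]
           + vv[..., None] * spec.leaf_width * side[None, None, :])
    pts[..., 2] += lift + spec.cross_curl * (2 * vv) ** 2
    return pts.reshape(-1, 3), _grid_faces(nu, nv, 0)


def build_scene(spec: PlantSpec) -> Scene:
    """Deterministic scene construction: stem + leaves (PLANT), pot and
    turntable (BN).  Identical seeds give identical vertex arrays."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))
    all_v, all_f, all_l = [], [], []
    offset = 0
    leaf_ranges = []

    def add(verts, faces, label):
        nonlocal offset
        all_v.append(verts)
        all_f.append(faces + offset)
        all_l.append(np.full(len(faces), label, dtype=np.int16))
        offset += len(verts)

    z_base = spec.pot_height if spec.include_pot else 0.0
    sv, sf = _cylinder(spec.stem_radius, z_base, z_base + spec.stem_height, n_seg=12, n_z=8)
    add(sv, sf, Label.PLANT)

    golden = np.pi * (3.0 - np.sqrt(5.0))
    phase = rng.uniform(0.0, 2 * np.pi)
    for i in range(spec.n_leaves):
        azimuth = phase + i * golden
        height = z_base + spec.stem_height * (0.35 + 0.6 * (i + 0.5) / spec.n_leaves)
        attach = np.array([spec.stem_radius * np.cos(azimuth),
                           spec.stem_radius * np.sin(azimuth), height])
        lv, lf = _leaf_surface(attach, azimuth, spec)
        f0 = sum(len(f) for f in all_f)
        add(lv, lf, Label.PLANT)
        leaf_ranges.append((f0, f0 + len(lf)))

    if spec.include_pot:
        pv, pf = _cylinder(spec.pot_radius, 0.0, spec.pot_height, n_seg=24, n_z=4, cap_top=True)
        add(pv, pf, Label.BN)
    if spec.include_turntable:
        tv, tf = _disk(spec.turntable_radius, 0.0)
        add(tv, tf, Label.BN)

    return Scene(vertices=np.concatenate(all_v), faces=np.concatenate(all_f),
                 face_labels=np.concatenate(all_l), n_leaves=spec.n_leaves,
                 leaf_face_ranges=leaf_ranges)


def default_camera(spec: PlantSpec = PlantSpec(), distance: float = 0.75,
                   tilt_deg: float = 30.0) -> CameraModel:
    """Camera ``distance`` from the stem axis, tilted down so the optical
    axis passes through the plant's mid height."""
    tilt = np.deg2rad(tilt_deg)
    z_base = spec.pot_height if spec.include_pot else 0.0
    target_z = z_base + 0.5 * spec.stem_height
    vp = np.array([0.0, -distance, target_z + distance * np.tan(tilt)])
    z_cam = np.array([0.0, np.cos(tilt), -np.sin(tilt)])
    x_cam = np.array([1.0, 0.0, 0.0])
    y_cam = np.cross(z_cam, x_cam)  # up-ish
    axes = np.stack([x_cam, y_cam, z_cam], axis=1)
    return CameraModel(viewpoint=vp, tilt_theta=tilt, axes=axes)


def _wall_triangles(camera: CameraModel, distance: float, half_extent: float = 2.0):
    center = camera.viewpoint + distance * camera.z
    u, v = camera.x, camera.y
    corners = np.array([center - half_extent * u - half_extent * v,
                        center + half_extent * u - half_extent * v,
                        center + half_extent * u + half_extent * v,
                        center - half_extent * u + half_extent * v])
    return corners, np.array([[0, 1, 2], [0, 2, 3]])


def _rasterize(verts_cam: np.ndarray, faces: np.ndarray, face_labels: np.ndarray,
               W: int, H: int, fx: float, fy: float, z_near: float = 0.05):
    """Perspective z-buffer rasterization at pixel centres.

    Returns (depth (H,W), label (H,W), hit mask).  Depth is the camera-z of
    the surface along each pixel ray (exact for planar triangles)."""
    cx, cy = (W - 1) / 2.0, (H - 1) / 2.0
    zbuf = np.full((H, W), np.inf)
    lbuf = np.full((H, W), -1, dtype=np.int16)

    fv = verts_cam[faces]  # (F, 3, 3)
    for f in range(len(faces)):
        tri = fv[f]
        if np.any(tri[:, 2] <= z_near):
            continue
        px = tri[:, 0] / tri[:, 2] * fx + cx
        py = tri[:, 1] / tri[:, 2] * fy + cy
        x0, x1 = int(np.floor(px.min())), int(np.ceil(px.max()))
        y0, y1 = int(np.floor(py.min())), int(np.ceil(py.max()))
        x0, x1 = max(x0, 0), min(x1, W - 1)
        y0, y1 = max(y0, 0), min(y1, H - 1)
        if x0 > x1 or y0 > y1:
            continue
        gx, gy = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
        # edge functions in screen space
        ax, ay = px[0], py[0]
        bx, by = px[1], py[1]
        cx2, cy2 = px[2], py[2]
        den = (by - cy2) * (ax - cx2) + (cx2 - bx) * (ay - cy2)
        if abs(den) < 1e-12:
            continue
        w0 = ((by - cy2) * (gx - cx2) + (cx2 - bx) * (gy - cy2)) / den
        w1 = ((cy2 - ay) * (gx - cx2) + (ax - cx2) * (gy - cy2)) / den
        w2 = 1.0 - w0 - w1
        inside = (w0 >= 0) & (w1 >= 0) & (w2 >= 0)
        if not inside.any():
            continue
        inv_z = w0 / tri[0, 2] + w1 / tri[1, 2] + w2 / tri[2, 2]
        z = np.where(inv_z > 0, 1.0 / np.maximum(inv_z, 1e-300), np.inf)
        sub = zbuf[y0:y1 + 1, x0:x1 + 1]
        upd = inside & (z < sub)
        sub[upd] = z[upd]
        lsub = lbuf[y0:y1 + 1, x0:x1 + 1]
        lsub[upd] = face_labels[f]
    return zbuf, lbuf, np.isfinite(zbuf)


def render_frame(scene: Scene, camera: CameraModel,
                 noise: SensorNoiseSpec = SensorNoiseSpec(),
                 resolution: Tuple[int, int] = (512, 424),
                 fov_deg: Tuple[float, float] = (70.0, 60.0),
                 seed: int = 0, frame_id: int = 0) -> LabeledCloud:
    """Render one labeled depth frame (points in world coordinates)."""
    W, H = resolution
    fov_x, fov_y = np.deg2rad(fov_deg[0]), np.deg2rad(fov_deg[1])
    fx = (W / 2.0) / np.tan(fov_x / 2.0)
    fy = (H / 2.0) / np.tan(fov_y / 2.0)

    verts = scene.vertices
    faces = scene.faces
    labels = scene.face_labels
    if noise.background_distance > 0:
        wv, wf = _wall_triangles(camera, noise.background_distance)
        wf = wf + len(verts)
        verts = np.vstack([verts, wv])
        faces = np.vstack([faces, wf])
        labels = np.concatenate([labels, np.full(2, Label.BN, dtype=np.int16)])

    verts_cam = camera.to_camera(verts)
    zbuf, lbuf, hit = _rasterize(verts_cam, faces, labels, W, H, fx, fy)
    if not hit.any():
        raise EmptyFrameError("no visible surface in the frame")

    rng = np.random.default_rng(np.random.SeedSequence([seed, frame_id, 7]))

    ys, xs = np.nonzero(hit)
    z = zbuf[ys, xs]
    cxp, cyp = (W - 1) / 2.0, (H - 1) / 2.0
    dirs = np.stack([(xs - cxp) / fx, (ys - cyp) / fy, np.ones_like(z)], axis=1)
    pt_labels = lbuf[ys, xs].astype(np.int16)

    # flying pixels at depth discontinuities: uniform depth between the two
    # sides of the jump, replacing the ray's surface return
    pix_index = np.full((H, W), -1, dtype=np.int64)
    pix_index[ys, xs] = np.arange(len(z))
    fpn_new_z = np.full(len(z), np.nan)
    if noise.fpn_probability > 0:
        zpad = zbuf
        cand = {}
        for dy, dx in ((0, 1), (1, 0)):
            a = zpad[: H - dy, : W - dx]
            b = zpad[dy:, dx:]
            finite = np.isfinite(a) & np.isfinite(b)
            jump = finite.copy()
            np.less(noise.fpn_depth_jump_min, np.abs(np.where(finite, a - b, 0.0)),
                    out=jump, where=finite)
            jy, jx = np.nonzero(jump)
            for yy, xx, yy2, xx2 in zip(jy, jx, jy + dy, jx + dx):
                lo = min(zpad[yy, xx], zpad[yy2, xx2])
                hi = max(zpad[yy, xx], zpad[yy2, xx2])
                for (py_, px_) in ((yy, xx), (yy2, xx2)):
                    k = pix_index[py_, px_]
                    if k >= 0 and k not in cand:
                        cand[k] = (lo, hi)
        if cand:
            keys = np.fromiter(cand.keys(), dtype=np.int64)
            draws = rng.random(len(keys))
            chosen = keys[draws < noise.fpn_probability]
            for k in chosen:
                lo, hi = cand[int(k)]
                fpn_new_z[k] = rng.uniform(lo, hi)

    is_fpn = np.isfinite(fpn_new_z)
    z_eff = np.where(is_fpn, fpn_new_z, z)
    pt_labels = np.where(is_fpn, np.int16(Label.FPN), pt_labels)

    pts_cam = dirs * z_eff[:, None]
    rng_axial = np.random.default_rng(np.random.SeedSequence([seed, frame_id, 11]))
    if noise.axial_sigma > 0 or noise.wiggle_amplitude > 0:
        rho = np.linalg.norm(pts_cam, axis=1)
        delta = noise.wiggle_amplitude * np.sin(2 * np.pi * noise.wiggle_frequency * rho)
        if noise.axial_sigma > 0:
            delta = delta + rng_axial.normal(scale=noise.axial_sigma, size=len(rho))
        pts_cam = pts_cam * ((rho + delta) / rho)[:, None]

    points = camera.to_world(pts_cam)
    out_labels = pt_labels

    if noise.outlier_rate > 0:
        n_out = int(round(noise.outlier_rate * len(points)))
        if n_out:
            rng_on = np.random.default_rng(np.random.SeedSequence([seed, frame_id, 13]))
            plant_v = scene.plant_vertices()
            center = plant_v.mean(axis=0)
            r_plant = float(np.linalg.norm(plant_v - center, axis=1).max())
            u = rng_on.normal(size=(n_out, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            radii = rng_on.uniform(r_plant, r_plant + noise.outlier_shell, size=n_out)
            on_pts = center + u * radii[:, None]
            points = np.vstack([points, on_pts])
            out_labels = np.concatenate([out_labels, np.full(n_out, Label.ON, dtype=np.int16)])

    return LabeledCloud(points=points, labels=out_labels, frame_id=frame_id)


def render_sequence(scene: Scene, camera: CameraModel,
                    noise: SensorNoiseSpec = SensorNoiseSpec(),
                    n_frames: int = 8,
                    resolution: Tuple[int, int] = (512, 424),
                    fov_deg: Tuple[float, float] = (70.0, 60.0),
                    seed: int = 0) -> FrameSequence:
    """Turntable sequence: frame i is the scene rotated by i·360°/n about
    the vertical axis.  gt_transforms[i] maps frame i into frame 0's
    coordinates (rotation by −i·360°/n)."""
    if n_frames < 1:
        raise InvalidInputError("n_frames must be >= 1")
    frames, gts = [], []
    for i in range(n_frames):
        angle = 2 * np.pi * i / n_frames
        fr = render_frame(scene.rotated(angle), camera, noise, resolution=resolution,
                          fov_deg=fov_deg, seed=seed, frame_id=i)
        frames.append(fr)
        gts.append(RigidTransform.about_axis([0, 0, 1], -angle))
    return FrameSequence(frames=frames, gt_transforms=gts)


def leaf_surface_points(n: int = 2500, spec: PlantSpec = PlantSpec(), seed: int = 0,
                        attach=(0.0, 0.0, 0.2), azimuth: float = 0.0):
    """Random samples of one parametric leaf surface with analytic normals
    (numerical partials of the parametrization)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))
    u = rng.uniform(0.0, 1.0, n)
    v = rng.uniform(-0.5, 0.5, n)
    attach = np.asarray(attach, dtype=np.float64)

    def param(uu, vv):
        direction = np.array([np.cos(azimuth), np.sin(azimuth), 0.0])
        side = np.array([-np.sin(azimuth), np.cos(azimuth), 0.0])
        c1, c2 = spec.leaf_curl
        lift = _bezier(uu, 0.0, c1, c1 + c2, c2)
        p = (attach[None, :] + uu[:, None] * spec.leaf_length * direction[None, :]
             + vv[:, None] * spec.leaf_width * side[None, :])
        p[:, 2] += lift + spec.cross_curl * (2 * vv) ** 2
        return p

    pts = param(u, v)
    eps = 1e-6
    du = (param(u + eps, v) - param(u - eps, v)) / (2 * eps)
    dv = (param(u, v + eps) - param(u, v - eps)) / (2 * eps)
    nrm = np.cross(du, dv)
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
    return pts, nrm


def leaf_surface_grid(n_u: int = 400, n_v: int = 200, spec: PlantSpec = PlantSpec(),
                      attach=(0.0, 0.0, 0.2), azimuth: float = 0.0) -> np.ndarray:
    """Dense regular (u, v) sampling of the parametric leaf — the reference
    surface for point-to-surface distance measurements (regular spacing
    keeps the nearest-sample error uniform across the surface)."""
    attach = np.asarray(attach, dtype=np.float64)
    u = np.linspace(0.0, 1.0, n_u)
    v = np.linspace(-0.5, 0.5, n_v)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    direction = np.array([np.cos(azimuth), np.sin(azimuth), 0.0])
    side = np.array([-np.sin(azimuth), np.cos(azimuth), 0.0])
    c1, c2 = spec.leaf_curl
    lift = _bezier(uu, 0.0, c1, c1 + c2, c2)
    p = (attach[None, None, :] + uu[..., None] * spec.leaf_length * direction[None, None, :]
         + vv[..., None] * spec.leaf_width * side[None, None, :])
    p[..., 2] += lift + spec.cross_curl * (2 * vv) ** 2
    return p.reshape(-1, 3)


def layered_leaf_clouds(offset: float = 0.003, noise_sigma: float = 0.0005,
                        n: int = 2500, seed: int = 0,
                        spec: PlantSpec = PlantSpec()):
    """Two-layer leaf fixture: the layered-point situation left behind by
    imperfect registration.  Two noisy samplings of the same leaf surface
    sit at ±offset/2 along the surface normal; the surface itself is the
    ground truth.  Returns (cloud_a, cloud_b, surface_points)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 37]))
    pts_a, nrm_a = leaf_surface_points(n, spec, seed=seed + 1)
    pts_b, nrm_b = leaf_surface_points(n, spec, seed=seed + 2)
    a = pts_a + 0.5 * offset * nrm_a + rng.normal(scale=noise_sigma, size=pts_a.shape)
    b = pts_b - 0.5 * offset * nrm_b + rng.normal(scale=noise_sigma, size=pts_b.shape)
    surface = leaf_surface_grid(spec=spec)
    return (LabeledCloud(points=a, labels=np.full(n, Label.PLANT, dtype=np.int16), frame_id=0),
            LabeledCloud(points=b, labels=np.full(n, Label.PLANT, dtype=np.int16), frame_id=1),
            surface)


def two_plane_edge_scene(foreground_depth: float = 0.75, background_depth: float = 1.2,
                         half_width: float = 0.3) -> Tuple[Scene, CameraModel]:
    """Flying-pixel fixture: a foreground plane covering the left half of
    the view and a background plane behind it, separated by a vertical
    depth edge (the foreground spans the whole vertical field of view, so
    the only depth discontinuities are vertical silhouette edges — the
    geometry the view-angle test is designed for).  Foreground faces carry
    label PLANT and background faces BN so surface-vs-FPN bookkeeping stays
    trivial."""
    cam = CameraModel(viewpoint=np.zeros(3), tilt_theta=0.0, axes=np.eye(3))

    def quad(x0, x1, y0, y1, z):
        v = np.array([[x0, y0, z], [x1, y0, z], [x1, y1, z], [x0, y1, z]])
        f = np.array([[0, 1, 2], [0, 2, 3]])
        return v, f

    y_half_fg = foreground_depth * 1.3  # beyond the vertical FOV
    fv, ff = quad(-half_width, 0.0, -y_half_fg, y_half_fg, foreground_depth)
    bscale = background_depth * 1.6
    bv, bf = quad(-bscale, bscale, -bscale, bscale, background_depth)
    verts = np.vstack([fv, bv])
    faces = np.vstack([ff, bf + 4])
    labels = np.array([Label.PLANT, Label.PLANT, Label.BN, Label.BN], dtype=np.int16)
    return Scene(vertices=verts, faces=faces, face_labels=labels), cam


def noisy_plane_cloud(n_side: int = 60, spacing: float = 0.001, noise_sigma: float = 0.0005,
                      seed: int = 0) -> Tuple[LabeledCloud, np.ndarray]:
    """Plane z = 0 sampled on a grid with Gaussian z-noise; returns the
    cloud (true plane normals attached) and the noiseless z values."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 41]))
    xx, yy = np.meshgrid(np.arange(n_side), np.arange(n_side), indexing="ij")
    pts = np.stack([xx.ravel() * spacing, yy.ravel() * spacing,
                    np.zeros(n_side * n_side)], axis=1)
    pts[:, 2] += rng.normal(scale=noise_sigma, size=len(pts))
    normals = np.tile([0.0, 0.0, 1.0], (len(pts), 1))
    return LabeledCloud(points=pts, normals=normals), np.zeros(len(pts))


def step_edge_cloud(n_side: int = 50, spacing: float = 0.001, step: float = 0.02,
                    noise_sigma: float = 0.0005, seed: int = 0) -> Tuple[LabeledCloud, np.ndarray]:
    """Two parallel half-planes ``step`` apart with Gaussian z-noise; the
    edge-preservation fixture.  Returns (cloud, noiseless z)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 43]))
    xx, yy = np.meshgrid(np.arange(n_side), np.arange(n_side), indexing="ij")
    z_true = np.where(xx.ravel() < n_side // 2, 0.0, step)
    pts = np.stack([xx.ravel() * spacing, yy.ravel() * spacing, z_true.copy()], axis=1)
    pts[:, 2] += rng.normal(scale=noise_sigma, size=len(pts))
    normals = np.tile([0.0, 0.0, 1.0], (len(pts), 1))
    return LabeledCloud(points=pts, normals=normals), z_true


def pixel_footprint(camera_distance: float = 0.75, resolution_x: int = 512,
                    fov_x_deg: float = 70.0) -> float:
    """Lateral spacing of adjacent rays at the working distance — the scale
    every density-sensitive parameter must be matched to."""
    return 2.0 * camera_distance * np.tan(np.deg2rad(fov_x_deg) / 2.0) / resolution_x


def calibrate_denoise_config(scene: Scene, camera: CameraModel,
                             resolution: Tuple[int, int] = (320, 264),
                             fov_deg: Tuple[float, float] = (70.0, 60.0),
                             margin: float = 0.015,
                             pot_margin: float = 0.003,
                             pre_crop_depth: Tuple[float, float] = (0.2, 1.2)) -> DenoiseConfig:
    """Calibrate the denoising configuration for a rig from one noiseless
    reference capture — the synthetic analogue of choosing pass-through
    thresholds that 'preserve a complete plant' on a manually segmented
    benchmark frame.

    The pass-through intervals are the rectified-frame bounding box of the
    reference frame's plant points plus ``margin``, except on the face
    toward the pot where the stem base sits exactly at the pot plane and a
    tight ``pot_margin`` is used (crop thresholds are naturally asymmetric
    on the vertical axis).  The outlier radius is matched to the pixel
    footprint at the plant distance.
    """
    clean = render_frame(scene, camera, SensorNoiseSpec.noiseless(),
                         resolution=resolution, fov_deg=fov_deg, seed=0)
    pre = PassThroughRanges((-0.8, 0.8), (-0.8, 0.8), pre_crop_depth)
    cam_pts = camera.to_camera(clean.points)
    local = LabeledCloud(points=cam_pts, labels=clean.labels)
    local = pass_through(local, pre)
    box = compute_mobb(local)
    cam_here = CameraModel(viewpoint=np.zeros(3), tilt_theta=camera.tilt_theta, axes=np.eye(3))
    sol = alignment_rotation(box, cam_here)
    R = sol.rotation.rotation
    plant = local.points[local.labels == Label.PLANT]
    plant_rect = (plant - box.center) @ R.T + box.center
    lo = plant_rect.min(axis=0) - margin
    hi = plant_rect.max(axis=0) + margin

    # tighten the face toward the pot: world-down in the rectified frame
    down = R @ (camera.axes.T @ np.array([0.0, 0.0, -1.0]))
    k = int(np.argmax(np.abs(down)))
    if down[k] > 0:
        hi[k] = plant_rect[:, k].max() + pot_margin
    else:
        lo[k] = plant_rect[:, k].min() - pot_margin

    foot = pixel_footprint(float(np.linalg.norm(camera.viewpoint[:2])), resolution[0], fov_deg[0])
    outlier = OutlierParams(radius=3.5 * foot, k_min=4, n_sigma=2.0)
    return DenoiseConfig(
        ranges=PassThroughRanges((lo[0], hi[0]), (lo[1], hi[1]), (lo[2], hi[2])),
        outlier=outlier,
        fpn=FpnParams(),
        normal_k=30,
        rectify=True,
        pre_crop=pre,
    )


def standard_denoise_setup(seed: int = 0, resolution: Tuple[int, int] = (320, 264)):
    """The standard labeled synthetic frame plus a calibrated configuration:
    plant on pot/turntable, background wall, axial + wiggle noise, flying
    pixels and outliers at the generator defaults.

    Returns (frame, camera, config, scene).
    """
    spec = PlantSpec(seed=0)
    scene = build_scene(spec)
    camera = default_camera(spec)
    noise = SensorNoiseSpec()
    frame = render_frame(scene, camera, noise, resolution=resolution, seed=seed)
    config = calibrate_denoise_config(scene, camera, resolution=resolution)
    return frame, camera, config, scene


def sample_visible_surface(scene: Scene, camera: CameraModel, n_frames: int = 8,
                           resolution: Tuple[int, int] = (256, 212),
                           fov_deg: Tuple[float, float] = (70.0, 60.0),
                           label: Optional[int] = None) -> np.ndarray:
    """Ground-truth sampling of the surface actually observable over a
    noise-free turntable sweep, expressed in frame-0 coordinates; the
    reference set for chamfer evaluation of reconstructed clouds."""
    pts = []
    for i in range(n_frames):
        angle = 2 * np.pi * i / n_frames
        fr = render_frame(scene.rotated(angle), camera, SensorNoiseSpec.noiseless(),
                          resolution=resolution, fov_deg=fov_deg, seed=0, frame_id=i)
        back = RigidTransform.about_axis([0, 0, 1], -angle)
        cloud = fr if label is None else fr.select(fr.labels == label)
        pts.append(back.apply(cloud.points))
    return np.concatenate(pts, axis=0)
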