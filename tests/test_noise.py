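"""Single-frame noise removal: MOBB, pose alignment, pass-through,
radius-density filter, flying-pixel test, full stage composition."""

import dataclasses

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from plantcloud import (
    CameraModel,
    FpnParams,
    Label,
    LabeledCloud,
    OutlierParams,
    PassThroughRanges,
    RigidTransform,
    alignment_rotation,
    boundary_precheck,
    compute_mobb,
    denoise_frame,
    estimate_normals,
    pass_through,
    radius_density_filter,
    remove_flying_pixels,
    transform,
)
from plantcloud.errors import (
    DegenerateGeometryError,
    InvalidInputError,
    InvalidParameterError,
)
from plantcloud.noise import tilt_from_object_angle
from plantcloud.evaluation import vpp

CUBE_CORNERS = np.array([[x, y, z] for x in (0, 1.0) for y in (0, 1.0) for z in (0, 1.0)])


class TestMobb:
    def test_axis_aligned_unit_cube(self):
        box = compute_mobb(CUBE_CORNERS)
        assert np.allclose(np.sort(box.extents), [1, 1, 1], atol=1e-9)
        assert box.volume == pytest.approx(1.0, abs=1e-9)

    def test_rotated_cube_recovers_unit_volume(self):
        T = RigidTransform.about_axis([0, 0, 1], np.deg2rad(30))
        box = compute_mobb(T.apply(CUBE_CORNERS))
        assert box.volume == pytest.approx(1.0, rel=0.05)

    def test_contains_all_input_points(self):
        rng = np.random.default_rng(0)
        pts = rng.random((200, 3)) * [0.4, 0.2, 0.1]
        T = RigidTransform.about_axis(rng.normal(size=3), 1.0)
        pts = T.apply(pts)
        box = compute_mobb(pts)
        assert box.contains(pts, tol=1e-9).all()

    def test_coplanar_input_rejected(self):
        pts = np.column_stack([np.random.default_rng(1).random((10, 2)), np.zeros(10)])
        with pytest.raises(DegenerateGeometryError):
            compute_mobb(pts)

    def test_three_points_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            compute_mobb(np.eye(3))

    def test_volume_rotation_invariant(self):
        """MOBB volume changes by <1% under random rigid motions."""
        rng = np.random.default_rng(5)
        base = np.vstack([CUBE_CORNERS * [0.3, 0.15, 0.08],
                          rng.random((100, 3)) * [0.3, 0.15, 0.08]])
        v0 = compute_mobb(base).volume
        for _ in range(50):
            T = RigidTransform(
                rotation=RigidTransform.about_axis(rng.normal(size=3),
                                                   rng.uniform(0, np.pi)).rotation,
                translation=rng.normal(size=3))
            v = compute_mobb(T.apply(base)).volume
            assert abs(v - v0) / v0 < 0.01


class TestAlignment:
    def test_already_aligned_gives_identity(self):
        from plantcloud.noise import OrientedBox

        box = OrientedBox(center=np.zeros(3), axes=np.eye(3), extents=[1, 2, 3])
        cam = CameraModel(viewpoint=[0, 0, -1])
        sol = alignment_rotation(box, cam)
        assert sol.beta == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(sol.rotation.rotation, np.eye(3), atol=1e-12)

    def test_planar_ideal_case_rotation_equals_tilt(self):
        """Box tilted by the camera tilt angle: the alignment rotation angle
        equals the tilt (theta = beta in the ideal construction)."""
        from plantcloud.noise import OrientedBox

        theta = np.deg2rad(30.0)
        R = RigidTransform.about_axis([1, 0, 0], theta).rotation
        box = OrientedBox(center=np.zeros(3), axes=R, extents=[1, 2, 3])
        cam = CameraModel(viewpoint=[0, 0, -1], tilt_theta=theta)
        sol = alignment_rotation(box, cam)
        assert np.rad2deg(sol.beta) == pytest.approx(30.0, abs=1e-9)
        assert sol.beta2 == pytest.approx(np.pi / 2 - theta + sol.alpha, abs=1e-12)

    def test_tilt_from_object_angle(self):
        assert np.rad2deg(tilt_from_object_angle(np.deg2rad(50))) == pytest.approx(40.0)


class TestPassThrough:
    RANGES = PassThroughRanges.from_cm((-9, 40), (-25, 50), (35, 70))

    def test_point_inside_camera_working_volume_kept(self):
        cloud = LabeledCloud(points=[[0.0, 0.0, 0.50]])
        assert len(pass_through(cloud, self.RANGES)) == 1

    def test_point_beyond_depth_window_removed(self):
        cloud = LabeledCloud(points=[[0.0, 0.0, 0.80]])
        assert len(pass_through(cloud, self.RANGES)) == 0

    def test_disjoint_ranges_give_empty_cloud(self):
        cloud = LabeledCloud(points=np.random.default_rng(0).random((50, 3)))
        ranges = PassThroughRanges((5, 6), (5, 6), (5, 6))
        assert len(pass_through(cloud, ranges)) == 0

    def test_order_preserved(self):
        pts = np.array([[0, 0, 0.4], [0, 0, 2.0], [0.1, 0.1, 0.5], [0, 0, 0.69]])
        out = pass_through(LabeledCloud(points=pts), self.RANGES)
        assert np.array_equal(out.points, pts[[0, 2, 3]])

    def test_invalid_interval_rejected(self):
        with pytest.raises(InvalidParameterError):
            PassThroughRanges((1, 0), (0, 1), (0, 1))


def _block(spacing=0.01, n=6):
    g = np.arange(n) * spacing
    xx, yy, zz = np.meshgrid(g, g, g, indexing="ij")
    return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])


class TestBoundaryPrecheck:
    PARAMS = OutlierParams(radius=0.02, k_min=3, n_sigma=2.0)

    def test_clean_block_unchanged(self):
        cloud = LabeledCloud(points=_block())
        out = boundary_precheck(cloud, self.PARAMS)
        assert np.array_equal(out.points, cloud.points)

    def test_single_isolated_extreme_removed(self):
        pts = _block()
        outlier = pts[:, 0].max() + 0.10
        cloud = LabeledCloud(points=np.vstack([pts, [[outlier, 0.02, 0.02]]]))
        out = boundary_precheck(cloud, self.PARAMS)
        assert len(out) == len(pts)
        assert out.points[:, 0].max() < outlier

    def test_two_isolated_extremes_removed(self):
        pts = _block()
        extras = np.array([[pts[:, 0].max() + 0.10, 0.02, 0.02],
                           [0.02, 0.02, pts[:, 2].min() - 0.10]])
        cloud = LabeledCloud(points=np.vstack([pts, extras]))
        out = boundary_precheck(cloud, self.PARAMS)
        assert len(out) == len(pts)

    def test_too_few_points_rejected(self):
        with pytest.raises(InvalidInputError):
            boundary_precheck(LabeledCloud(points=np.zeros((5, 3))), self.PARAMS)


class TestRadiusDensityFilter:
    def test_uniform_grid_interior_kept(self):
        g = np.arange(10) * 0.001
        xx, yy, zz = np.meshgrid(g, g, g, indexing="ij")
        pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
        params = OutlierParams(radius=0.002, k_min=4, n_sigma=2.0)
        kept, removed, report = radius_density_filter(LabeledCloud(points=pts), params)
        interior = np.all((pts > 0.0005) & (pts < 0.0085), axis=1)
        kept_set = {tuple(p) for p in kept.points}
        assert all(tuple(p) in kept_set for p in pts[interior])
        assert report.kept_count + report.removed_count == len(pts)

    def test_isolated_point_removed(self):
        g = np.arange(10) * 0.001
        xx, yy, zz = np.meshgrid(g, g, g, indexing="ij")
        pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
        pts = np.vstack([pts, [[0.1, 0.1, 0.1]]])
        params = OutlierParams(radius=0.002, k_min=4, n_sigma=2.0)
        kept, removed, _ = radius_density_filter(LabeledCloud(points=pts), params)
        assert len(removed) >= 1
        assert any(np.allclose(p, [0.1, 0.1, 0.1]) for p in removed.points)

    def test_matches_bruteforce_partition(self):
        rng = np.random.default_rng(9)
        pts = rng.uniform(0, 0.05, (300, 3))
        params = OutlierParams(radius=0.005, k_min=4, n_sigma=2.0)
        kept, removed, _ = radius_density_filter(LabeledCloud(points=pts), params)

        d = cdist(pts, pts)
        np.fill_diagonal(d, np.inf)
        within = d <= params.radius
        K = within.sum(axis=1)
        dbar = np.where(K > 0, np.where(within, d, 0).sum(axis=1) / np.maximum(K, 1), np.inf)
        finite = np.isfinite(dbar)
        mu, sigma = dbar[finite].mean(), dbar[finite].std()
        bad = (dbar > mu + 2.0 * sigma) | (K < 4)
        assert np.array_equal(kept.points, pts[~bad])
        assert np.array_equal(removed.points, pts[bad])

    def test_strict_literal_inequality_mode(self):
        """The printed conjunction removes only dense points with large d̄."""
        rng = np.random.default_rng(10)
        pts = rng.uniform(0, 0.05, (200, 3))
        params = OutlierParams(radius=0.005, k_min=4, n_sigma=1.0,
                               strict_paper_inequality=True)
        kept, removed, _ = radius_density_filter(LabeledCloud(points=pts), params)
        if len(removed):
            from plantcloud.noise import _density_stats

            K, dbar, mu, sigma = _density_stats(pts, params.radius)
            removed_idx = [i for i, p in enumerate(pts)
                           if any(np.array_equal(p, q) for q in removed.points)]
            assert all(K[i] > params.k_min for i in removed_idx)

    def test_density_criterion_idempotent(self):
        """Re-running on `kept` removes no further density-floor points
        (holds when the cloud is clearly denser than the floor, so the
        removed isolated points are not load-bearing neighbors)."""
        rng = np.random.default_rng(11)
        g = np.arange(10) * 0.002
        xx, yy, zz = np.meshgrid(g, g, g, indexing="ij")
        block = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
        isolated = rng.uniform(0.1, 0.2, (30, 3))
        pts = np.vstack([block, isolated])
        params = OutlierParams(radius=0.006, k_min=4, n_sigma=1e9)  # density path only
        kept, removed, _ = radius_density_filter(LabeledCloud(points=pts), params)
        assert len(removed) > 0  # the isolated points actually exercised the floor
        kept2, removed2, _ = radius_density_filter(kept, params)
        assert len(removed2) == 0

    def test_invalid_radius_rejected(self):
        with pytest.raises(InvalidParameterError):
            OutlierParams(radius=-0.001)


class TestFlyingPixels:
    def test_normal_parallel_to_ray_kept(self):
        cam = CameraModel(viewpoint=np.zeros(3))
        cloud = LabeledCloud(points=[[0, 0, 1.0]], normals=[[0, 0, 1.0]])
        kept, removed = remove_flying_pixels(cloud, cam)
        assert len(kept) == 1 and len(removed) == 0

    def test_normal_perpendicular_to_ray_removed(self):
        cam = CameraModel(viewpoint=np.zeros(3))
        cloud = LabeledCloud(points=[[0, 0, 1.0]], normals=[[1.0, 0, 0]])
        kept, removed = remove_flying_pixels(cloud, cam, FpnParams())
        assert len(removed) == 1

    def test_missing_normals_rejected(self):
        with pytest.raises(InvalidInputError):
            remove_flying_pixels(LabeledCloud(points=[[0, 0, 1]]),
                                 CameraModel(viewpoint=np.zeros(3)))

    def test_dense_ray_curtain_removed(self):
        """Points strung densely along view rays (estimated normals) are
        removed while a fronto-parallel wall survives."""
        rng = np.random.default_rng(12)
        cam = CameraModel(viewpoint=np.zeros(3))
        # curtain: the vertical epipolar plane x=0, depths 0.8-1.1
        ys = rng.uniform(-0.2, 0.2, 3000)
        zs = rng.uniform(0.8, 1.1, 3000)
        curtain = np.column_stack([np.zeros(3000), ys, zs])
        # wall at z=1.3
        wall = np.column_stack([rng.uniform(0.05, 0.4, 3000),
                                rng.uniform(-0.2, 0.2, 3000), np.full(3000, 1.3)])
        cloud = LabeledCloud(points=np.vstack([curtain, wall]),
                             labels=np.r_[np.full(3000, Label.FPN, dtype=np.int16),
                                          np.full(3000, Label.BN, dtype=np.int16)])
        withn = estimate_normals(cloud, k=12, camera=cam)
        kept, removed = remove_flying_pixels(withn, cam, FpnParams())
        fpn_removed = (removed.labels == Label.FPN).sum() / 3000
        wall_removed = (removed.labels == Label.BN).sum() / 3000
        assert fpn_removed >= 0.90
        assert wall_removed <= 0.02

    def test_invariance_under_joint_rigid_transform(self):
        rng = np.random.default_rng(13)
        pts = rng.random((200, 3)) + [0, 0, 1.0]
        normals = rng.normal(size=(200, 3))
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        cloud = LabeledCloud(points=pts, normals=normals)
        cam = CameraModel(viewpoint=np.zeros(3))
        k0, r0 = remove_flying_pixels(cloud, cam, FpnParams(mode="full_3d"))
        T = RigidTransform.about_axis(rng.normal(size=3), 1.2, center=[1, 2, 3])
        cam_t = CameraModel(viewpoint=T.apply(cam.viewpoint[None])[0],
                            axes=T.rotation @ cam.axes)
        k1, r1 = remove_flying_pixels(transform(cloud, T), cam_t, FpnParams(mode="full_3d"))
        assert len(k0) == len(k1) and len(r0) == len(r1)


class TestDenoiseFrame:
    def test_matches_manual_stage_sequence(self, standard_frame):
        """denoise_frame equals sequential application of its stages."""
        frame = standard_frame["frame"]
        camera = standard_frame["camera"]
        config = standard_frame["config"]
        clean, reports = denoise_frame(frame, camera, config)

        from plantcloud.noise import OrientedBox  # noqa: F401 (stage replication)

        cur = frame.with_(points=camera.to_camera(frame.points))
        cur = pass_through(cur, config.pre_crop)
        cur = boundary_precheck(cur, config.outlier)
        box = compute_mobb(cur)
        cam0 = CameraModel(viewpoint=np.zeros(3), tilt_theta=camera.tilt_theta)
        sol = alignment_rotation(box, cam0)
        R = sol.rotation.rotation
        T = RigidTransform(rotation=R, translation=box.center - R @ box.center)
        cur = transform(cur, T)
        vp = T.apply(np.zeros(3))
        cur = pass_through(cur, config.ranges)
        cur, _, _ = radius_density_filter(cur, config.outlier)
        cam_loc = CameraModel(viewpoint=vp, tilt_theta=camera.tilt_theta, axes=R)
        cur = estimate_normals(cur, k=config.normal_k, camera=cam_loc)
        cur, _ = remove_flying_pixels(cur, cam_loc, config.fpn)
        assert np.allclose(clean.points, cur.points, atol=1e-12)

    def test_rectified_keeps_at_least_as_many_plant_points(self):
        """A tall plant in a tilted pose (its axis not perpendicular to the
        camera projection): pose-rectified cropping keeps at least as many
        ground-truth plant points as cropping the tilted cloud directly."""
        from plantcloud.synth import (
            PlantSpec,
            SensorNoiseSpec,
            build_scene,
            calibrate_denoise_config,
            default_camera,
            render_frame,
        )

        spec = PlantSpec(n_leaves=6, leaf_length=0.08, leaf_width=0.05,
                         stem_height=0.35, include_pot=False,
                         include_turntable=False, seed=0)
        scene = build_scene(spec).rotated(np.deg2rad(20.0), axis=(1, 0, 0),
                                          center=(0, 0, 0.2))
        camera = default_camera(spec)
        noise = SensorNoiseSpec(axial_sigma=0.0015, fpn_probability=0.0, outlier_rate=0.0,
                                background_distance=0.0)
        frame = render_frame(scene, camera, noise, resolution=(320, 264), seed=2)
        config = calibrate_denoise_config(scene, camera, resolution=(320, 264))
        clean_r, _ = denoise_frame(frame, camera, config)
        clean_u, _ = denoise_frame(frame, camera, dataclasses.replace(config, rectify=False))
        assert (clean_r.labels == Label.PLANT).sum() >= (clean_u.labels == Label.PLANT).sum()

    def test_noise_free_frame_retention(self, plant_only_scene):
        """With sensor noise off and no background, the geometric stages
        (crop, rectification, flying-pixel test) retain ≥99% of the clean
        points.  The statistical distance trim is neutralized: a relative
        μ+nσ criterion removes its tail on any input by construction."""
        from plantcloud.synth import SensorNoiseSpec, calibrate_denoise_config, render_frame

        scene, camera = plant_only_scene["scene"], plant_only_scene["camera"]
        frame = render_frame(scene, camera, SensorNoiseSpec.noiseless(),
                             resolution=(320, 264), seed=0)
        config = calibrate_denoise_config(scene, camera, resolution=(320, 264))
        config = dataclasses.replace(
            config, outlier=dataclasses.replace(config.outlier, k_min=1, n_sigma=8.0))
        clean, _ = denoise_frame(frame, camera, config)
        assert len(clean) / len(frame) >= 0.99

    def test_small_cloud_rejected(self):
        cam = CameraModel(viewpoint=np.zeros(3))
        cfg_ranges = PassThroughRanges((-1, 1), (-1, 1), (-1, 1))
        from plantcloud import DenoiseConfig

        with pytest.raises(InvalidInputError):
            denoise_frame(LabeledCloud(points=np.random.default_rng(0).random((50, 3))),
                          cam, DenoiseConfig(ranges=cfg_ranges))
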