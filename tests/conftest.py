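"""Shared fixtures.

Heavy synthetic-scene computations are session-scoped so unit tests and the
acceptance suite share one run.  Fixture seeds are fixed: the suites verify
properties of the method under the documented study conditions, not under
arbitrary randomness.
"""

import numpy as np
import pytest

from plantcloud import (
    Label,
    OptimizeParams,
    denoise_frame,
    greedy_triangulate,
    optimize_pair,
)
from plantcloud.synth import (
    PlantSpec,
    SensorNoiseSpec,
    build_scene,
    default_camera,
    layered_leaf_clouds,
    render_frame,
    standard_denoise_setup,
)

SEED = 1


@pytest.fixture(scope="session")
def fixture_opt_params():
    # discrete meshes are parallel within the normal-jitter scale
    return OptimizeParams(parallel_eps=float(np.sin(np.deg2rad(5.0))))


@pytest.fixture(scope="session")
def standard_frame():
    """The standard noisy synthetic capture plus its calibrated config."""
    frame, camera, config, scene = standard_denoise_setup(seed=SEED)
    return {"frame": frame, "camera": camera, "config": config, "scene": scene}


@pytest.fixture(scope="session")
def denoised_standard_frame(standard_frame):
    clean, reports = denoise_frame(standard_frame["frame"], standard_frame["camera"],
                                   standard_frame["config"])
    return {"clean": clean, "reports": reports, **standard_frame}


@pytest.fixture(scope="session")
def plant_only_scene():
    spec = PlantSpec(include_pot=False, include_turntable=False, seed=0)
    scene = build_scene(spec)
    return {"spec": spec, "scene": scene, "camera": default_camera(spec)}


@pytest.fixture(scope="session")
def layered_leaf_fixture(fixture_opt_params):
    """Noisy two-layer leaf fixture with its triangulations and the
    optimized result (shared by ratio/monotonicity tests)."""
    a, b, surface = layered_leaf_clouds(offset=0.003, noise_sigma=0.0002, n=1200, seed=SEED)
    mesh_a = greedy_triangulate(a, max_edge=0.010, mu=3.0)
    mesh_b = greedy_triangulate(b, max_edge=0.010, mu=3.0)
    opt_a, opt_b, stats = optimize_pair(mesh_a, mesh_b, fixture_opt_params)
    return {"a": a, "b": b, "surface": surface, "mesh_a": mesh_a, "mesh_b": mesh_b,
            "opt_a": opt_a, "opt_b": opt_b, "stats": stats}


@pytest.fixture(scope="session")
def two_plane_frame():
    from plantcloud.synth import two_plane_edge_scene

    scene, camera = two_plane_edge_scene()
    noise = SensorNoiseSpec(axial_sigma=0.0005, wiggle_amplitude=0.0, fpn_probability=1.0,
                            outlier_rate=0.0, background_distance=0.0)
    frame = render_frame(scene, camera, noise, resolution=(512, 424), seed=SEED)
    return {"scene": scene, "camera": camera, "frame": frame}
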