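"""Shared fixtures: textures, synthetic scenes and a full pipeline run."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest
from scipy import ndimage

from ms3d import imreg, pipeline as pl, pointcloud as pc, synth, turntable as tt


def make_texture(seed: int, shape=(128, 128), smooth: float = 2.0) -> np.ndarray:
    """Band-limited random texture in [0, 1]."""
    rng = np.random.default_rng(seed)
    t = ndimage.gaussian_filter(rng.standard_normal(shape), smooth)
    return (t - t.min()) / np.ptp(t)


@pytest.fixture(scope="session")
def texture() -> np.ndarray:
    return make_texture(0)


@pytest.fixture(scope="session")
def scene() -> synth.SyntheticScene:
    return synth.make_scene(seed=11)


@pytest.fixture(scope="session")
def dense_reference_surface(scene) -> np.ndarray:
    """True scene surface, densely resampled, in the reconstruction frame."""
    dense = synth.make_scene(
        replace(scene.params, point_spacing=0.0006), seed=scene.seed
    )
    return synth.true_surface_in_common_frame(dense)


@pytest.fixture(scope="session")
def calibration(scene):
    k = scene.params.intrinsics
    r0 = synth.render_view(scene, 0.0, noise_seed=71, table_only=True)
    r180 = synth.render_view(scene, 180.0, noise_seed=72, table_only=True)
    calib, info = tt.calibrate_from_views(
        pc.unproject(r0.depth_mm, k, rgb=r0.rgb),
        pc.unproject(r180.depth_mm, k, rgb=r180.rgb),
    )
    return calib, info


@pytest.fixture(scope="session")
def sensor_transform(scene) -> imreg.RegistrationTransform2D:
    board, moving = synth.render_calibration_pair(scene, noise_seed=5)
    return imreg.estimate_similarity(board, moving)


@pytest.fixture(scope="session")
def rendered_views(scene) -> list[synth.ViewRender]:
    return [
        synth.render_view(scene, vi * 90.0, noise_seed=300 + vi) for vi in range(4)
    ]


@pytest.fixture(scope="session")
def pipeline_result(scene, calibration, sensor_transform, rendered_views):
    """One full 4-view reconstruction shared by the end-to-end tests."""
    cfg = pl.PipelineConfig(intrinsics=scene.params.intrinsics)
    views = [
        pl.ViewInput(rgb=r.rgb, depth_mm=r.depth_mm, cube=r.cube)
        for r in rendered_views
    ]
    return pl.run_pipeline(cfg, views, calibration[0], sensor_transform)
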