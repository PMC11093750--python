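import numpy as np
import pytest

from emflight.geometry import FramedCurve, fit_bspline
from emflight.synthetic import SceneConfig, generate_scene, straight_tube_scene


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def straight_curve():
    """A straight 30 um centerline along x."""
    nodes = np.stack([np.linspace(0, 30, 12), np.zeros(12), np.zeros(12)], axis=1)
    return fit_bspline(nodes, degree=4)


@pytest.fixture(scope="session")
def straight_framed(straight_curve):
    return FramedCurve(straight_curve)


@pytest.fixture(scope="session")
def circle_curve():
    """Half circle of radius 2 um in the xy plane (kappa = 0.5)."""
    th = np.linspace(0, np.pi, 40)
    nodes = np.stack([2 * np.cos(th), 2 * np.sin(th), 0 * th], axis=1)
    return fit_bspline(nodes, degree=4)


@pytest.fixture(scope="session")
def tube_scene():
    """A single straight noisy tube, radius 0.2 um, 5 um long (axis z)."""
    return straight_tube_scene(radius=0.2, length=5.0, seed=0)


@pytest.fixture(scope="session")
def small_scene():
    """A small multi-neurite rasterized scene."""
    cfg = SceneConfig(
        shape=(96, 96, 96),
        voxel_size_nm=(25, 25, 45),
        n_neurites=6,
        radius_range=(0.12, 0.25),
        tortuosity=0.15,
        varicosity_rate=0.3,
        noise_sigma=0.04,
    )
    return generate_scene(cfg, seed=1)


@pytest.fixture(scope="session")
def skeleton_scene():
    """Skeleton-only scene with well-separated long neurites (for metrics)."""
    cfg = SceneConfig(
        shape=(64, 64, 64),
        voxel_size_nm=(300, 300, 300),
        n_neurites=5,
        radius_range=(0.15, 0.25),
        tortuosity=0.1,
        varicosity_rate=0.0,
        rasterize=False,
        min_separation_factor=8.0,
    )
    return generate_scene(cfg, seed=3)
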