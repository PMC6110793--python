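import numpy as np
import pytest

from benthospec.cube import HyperCube, Stage
from benthospec.simulate import default_scene_config, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cube(rng):
    """A 4x5x6 raw cube with positive random values."""
    data = rng.uniform(10.0, 100.0, size=(4, 5, 6)).astype(np.float32)
    wl = np.linspace(400.0, 700.0, 6)
    return HyperCube(data=data, wavelengths=wl, track_id="unit")


@pytest.fixture(scope="session")
def default_scene():
    """The standard 300x400x112 synthetic scene (seed 7), shared
    read-only across tests."""
    return generate_scene(default_scene_config(seed=7))


@pytest.fixture(scope="session")
def clean_scene():
    """Zero-noise, flat-illumination variant for identifiability tests.

    Uses a longer (600-line) track so that, as on real survey tracks,
    every cross-track column stays majority-background and the column
    reference is uncontaminated by the planted objects.
    """
    cfg = default_scene_config(
        seed=11, lines=600, noise_frac=0.0, edge_illumination=1.0, drift_amplitude=0.0
    )
    return generate_scene(cfg)


def make_cube(data, wavelengths=None, stage=Stage.RAW, **kw):
    data = np.asarray(data, dtype=np.float32)
    if wavelengths is None:
        wavelengths = 400.0 + 4.0 * np.arange(data.shape[2])
    return HyperCube(data=data, wavelengths=np.asarray(wavelengths, float), stage=stage, **kw)
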