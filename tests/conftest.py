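"""Shared fixtures: small phantoms and the full default experiment."""

from __future__ import annotations

import numpy as np
import pytest

from ecamri.phantom import PhantomConfig, build_phantom
from ecamri.pipeline import demo_config, simulate_and_reconstruct


def small_config(**overrides) -> PhantomConfig:
    """A fast 8 x 6 x 4 phantom with one lesion voxel region and one vessel."""
    defaults = dict(
        grid_shape=(8, 6, 4),
        lesion_center=(5.0, 4.0, 1.0),
        lesion_semiaxes=(1.2, 1.2, 1.2),
        vessel_centers=((1.0, 2.0),),
        vessel_radius=0.8,
        vessel_t0_range=(10.0, 12.0),
    )
    defaults.update(overrides)
    return PhantomConfig(**defaults)


@pytest.fixture()
def small_phantom():
    return build_phantom(small_config(), seed=11)


@pytest.fixture()
def static_phantom():
    """No enhancing voxels: the phantom is time-invariant."""
    cfg = small_config(lesion_semiaxes=(0.0, 0.0, 0.0), vessel_centers=())
    return build_phantom(cfg, seed=11)


@pytest.fixture(scope="session")
def demo_run():
    """The package's standard study condition, simulated once per session.

    56 s UnWRAP scan of the default 32 x 28 x 7 phantom with calibrated
    noise, reconstructed by both methods at 0.25 s / 3.5 s.
    """
    cfg = demo_config(seed=1)
    return cfg, simulate_and_reconstruct(cfg)


def assert_deterministic(a: np.ndarray, b: np.ndarray) -> None:
    np.testing.assert_array_equal(np.asarray(a), np.asarray(b))
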