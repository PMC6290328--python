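import numpy as np
import pytest

from gubquant.synthetic_data import VolumePhantomSpec
from gubquant.volume_io import ConfocalVolume


def small_phantom_spec(**overrides) -> VolumePhantomSpec:
    """A quick-to-render phantom for unit tests (a few seconds end to end)."""
    defaults = dict(
        shape=(32, 48, 48),
        spacing_um=(2.15, 1.1, 1.1),
        semi_axes_um=(22.0, 16.0, 16.0),
        cord_length_um=12.0,
        cord_radius_um=5.0,
        nuclear_density_per_1000um3=10.0,
        noise_sigma=10.0,
        seed=0,
    )
    defaults.update(overrides)
    return VolumePhantomSpec(**defaults)


@pytest.fixture
def small_spec() -> VolumePhantomSpec:
    return small_phantom_spec()


@pytest.fixture
def tiny_volume() -> ConfocalVolume:
    """A 2-channel constant-background volume for contract tests."""
    data = np.full((2, 4, 5, 6), 7.0)
    return ConfocalVolume(
        data=data,
        channel_roles=("nuclear", "ar"),
        spacing_um=(2.0, 1.0, 1.0),
        metadata={"specimen_id": "tiny"},
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
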