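import numpy as np
import pytest

from eggsight.synthetic import (SpeciesProfile, default_profiles,
                                generate_clutch, render_egg, _base_params,
                                _clip_params)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def basic_profile():
    return SpeciesProfile(
        name="test-sp",
        background_color_mean=(0.82, 0.75, 0.68),
        spot_density_mean=40.0,
        ring_concentration=6.0,
    )


@pytest.fixture(scope="session")
def rendered_egg(basic_profile):
    """One egg at the full 256-px working size."""
    egg = generate_clutch(basic_profile, 1, np.random.default_rng(7),
                          canvas=256)[0]
    egg.validate()
    return egg


@pytest.fixture(scope="session")
def small_egg(basic_profile):
    """One egg at 64 px for cheap tests."""
    return generate_clutch(basic_profile, 1, np.random.default_rng(11),
                           canvas=64)[0]


def render_from_profile(profile, seed, canvas=256):
    """Render a single egg with the profile's mean parameters."""
    params = _clip_params(_base_params(profile))
    return render_egg(profile, params, np.random.default_rng(seed),
                      canvas=canvas)
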