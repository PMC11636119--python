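import pytest
from hypothesis import settings as hypothesis_settings

from sandstab import SynthConfig, generate_community, generate_soil

hypothesis_settings.register_profile("deterministic", derandomize=True,
                                     database=None)
hypothesis_settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_config() -> SynthConfig:
    return SynthConfig(seed=1)


@pytest.fixture(scope="session")
def community_seed1(default_config):
    """Generated community dataset + manifest at seed 1, default config."""
    return generate_community(default_config)


@pytest.fixture(scope="session")
def soil_seed1(default_config):
    return generate_soil(default_config)


@pytest.fixture(scope="session")
def noiseless_config() -> SynthConfig:
    cfg = SynthConfig(seed=1)
    cfg.noise = {"community": 0.0, "soil": 0.0, "pH": 0.0}
    return cfg


@pytest.fixture(scope="session")
def community_noiseless(noiseless_config):
    return generate_community(noiseless_config)


# Published stability-curve rows of the field study used as oracles:
# (restoration_years, position, (c0, c1, c2), printed x*, printed distance).
# The corrupted 13-yr under-crown row is excluded.
STABILITY_ROWS = [
    (0, "control", (16.66, 0.833, 0.0), 45.48, 36.03),
    (13, "outside_crown", (14.51, 1.857, -0.010), 33.95, 19.73),
    (25, "under_crown", (20.09, 1.82, -0.010), 31.96, 16.91),
    (25, "outside_crown", (12.54, 2.287, -0.014), 30.59, 14.98),
    (45, "under_crown", (20.27, 1.989, -0.012), 30.38, 14.68),
    (45, "outside_crown", (26.09, 1.772, -0.010), 29.88, 13.97),
]
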