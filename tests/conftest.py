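import numpy as np
import pytest

from herbspec import (
    SyntheticConfig,
    crop_wavelengths,
    simulate_spectra_table,
    stratified_split,
    well_separated_config,
)


@pytest.fixture(scope="session")
def default_config():
    return SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def default_table(default_config):
    return simulate_spectra_table(default_config)


@pytest.fixture(scope="session")
def separated_table():
    """Well-separated preset, cropped to the stable window: the fixture used
    wherever a model must reach high accuracy deterministically."""
    cfg = well_separated_config(seed=3)
    return crop_wavelengths(simulate_spectra_table(cfg), 875, 1546)


@pytest.fixture(scope="session")
def separated_split(separated_table):
    return stratified_split(separated_table.labels, (4, 1), seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
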