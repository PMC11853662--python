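import numpy as np
import pytest

import polchip as pc


@pytest.fixture(scope="session")
def grid():
    return pc.canonical_grid()


@pytest.fixture(scope="session")
def led(grid):
    return pc.led_spectrum(grid=grid)


@pytest.fixture(scope="session")
def cmf(grid):
    return pc.cie_1931_cmf(grid)


@pytest.fixture(scope="session")
def crossed_train():
    """Ideal crossed polarizers (LP1 at 0, LP2 at 90), no waveplate."""
    return pc.OpticalTrainConfig()


@pytest.fixture(scope="session")
def white(led, cmf):
    return pc.reference_white(led, cmf)


@pytest.fixture(scope="session")
def default_lut(led, crossed_train):
    """Full-resolution reference table, shared across tests (deterministic)."""
    return pc.build_color_lut(led, crossed_train)
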