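import dataclasses

import numpy as np
import pytest

from blastosim.config import default_config
from blastosim.geometry import Eggshell
from blastosim.mechanics import ForceParams
from blastosim.state import Cell, EmbryoState


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def fast_cfg(cfg):
    """Default config with shortened schedule, for structural tests."""
    return dataclasses.replace(cfg, t_first=50.0, stagger=25.0, settle=100.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def huge_shell():
    """Shell so large that its force and clamping never act."""
    return Eggshell(1e6, 1e6)


@pytest.fixture
def quiet_params():
    return ForceParams(noise_variance=0.0)


def make_state(cells, shell, time=0.0):
    return EmbryoState(time=time, cells=cells, shell=shell)


@pytest.fixture
def four_cell_factory(huge_shell):
    """Build a four-cell state from {label: (position, radius)}."""

    def build(spec):
        cells = [
            Cell(label, np.asarray(pos, dtype=float), radius)
            for label, (pos, radius) in spec.items()
        ]
        return make_state(cells, huge_shell)

    return build
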