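import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from lipidixs import ResolutionFunction, SpectralModelParams, DHOMode


@pytest.fixture
def rf():
    return ResolutionFunction(1.7, 0.5)


@pytest.fixture
def grid97():
    """The standard 97-point symmetric energy grid (meV)."""
    return np.linspace(-15.0, 15.0, 97)


@pytest.fixture
def gel_like_params(rf):
    """Two well-separated true modes (transverse 2 meV, longitudinal 6 meV)
    on a bright elastic line, as in a gel-phase low-Q scan."""
    return SpectralModelParams(
        elastic_amplitude=5000.0 / rf(0.0),
        background=10.0,
        modes=(DHOMode(2.0, 0.8, 3000.0), DHOMode(6.0, 1.5, 3000.0)),
        temperature=293.15,
    )


@pytest.fixture
def data_dir():
    return Path(__file__).parent / "data"
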