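import numpy as np
import pytest

from vgnodal import default_parameters


@pytest.fixture(scope="session")
def params():
    """The published default parameterization (shared, frozen dataclass)."""
    return default_parameters()


@pytest.fixture(scope="session")
def coarse_grid(params):
    """A 5-minute grid: fast to integrate, fine enough for interpolation."""
    return np.append(np.arange(0.0, params.t_end, 300.0), params.t_end)
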