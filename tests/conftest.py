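import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from ceemi.toy_model import ToyPopulation, build_input_gamma, quantile_grid_ensemble


@pytest.fixture(scope="session")
def toy_input():
    """Default discretized-gamma ligand input (mean 10, CV 1, 25 doses)."""
    return build_input_gamma()


@pytest.fixture(scope="session")
def toy_ensemble_cv03():
    """Deterministic 21-cell toy ensemble, R0 ~ gamma(mean 500, CV 0.3)."""
    return quantile_grid_ensemble(ToyPopulation("R0", 500.0, 0.3), 21)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
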