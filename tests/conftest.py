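import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from lsrqs import KineticParameters, KnockoutSet, ModelSpec, ModelVariant


@pytest.fixture(scope="session")
def defaults() -> KineticParameters:
    """The built-in best-fit parameter set."""
    return KineticParameters()


@pytest.fixture(scope="session")
def intact_spec(defaults) -> ModelSpec:
    return ModelSpec(ModelVariant.REG_BINDING, KnockoutSet(), defaults)


@pytest.fixture(scope="session")
def hourly_times() -> np.ndarray:
    return np.arange(0.0, 481.0, 60.0)


@pytest.fixture(scope="session")
def minute_grid() -> np.ndarray:
    return np.arange(0.0, 501.0, 1.0)
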