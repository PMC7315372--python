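import numpy as np
import pytest

from mvpatiming.preprocess import AlgorithmParams
from mvpatiming.synthesize import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def params():
    return AlgorithmParams()


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully structured cohort shared by read-only tests."""
    return simulate_cohort(SimConfig(n_participants=10, n_days=8, seed=42))
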