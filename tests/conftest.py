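import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from togcn import ExpressionMatrix, SimConfig, simulate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: the study's condition split used throughout the tests
CONDITION_MAP = {"LG": "C1", "MY": "C1", "XC": "C2", "XH": "C2", "ST": "excluded"}


@pytest.fixture(scope="session")
def condition_map():
    return dict(CONDITION_MAP)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Default-design dataset with the noise turned off."""
    return simulate_dataset(SimConfig(noise_sigma=0.0, rng_seed=0))


@pytest.fixture(scope="session")
def noisy_dataset():
    """Default-design dataset at the default noise level."""
    return simulate_dataset(SimConfig(rng_seed=0))


def toy_matrix(values, columns, genes=None):
    genes = genes or [f"G{i}" for i in range(len(values))]
    df = pd.DataFrame(np.asarray(values, dtype=float), index=genes, columns=columns)
    return ExpressionMatrix.from_dataframe(df)
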