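import numpy as np
import pandas as pd
import pytest

from sigconcord import SyntheticConfig, generate_study


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study, shared across tests that only read it."""
    return generate_study(SyntheticConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_expr(rng):
    """Random 50-gene x 10-sample log2 expression matrix."""
    genes = [f"g{i:03d}" for i in range(50)]
    samples = [f"s{j}" for j in range(10)]
    return pd.DataFrame(rng.normal(8, 1, (50, 10)), index=genes, columns=samples)
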