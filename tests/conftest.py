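import numpy as np
import pandas as pd
import pytest

from biosol.dataset import CompoundRecord, SolubilityDataset, load_fixture


@pytest.fixture(scope="session")
def fixture_ds() -> SolubilityDataset:
    return load_fixture()


@pytest.fixture()
def toy_ds() -> SolubilityDataset:
    return SolubilityDataset([
        CompoundRecord(name="alpha", mw=300.0, logd65=2.5, psa=80.0, rotb=3,
                       logs_phb=-4.0, logs_fassif=-3.5, logs_hif=-3.8, tm_c=150.0),
        CompoundRecord(name="beta", mw=400.0, logd65=4.5, psa=120.0, rotb=5,
                       logs_phb=-5.0, logs_fassif=-4.2, tm_c=210.0),
        CompoundRecord(name="gamma", mw=250.0, logd65=1.5, psa=60.0, rotb=1,
                       logs_fassif=-2.8, logs_hif=-3.0),
    ])


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20140904)


def random_regression(rng, n=40, p=8, noise=0.1):
    """Small random X, y with a linear relation, as a DataFrame/Series pair."""
    X = pd.DataFrame(rng.standard_normal((n, p)),
                     columns=[f"d{j}" for j in range(p)])
    beta = rng.standard_normal(p)
    y = pd.Series(X.to_numpy() @ beta + noise * rng.standard_normal(n), name="y")
    return X, y
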