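import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mirwalker as mw

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[
        HealthCheck.too_slow,
        HealthCheck.function_scoped_fixture,
    ],
)
settings.load_profile("suite")


@pytest.fixture
def two_by_two():
    """The hand-checkable 2-disease / 2-miRNA network fixture:
    Wdd = [[1, .5], [.5, 1]], Wdm = I."""
    dataset = mw.AssociationDataset(
        ("d1", "d2"), ("m1", "m2"), np.eye(2)
    )
    SD = np.array([[1.0, 0.5], [0.5, 1.0]])
    SM = np.array([[1.0, 0.5], [0.5, 1.0]])
    return dataset, SD, SM


@pytest.fixture
def chain_forest():
    """Two sibling diseases under a shared root plus one outsider:
    d1 -> r, d2 -> r, d3 -> s."""
    return mw.OntologyForest(
        terms=frozenset({"d1", "d2", "d3", "r", "s"}),
        parent_edges=frozenset({("d1", "r"), ("d2", "r"), ("d3", "s")}),
    )


@pytest.fixture
def small_planted():
    """A small planted-cluster dataset for fast end-to-end tests."""
    return mw.generate(
        mw.SyntheticConfig(n_d=10, n_m=16, k=2, p_in=0.7, p_out=0.05, seed=7)
    )


def random_fitted_model(seed: int, n_d: int = 6, n_m: int = 8, k: int = 2):
    """A fitted model on a random small synthetic dataset."""
    data = mw.generate(
        mw.SyntheticConfig(
            n_d=n_d, n_m=n_m, k=k, p_in=0.6, p_out=0.15, seed=seed
        )
    )
    return data, mw.fit_model(data.dataset, data.forest, data.fs)
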