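import numpy as np
import pandas as pd
import pytest

import graftpop as gp


@pytest.fixture(scope="session")
def small_population():
    """A 40-graft population with planted structure, shared across tests."""
    truth = gp.default_truth(7, n_outliers=1)
    pop, truth = gp.generate_population(truth, n_grafts=40)
    return pop, truth


@pytest.fixture(scope="session")
def default_population():
    """The full-size default population (255 grafts), generated once."""
    truth = gp.default_truth(11)
    pop, truth = gp.generate_population(truth)
    return pop, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_profile(fc: pd.DataFrame, kinds: dict[str, str],
                 reference_id: str = "REF") -> gp.ResponseProfile:
    """Assemble a ResponseProfile directly from a fold-change matrix."""
    return gp.ResponseProfile(fc=fc, feature_kind=kinds,
                              reference_id=reference_id)
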