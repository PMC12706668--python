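import numpy as np
import pytest

from needskit import datasets
from needskit.kano import EvaluationTable


@pytest.fixture(scope="session")
def eval_table():
    return EvaluationTable.default()


@pytest.fixture(scope="session")
def kano_counts():
    return datasets.load_kano_counts()


@pytest.fixture(scope="session")
def kano_responses():
    return datasets.load_kano_responses()


@pytest.fixture(scope="session")
def hierarchy():
    return datasets.load_hierarchy()


@pytest.fixture(scope="session")
def hierarchy_verbatim():
    return datasets.load_hierarchy(exact=False)


@pytest.fixture(scope="session")
def ahp_expected():
    return datasets.load_ahp_expected()


@pytest.fixture(scope="session")
def hoq_weights():
    return datasets.load_hoq_weights()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
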