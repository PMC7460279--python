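import numpy as np
import pytest

from galdiv import call_roh_dataset, make_study_fixture

STUDY_SEED = 7


@pytest.fixture(scope="session")
def study():
    """The full synthetic multi-breed study dataset plus its truth set."""
    return make_study_fixture(STUDY_SEED)


@pytest.fixture(scope="session")
def study_roh(study):
    """ROH called on the study dataset with default (segment-mode) parameters."""
    ds, _ = study
    return call_roh_dataset(ds)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
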