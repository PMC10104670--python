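import numpy as np
import pytest

from depotpk import (
    PKParams,
    ReleaseModel,
    default_release_params,
    simulate,
)


@pytest.fixture(scope="session")
def model_65():
    return ReleaseModel(default_release_params("6.5 um"))


@pytest.fixture(scope="session")
def default_pk_params():
    return PKParams()


@pytest.fixture(scope="session")
def default_timecourse(default_pk_params):
    return simulate(default_pk_params, t_end=672.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
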