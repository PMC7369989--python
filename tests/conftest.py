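import numpy as np
import pytest

from cypminer.align import ScoringScheme
from cypminer.pipeline import run_cohort_bundle
from cypminer.simulate import SimSpec, make_cohort, make_reference_db


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme()


@pytest.fixture(scope="session")
def small_refdb(scheme):
    """Two families, two subfamilies each, with its identity certificate."""
    refdb, cert = make_reference_db(2, 2, rng=7, scheme=scheme)
    return refdb, cert


@pytest.fixture(scope="session")
def bundle42():
    """The five-species synthetic cohort under the default study conditions."""
    return make_cohort(SimSpec(seed=42))


@pytest.fixture(scope="session")
def result42(bundle42):
    return run_cohort_bundle(bundle42)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
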