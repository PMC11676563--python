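import numpy as np
import pytest

from carenet.ehr import TimelineConfig, build_bundles, build_vocabulary
from carenet.simulate import VITAL_CODES, SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 120-visit cohort at default signal strength (light event volume to
    keep unit tests quick; the full-scale conditions live in the acceptance
    tests)."""
    return generate_cohort(SimConfig(n_visits=120, events_median=60.0,
                                     events_iqr=(25.0, 140.0), seed=5))


@pytest.fixture(scope="session")
def small_vocab(small_cohort):
    tokens = small_cohort.events[~small_cohort.events.code.isin(VITAL_CODES)]
    return build_vocabulary(tokens, min_count=5)


@pytest.fixture(scope="session")
def small_bundles(small_cohort, small_vocab):
    return build_bundles(small_cohort.events, small_cohort.visits, small_vocab,
                         TimelineConfig(), numeric_codes=VITAL_CODES)


@pytest.fixture(scope="session")
def small_labels(small_cohort):
    return small_cohort.labels_array()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
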