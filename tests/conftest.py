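import numpy as np
import pytest

from mirrortrail.pipeline import cohort_features, complete_rows
from mirrortrail.records import SampledSeries
from mirrortrail.synthetic import generate_cohort_dataset, study_config


@pytest.fixture(scope="session")
def tiny_dataset():
    """A 3+3-participant dataset under default study conditions, for structural tests."""
    return generate_cohort_dataset(study_config(n_per_cohort=3, seed=99))


@pytest.fixture(scope="session")
def tiny_features(tiny_dataset):
    return complete_rows(cohort_features(tiny_dataset))


def uniform_series(duration_s: float, rate_hz: float, fn) -> SampledSeries:
    t = np.arange(0.0, duration_s, 1.0 / rate_hz)
    return SampledSeries(t, fn(t), rate_hz)
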