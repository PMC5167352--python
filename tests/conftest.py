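import numpy as np
import pytest

from handscreen import CohortConfig, PipelineConfig, generate_cohort, run_pipeline, sample_evaluated
from handscreen.frascati import classify_cohort


@pytest.fixture(scope="session")
def default_config():
    return CohortConfig(seed=1)


@pytest.fixture(scope="session")
def classified_cohort(default_config):
    """Default cohort, evaluated and classified (seed 1)."""
    records = generate_cohort(default_config)
    sample_evaluated(records, default_config)
    classify_cohort(records)
    return records


@pytest.fixture(scope="session")
def pipeline_result():
    return run_pipeline(PipelineConfig(cohort=CohortConfig(seed=1)))


@pytest.fixture()
def rng():
    return np.random.default_rng(20160)
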