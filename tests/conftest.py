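import numpy as np
import pytest

from oncowga import pipeline
from oncowga.reference import build_toy_reference
from oncowga.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def bundle():
    return build_toy_reference()


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(SimulationConfig(n_cases=25), seed=11)


@pytest.fixture(scope="session")
def small_reports(small_cohort):
    return pipeline.run_interpretation(small_cohort.cases, small_cohort.callsets,
                                       small_cohort.bundle)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
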