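import numpy as np
import pytest

from renovar.genome import synthetic_genome
from renovar.simulate import (
    build_read_matrix,
    default_cohort_config,
    second_pipeline_calls,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def genome():
    return synthetic_genome()


@pytest.fixture(scope="session")
def cohort():
    """Small labelled cohort shared across test modules (seed fixed)."""
    return simulate_cohort(default_cohort_config(scale=0.04), seed=11)


@pytest.fixture(scope="session")
def cascade_result(cohort):
    from renovar.filtering import run_cascade

    matrix = build_read_matrix(cohort)
    calls_b = second_pipeline_calls(cohort, seed=12)
    final, report = run_cascade(cohort.calls, calls_b, matrix)
    return final, report, matrix


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
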