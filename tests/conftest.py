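"""Shared fixtures: small simulated cohorts, all generated at test time."""

import numpy as np
import pytest

from mirdiag import (CohortConfig, correct_background, simulate_cohort,
                     summarize_replicates, vsn_normalize)


@pytest.fixture(scope="session")
def small_cohort():
    """A small two-class cohort with planted markers (probe level)."""
    config = CohortConfig(n_mirnas=120, class_sizes={"PDAC": 15, "healthy": 15},
                          n_differential=12, effect_size=1.5, seed=101)
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def small_normalized(small_cohort):
    """The small cohort taken through the full preprocessing chain."""
    data, annotation, truth = small_cohort
    matrix, fit = vsn_normalize(summarize_replicates(correct_background(data)))
    return matrix, annotation, truth, fit


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
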