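"""Shared fixtures: small synthetic cohorts and their forcings.

Everything is generated programmatically at test time; expensive cohorts
are session-scoped.
"""

import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("ci", derandomize=True)
hypothesis_settings.load_profile("ci")

from adipoflux import CANONICAL_TIMES, ModelParameters, simulate
from adipoflux.synthetic import (
    CohortSpec,
    cohort_mean_forcing,
    generate_cohort_fluxes,
)


@pytest.fixture(scope="session")
def truth_params() -> ModelParameters:
    return ModelParameters.baseline()


@pytest.fixture(scope="session")
def clean_cohort():
    """Deterministic cohort: no noise, no between-subject variability.

    Its FluxDataset means equal the noiseless model fluxes exactly.
    """
    spec = CohortSpec(seed=1, n_subjects=2, shape_cv=0.0, peak_time_cv=0.0,
                      noise_frac=0.0)
    table, dataset, truth = generate_cohort_fluxes(spec)
    return table, dataset, truth


@pytest.fixture(scope="session")
def clean_forcing(clean_cohort):
    table, _, _ = clean_cohort
    return cohort_mean_forcing(table)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Study-design-like cohort: 16 subjects, variability and noise."""
    spec = CohortSpec(seed=7)
    table, dataset, truth = generate_cohort_fluxes(spec)
    return table, dataset, truth


@pytest.fixture(scope="session")
def baseline_sim(truth_params, clean_forcing):
    """Dense baseline simulation on the 1-min grid."""
    return simulate(truth_params, clean_forcing)


@pytest.fixture()
def times():
    return np.array(CANONICAL_TIMES)
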