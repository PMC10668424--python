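import numpy as np
import pytest

from ovarisk.cohort import (GeneratorConfig, OUTCOME_LEVELS,
                            default_latent_coefficients, generate_cohort,
                            generate_from_latent_mlr)


@pytest.fixture(scope="session")
def small_cohort():
    """Complete-CA125 multicenter cohort, all five classes present."""
    return generate_cohort(GeneratorConfig(n_patients=600, n_centers=4, seed=101))


@pytest.fixture(scope="session")
def cohort_with_missing():
    return generate_cohort(GeneratorConfig(
        n_patients=800, n_centers=4, ca125_missing_rate=0.30, seed=102))


@pytest.fixture(scope="session")
def latent_cohort():
    """Known-truth cohort: (table, true probability matrix, config)."""
    cfg = GeneratorConfig(n_patients=2000, n_centers=4, seed=103,
                          latent_mlr_coefficients=default_latent_coefficients())
    table, true_p = generate_from_latent_mlr(cfg)
    return table, true_p, cfg


@pytest.fixture
def balanced_outcomes():
    """3 patients per class, labels in canonical order."""
    return np.repeat(np.arange(len(OUTCOME_LEVELS)), 3)
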