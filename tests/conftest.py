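import numpy as np
import pytest

import nacstrat as ns


@pytest.fixture(scope="session")
def planted_cohort():
    """A single Gaussian cohort with five planted response genes at d=2."""
    spec = ns.CohortSimSpec(cohort_sizes=(40,), n_genes=200, n_informative=5,
                            effect_size=2.0, shape="gaussian",
                            cohort_shift=0.0, cohort_scale=1.0, seed=11)
    cohorts, truth = ns.generate_cohorts(spec)
    return cohorts[0], truth


@pytest.fixture(scope="session")
def four_cohorts():
    """Four small cohorts with cohort-specific distortions (shared truth)."""
    spec = ns.CohortSimSpec(cohort_sizes=(16, 23, 38, 60), n_genes=120,
                            n_informative=8, effect_size=1.5, seed=7)
    return ns.generate_cohorts(spec)


@pytest.fixture(scope="session")
def pathology_small():
    """A 12-marker pathology table with two predictive markers per compartment."""
    spec = ns.PathologySimSpec(n_patients=(55, 36), n_markers=12, n_predictive=2,
                               seed=13)
    return ns.generate_pathology(spec)


@pytest.fixture(scope="session")
def pathology_n200():
    """A 200-patient pathology table (12 markers, 2 predictive/compartment)."""
    spec = ns.PathologySimSpec(n_patients=(110, 90), n_markers=12, n_predictive=2,
                               seed=13)
    return ns.generate_pathology(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
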