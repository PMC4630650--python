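import numpy as np
import pytest

from dexmet import default_cohort_spec, generate_cohort, preprocess
from dexmet.cohort import CohortSpec
from dexmet.design import default_design


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def default_cohort():
    """The emulated study: 20 subjects x 11 slots, 214 metabolites, seed 1."""
    return generate_cohort(default_cohort_spec(seed=1))


@pytest.fixture(scope="session")
def default_processed(default_cohort):
    return preprocess(default_cohort)


def small_spec(seed=0, n_subjects=6, n_metabolites=12, **overrides) -> CohortSpec:
    """A fast, fully-null cohort spec for unit tests; override fields freely."""
    kwargs = dict(
        n_subjects=n_subjects,
        n_metabolites=n_metabolites,
        baseline_log_mean=np.full(n_metabolites, 1.0),
        subject_sd=np.full(n_metabolites, 0.1),
        noise_sd=np.full(n_metabolites, 0.05),
        n_pool_replicates=4,
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortSpec(**kwargs)


@pytest.fixture
def small_cohort():
    return generate_cohort(small_spec(seed=3))
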