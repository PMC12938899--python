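import warnings

import pytest

from evpanel.synthetic import SyntheticConfig, generate_npx_cohort
from evpanel.npx import apply_filters

# simulation sizes are deliberately small: unit tests exercise contracts,
# the acceptance tests exercise the study-scale conditions
SMALL = dict(n_hc=15, n_pt=15, n_fu=10, n_proteins=20, n_planted_diag=2,
             n_planted_resp=2, seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    matrix, truth = generate_npx_cohort(SyntheticConfig(**SMALL))
    return matrix, truth


@pytest.fixture(scope="session")
def default_cohort():
    """The study-scale cohort: 28 HC + 29 PT, 60 proteins, 2 planted markers."""
    matrix, truth = generate_npx_cohort(SyntheticConfig(seed=3))
    return matrix, truth


@pytest.fixture(scope="session")
def filtered_default(default_cohort):
    matrix, truth = default_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        filtered, report = apply_filters(matrix)
    return filtered, truth, report
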