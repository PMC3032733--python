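import numpy as np
import pytest

from twinace import CholeskyParams, SimConfig, simulate_cohort
from twinace.pipeline import fixture_components


@pytest.fixture(scope="session")
def uni_params():
    """Univariate ACE model with a2=.52, c2=.30, e2=.18."""
    return CholeskyParams.univariate(0.52, 0.30, 0.18, trait="ach")


@pytest.fixture(scope="session")
def big_uni_cohort(uni_params):
    """20,000 pairs per zygosity from the univariate reference model."""
    return simulate_cohort(
        SimConfig(n_mz_pairs=20_000, n_dz_pairs=20_000, cholesky=uni_params, seed=424)
    )


@pytest.fixture(scope="session")
def bivariate_params():
    """g -> teacher-achievement model from the reference generating structure."""
    sa, sc, se, names = fixture_components()
    idx = [2, 3]  # g, ach12_teacher
    sub = np.ix_(idx, idx)
    return CholeskyParams.from_components(
        sa[sub], sc[sub], se[sub], ("g", "ach")
    )


@pytest.fixture(scope="session")
def small_cohort(uni_params):
    """Small mixed cohort with missingness for smoke-level assertions."""
    return simulate_cohort(
        SimConfig(
            n_mz_pairs=300,
            n_dz_pairs=400,
            cholesky=uni_params,
            sex_effect=0.1,
            age_effect=0.1,
            missing_rate=0.1,
            seed=99,
        )
    )
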