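import numpy as np
import pytest

from pazopk import (
    CohortDesign,
    PopulationParameters,
    generate_cohort,
    impute_covariates,
)
from pazopk.model import IndividualParameters
from pazopk.saem import CovariateCandidate, SaemSettings, fit_saem


@pytest.fixture(scope="session")
def reference_pop():
    return PopulationParameters.reference()


@pytest.fixture(scope="session")
def typical_ip(reference_pop):
    """The published typical subject: ka 0.976, V 22.3, Cl 0.458."""
    return IndividualParameters.from_rates(ka=0.976, v=22.3, cl=0.458)


@pytest.fixture(scope="session")
def default_cohort(reference_pop):
    """Default two-arm synthetic database (58 TDM + 15 rich), seed 1."""
    return generate_cohort(CohortDesign(seed=1), reference_pop)


@pytest.fixture(scope="session")
def imputed_cohort(default_cohort):
    return impute_covariates(default_cohort)


@pytest.fixture(scope="session")
def neutral_init():
    """Generic starting values away from the reference estimates."""
    return PopulationParameters(
        ka_pop=2.0, v_pop=50.0, cl_pop=1.0,
        omega_ka=0.3, omega_v=0.3, omega_cl=0.3,
        gamma_v=0.1, gamma_cl=0.1, err_add=1.0, err_prop=0.3)


@pytest.fixture(scope="session")
def recovery_fit(imputed_cohort, neutral_init):
    """Parameter-recovery fit of the default cohort under the final model.

    Session-scoped: shared by the estimation tests and the acceptance
    checks (the fit is the expensive step).
    """
    settings = SaemSettings(seed=11, compute_ofv=False, compute_rse=True)
    return fit_saem(imputed_cohort, neutral_init, settings,
                    covariates=[CovariateCandidate("v", "ASAT", "power")])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
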