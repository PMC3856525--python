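import numpy as np
import pytest

from rcc_bia import config as cfgmod
from rcc_bia.budget_impact import BIASettings
from rcc_bia.cost_model import default_ae_profile, default_drugs
from rcc_bia.epi_model import EpiParams, simulate

#: Published eligible patient counts (favorable/intermediate risk) per year.
PRINTED_ELIGIBLE = {2013: 1591, 2014: 1615, 2015: 1638}


@pytest.fixture(scope="session")
def base_params():
    return EpiParams()


@pytest.fixture(scope="session")
def base_demo(base_params):
    return cfgmod.build_demographics(cfgmod.default_config(), base_params)


@pytest.fixture(scope="session")
def base_trajectory(base_params, base_demo):
    return simulate(base_params, base_demo)


@pytest.fixture(scope="session")
def drugs():
    return default_drugs()


@pytest.fixture(scope="session")
def ae_profile():
    return default_ae_profile()


@pytest.fixture(scope="session")
def settings():
    return BIASettings()


def cohort_progressions_oracle(params, demo):
    """Brute-force oracle: follow each annual diagnosis cohort independently
    through its 10-year survival table and sum relapses by calendar year.

    Under the default timing, the cohort diagnosed in year y bears its k-th
    tunnel-year progression risk during year y+k; under the same-cycle
    switch, during year y+k-1.
    """
    p = np.asarray(params.progression_prob)
    m = params.localized_mortality
    lag = 0 if params.same_cycle_first_risk else 1
    prog = {int(y): 0.0 for y in demo.years}
    for i, y in enumerate(demo.years):
        pop = demo.pop40plus[i]
        localized = (pop * params.kidney_incidence_40plus * params.rcc_fraction
                     * (1.0 - params.advanced_at_diagnosis_fraction))
        alive = localized
        for k in range(1, 11):
            year_at_risk = int(y) + k - 1 + lag
            if year_at_risk in prog:
                prog[year_at_risk] += alive * p[k - 1]
            alive *= 1.0 - p[k - 1] - m
    return prog
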