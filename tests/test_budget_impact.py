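import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from rcc_bia.budget_impact import (
    BIASettings,
    annual_arm_costs,
    discount_factor,
    incremental_cost,
    per_patient_budget_term,
    run_bia,
)
from rcc_bia.cost_model import DrugCostParams, ae_cost_per_patient

from conftest import PRINTED_ELIGIBLE


def test_discount_convention(settings):
    assert discount_factor(2013, settings) == 1.0
    assert discount_factor(2014, settings) == pytest.approx(1 / 1.03)
    assert discount_factor(2015, settings) == pytest.approx(1 / 1.03**2)
    with pytest.raises(ValueError):
        discount_factor(2012, settings)


def test_annual_arm_costs_2013_pazopanib(drugs, ae_profile, settings):
    ae = ae_cost_per_patient(ae_profile, "pazopanib")
    costs = annual_arm_costs(1591, drugs["pazopanib"], ae, 2013, settings)
    assert costs.overall == pytest.approx(30_404_210, rel=1e-3)
    assert costs.overall == costs.pharm + costs.ae


def test_annual_arm_costs_2014_discounted_pharm(drugs, ae_profile, settings):
    costs = annual_arm_costs(1615, drugs["pazopanib"], 0.0, 2014, settings)
    assert costs.pharm == pytest.approx(28_925_945, rel=1e-3)


def test_zero_patients_cost_nothing(drugs, settings):
    costs = annual_arm_costs(0, drugs["sunitinib"], 974.08, 2015, settings)
    assert costs == (0.0, 0.0)


def test_full_share_2013_saving(drugs, ae_profile, settings):
    inc = incremental_cost(1591, 1.0, 2013, drugs["pazopanib"], drugs["sunitinib"],
                           ae_profile, settings)
    assert inc == pytest.approx(-6_723_622, rel=1e-3)
    assert incremental_cost(1591, 0.0, 2013, drugs["pazopanib"], drugs["sunitinib"],
                            ae_profile, settings) == 0.0


def test_per_point_saving(drugs, ae_profile, settings):
    inc = incremental_cost(1591, 0.01, 2013, drugs["pazopanib"], drugs["sunitinib"],
                           ae_profile, settings)
    assert inc == pytest.approx(-67_236, rel=1e-3)


def test_incremental_equals_mixed_world_minus_comparator(drugs, ae_profile, settings):
    """Oracle: in a share-s world s*n patients get pazopanib and (1-s)*n get
    sunitinib; the budget impact is that world's cost minus the
    all-sunitinib world's."""
    n, s, year = 1591.0, 0.37, 2014
    paz = per_patient_budget_term(drugs["pazopanib"], ae_profile)
    sun = per_patient_budget_term(drugs["sunitinib"], ae_profile)
    d = discount_factor(year, settings)
    mixed = (s * n * paz + (1 - s) * n * sun) * d
    all_sun = n * sun * d
    got = incremental_cost(n, s, year, drugs["pazopanib"], drugs["sunitinib"],
                           ae_profile, settings)
    assert got == pytest.approx(mixed - all_sun, rel=1e-12)
    # allocations always sum to the eligible count
    assert s * n + (1 - s) * n == pytest.approx(n)


@hsettings(max_examples=50, derandomize=True)
@given(share=st.floats(0, 1), n=st.floats(0, 1e5))
def test_linearity_in_share_and_population(share, n, drugs, ae_profile, settings):
    full = incremental_cost(n, 1.0, 2013, drugs["pazopanib"], drugs["sunitinib"],
                            ae_profile, settings)
    got = incremental_cost(n, share, 2013, drugs["pazopanib"], drugs["sunitinib"],
                           ae_profile, settings)
    assert got == pytest.approx(share * full, rel=1e-12, abs=1e-9)
    doubled = incremental_cost(2 * n, share, 2013, drugs["pazopanib"],
                               drugs["sunitinib"], ae_profile, settings)
    assert doubled == pytest.approx(2 * got, rel=1e-12, abs=1e-9)


def test_equal_arm_costs_give_zero_impact(ae_profile, settings, drugs):
    same = {"pazopanib": DrugCostParams("pazopanib", 4000.0),
            "sunitinib": DrugCostParams("sunitinib", 4000.0)}
    # identical prices but different AE profiles still differ; neutralize AE too
    inc = incremental_cost(1591, 1.0, 2013, same["pazopanib"], same["sunitinib"],
                           type(ae_profile)(()), settings)
    assert inc == 0.0


def test_single_patient_identity(drugs, ae_profile):
    settings = BIASettings(discount_rate=0.0)
    inc = incremental_cost(1.0, 1.0, 2013, drugs["pazopanib"], drugs["sunitinib"],
                           ae_profile, settings)
    expected = (per_patient_budget_term(drugs["pazopanib"], ae_profile)
                - per_patient_budget_term(drugs["sunitinib"], ae_profile))
    assert inc == pytest.approx(expected, rel=1e-12)


def test_run_bia_structure_and_overrides(base_trajectory, drugs, ae_profile, settings):
    result = run_bia(base_trajectory, drugs, ae_profile, settings,
                     eligible_override=PRINTED_ELIGIBLE)
    by_year = result.by_year.set_index(["year", "arm"])
    assert by_year.loc[(2015, "sunitinib"), "overall_cost"] == pytest.approx(
        36_030_382, rel=1e-3)
    # overall = pharm + ae exactly, every arm-year
    np.testing.assert_allclose(
        result.by_year["overall_cost"],
        result.by_year["pharm_cost"] + result.by_year["ae_cost"], rtol=1e-15)
    # incremental cost is linear in share within each year
    for year, grp in result.incremental.groupby("year"):
        full = grp.loc[grp["share"] == 1.0, "incremental_cost"].iloc[0]
        np.testing.assert_allclose(grp["incremental_cost"], grp["share"] * full,
                                   rtol=1e-12, atol=1e-6)
    assert result.cumulative_saving == pytest.approx(
        6_723_622 + 6_626_260 + 6_524_881, rel=1e-3)


def test_run_bia_uses_model_counts_by_default(base_trajectory, drugs, ae_profile,
                                              settings):
    result = run_bia(base_trajectory, drugs, ae_profile, settings)
    patients = result.by_year.set_index(["year", "arm"])["patients"]
    assert patients[(2013, "pazopanib")] == pytest.approx(
        base_trajectory.eligible(2013))
    # model-derived counts sit within 1% of the published ones
    for year, printed in PRINTED_ELIGIBLE.items():
        assert patients[(year, "pazopanib")] == pytest.approx(printed, rel=0.01)


def test_bia_settings_validation():
    with pytest.raises(ValueError):
        BIASettings(discount_rate=-0.01)
    with pytest.raises(ValueError):
        BIASettings(share_grid=(0.5, 0.2))
    with pytest.raises(ValueError):
        BIASettings(share_grid=(0.5, 1.2))
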