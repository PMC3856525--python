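"""Budget impact of introducing pazopanib vs an all-sunitinib scenario.

Aggregates the per-patient cost model over the eligible advanced-RCC
population for a 2013-2015 horizon. Pharmacological costs are weighted by
the expected time on treatment within a year (57%); adverse-event costs
apply once per treated patient per year. Future years are discounted at 3%
per year back to the reference year. The budget impact of a pazopanib
market share s is the cost difference between a world where a fraction s of
eligible patients receives pazopanib (the rest sunitinib) and the
all-sunitinib world; negative incremental cost is a saving.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .cost_model import (
    AEProfile,
    DrugCostParams,
    ae_cost_per_patient,
    annual_pharm_cost,
)
from .epi_model import EpiTrajectory

__all__ = [
    "BIASettings",
    "ArmCosts",
    "BudgetResult",
    "discount_factor",
    "annual_arm_costs",
    "per_patient_budget_term",
    "incremental_cost",
    "run_bia",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BIASettings:
    """Horizon, discounting and market-share grid for the analysis."""

    horizon_years: tuple = (2013, 2014, 2015)
    discount_rate: float = 0.03
    reference_year: int = 2013
    share_grid: tuple = field(default=tuple(np.round(np.linspace(0.0, 1.0, 101), 4)))

    def __post_init__(self) -> None:
        object.__setattr__(self, "horizon_years", tuple(int(y) for y in self.horizon_years))
        shares = tuple(float(s) for s in self.share_grid)
        object.__setattr__(self, "share_grid", shares)
        if self.discount_rate < 0:
            raise ValueError("discount_rate must be >= 0")
        if any(not 0.0 <= s <= 1.0 for s in shares):
            raise ValueError("market shares must lie in [0, 1]")
        if list(shares) != sorted(shares):
            raise ValueError("share_grid must be sorted ascending")


class ArmCosts(NamedTuple):
    pharm: float
    ae: float

    @property
    def overall(self) -> float:
        return self.pharm + self.ae


def discount_factor(year: int, settings: BIASettings) -> float:
    """(1 + r)^-(year - reference_year); equals 1 at the reference year."""
    if year < settings.reference_year:
        raise ValueError(
            f"year {year} precedes reference year {settings.reference_year}"
        )
    return (1.0 + settings.discount_rate) ** -(year - settings.reference_year)


def per_patient_budget_term(drug: DrugCostParams, profile: AEProfile) -> float:
    """Undiscounted per-patient annual cost as it enters the budget.

    Pharmacological cost is weighted by the time-on-treatment fraction;
    adverse-event cost applies once per treated patient per year.
    """
    return (annual_pharm_cost(drug) * drug.time_on_treatment_fraction
            + ae_cost_per_patient(profile, drug.name))


def annual_arm_costs(n_patients: float, drug: DrugCostParams, ae_cost: float,
                     year: int, settings: BIASettings) -> ArmCosts:
    """Discounted aggregate pharmacological and AE costs for one arm-year.

    ``ae_cost`` is the per-patient annual adverse-event cost for this arm.
    """
    if n_patients < 0:
        raise ValueError("n_patients must be >= 0")
    d = discount_factor(year, settings)
    pharm = n_patients * annual_pharm_cost(drug) * drug.time_on_treatment_fraction * d
    ae = n_patients * ae_cost * d
    return ArmCosts(pharm=pharm, ae=ae)


def incremental_cost(n_patients: float, share_pazopanib: float, year: int,
                     drug_new: DrugCostParams, drug_ref: DrugCostParams,
                     profile: AEProfile, settings: BIASettings) -> float:
    """Discounted budget impact of treating a share of patients with the new drug.

    Linear in the share: ``share x n x (per-patient budget term difference)``
    discounted to the reference year. Negative values are savings for the
    payer.
    """
    if not 0.0 <= share_pazopanib <= 1.0:
        raise ValueError("share must be in [0, 1]")
    diff = per_patient_budget_term(drug_new, profile) - per_patient_budget_term(drug_ref, profile)
    return share_pazopanib * n_patients * diff * discount_factor(year, settings)


@dataclass
class BudgetResult:
    """Tabular outputs of the budget-impact analysis."""

    by_year: pd.DataFrame       # year, arm, patients, pharm, ae, overall, discount
    incremental: pd.DataFrame   # year, share, incremental_cost
    per_point_saving: float     # saving per 1-point share increase, reference year
    saving_at_full_share: dict  # year -> saving when every patient gets the new drug
    cumulative_saving: float    # discounted sum of full-share savings over horizon

    def summary(self) -> dict:
        return {
            "per_point_saving_eur": self.per_point_saving,
            "saving_at_full_share_eur": dict(self.saving_at_full_share),
            "cumulative_saving_eur": self.cumulative_saving,
        }


def run_bia(trajectory: EpiTrajectory, drugs: dict, profile: AEProfile,
            settings: BIASettings, new_arm: str = "pazopanib",
            ref_arm: str = "sunitinib",
            eligible_override: dict | None = None) -> BudgetResult:
    """Full budget-impact analysis over the horizon.

    Eligible patient counts per year are taken from the epidemiological
    trajectory (unrounded); ``eligible_override`` maps year -> count to
    substitute externally fixed patient numbers.
    """
    drug_new, drug_ref = drugs[new_arm], drugs[ref_arm]
    ae_costs = {arm: ae_cost_per_patient(profile, arm) for arm in (new_arm, ref_arm)}

    rows, inc_rows = [], []
    saving_full, cumulative = {}, 0.0
    for year in settings.horizon_years:
        if eligible_override and year in eligible_override:
            n = float(eligible_override[year])
        else:
            n = trajectory.eligible(year)
        d = discount_factor(year, settings)
        for arm, drug in ((new_arm, drug_new), (ref_arm, drug_ref)):
            costs = annual_arm_costs(n, drug, ae_costs[arm], year, settings)
            rows.append({
                "year": year, "arm": arm, "patients": n,
                "pharm_cost": costs.pharm, "ae_cost": costs.ae,
                "overall_cost": costs.overall, "discount_factor": d,
            })
        full = incremental_cost(n, 1.0, year, drug_new, drug_ref, profile, settings)
        for share in settings.share_grid:
            inc_rows.append({"year": year, "share": share,
                             "incremental_cost": share * full})
        saving_full[year] = -full
        cumulative += -full
        logger.info("year %d: %.1f eligible patients, full-share saving EUR %.0f "
                    "(discount factor %.4f)", year, n, -full, d)

    ref_year = settings.reference_year
    n_ref = (float(eligible_override[ref_year])
             if eligible_override and ref_year in eligible_override
             else trajectory.eligible(ref_year))
    per_point = -incremental_cost(n_ref, 0.01, ref_year, drug_new, drug_ref,
                                  profile, settings)
    return BudgetResult(
        by_year=pd.DataFrame(rows),
        incremental=pd.DataFrame(inc_rows),
        per_point_saving=per_point,
        saving_at_full_share=saving_full,
        cumulative_saving=cumulative,
    )
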