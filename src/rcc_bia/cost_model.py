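"""Per-patient annual costs of first-line therapy for advanced RCC.

Two cost components are modelled from the Spanish NHS perspective, in
constant January-2013 euros:

* pharmacological cost — ex-factory price per 6-week cycle times 8 cycles
  per year (a 57% time-on-treatment fraction, reflecting discontinuation at
  progression, is applied only when costs are aggregated at budget level);
* adverse-event management cost — for each adverse event with trial
  incidence >= 30% in either arm, the grade-stratified incidence times the
  Spanish unit management cost, summed over grade bins and events. Trial
  incidences are treated as annual rates.

Default parameters cover pazopanib and sunitinib with the ten costed
adverse events (anorexia, diarrhea, fatigue, hand-foot syndrome,
hypertension, nausea, anemia, ALT elevation, neutropenia,
thrombocytopenia).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import floor

import pandas as pd

__all__ = [
    "DrugCostParams",
    "GradeBin",
    "AdverseEvent",
    "AEProfile",
    "ae_cost_per_event",
    "ae_cost_per_patient",
    "annual_pharm_cost",
    "overall_annual_cost_per_patient",
    "default_drugs",
    "default_ae_profile",
    "cost_breakdown_frame",
    "PAZOPANIB",
    "SUNITINIB",
]

PAZOPANIB = "pazopanib"
SUNITINIB = "sunitinib"


@dataclass(frozen=True)
class DrugCostParams:
    """Pharmacological cost parameters for one treatment arm."""

    name: str
    cost_per_cycle: float  # EUR per 6-week cycle, ex-factory VAT included
    cycles_per_year: int = 8
    time_on_treatment_fraction: float = 0.57

    def __post_init__(self) -> None:
        if self.cost_per_cycle < 0:
            raise ValueError("cost_per_cycle must be >= 0")
        if self.cycles_per_year < 1:
            raise ValueError("cycles_per_year must be >= 1")
        if not 0.0 < self.time_on_treatment_fraction <= 1.0:
            raise ValueError("time_on_treatment_fraction must be in (0, 1]")


@dataclass(frozen=True)
class GradeBin:
    """One severity bin of an adverse event: unit cost plus per-arm incidence."""

    grade: str
    unit_cost: float  # EUR per managed episode
    incidence: dict = field(default_factory=dict)  # arm -> annual incidence

    def __post_init__(self) -> None:
        if self.unit_cost < 0:
            raise ValueError(f"unit cost for grade {self.grade} must be >= 0")
        for arm, inc in self.incidence.items():
            if not 0.0 <= inc <= 1.0:
                raise ValueError(f"incidence {inc} for {arm}/{self.grade} outside [0, 1]")


@dataclass(frozen=True)
class AdverseEvent:
    label: str
    bins: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "bins", tuple(self.bins))


@dataclass(frozen=True)
class AEProfile:
    """Adverse-event cost profile: a set of events with grade bins."""

    events: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))

    def __iter__(self):
        return iter(self.events)

    def __len__(self):
        return len(self.events)


def ae_cost_per_event(event: AdverseEvent, arm: str) -> float:
    """Expected annual management cost of one adverse event for one arm."""
    total = 0.0
    for b in event.bins:
        inc = b.incidence.get(arm, 0.0)
        if inc > 0 and b.unit_cost is None:
            raise ValueError(f"{event.label}/{b.grade}: incidence without a unit cost")
        total += inc * b.unit_cost
    return total


def _round_cents(x: float) -> float:
    """Round half-up to the cent."""
    return floor(x * 100.0 + 0.5) / 100.0


def ae_cost_per_patient(profile: AEProfile, arm: str, round_events: bool = True) -> float:
    """Total annual per-patient adverse-event management cost for one arm.

    By default each event's cost is rounded to the cent before summing,
    mirroring how such cost tables are tabulated (the difference from the
    unrounded sum is below a cent per event). Pass ``round_events=False``
    for the exactly additive, unrounded sum.
    """
    if round_events:
        return sum(_round_cents(ae_cost_per_event(e, arm)) for e in profile)
    return sum(ae_cost_per_event(e, arm) for e in profile)


def annual_pharm_cost(drug: DrugCostParams) -> float:
    """Annual per-patient pharmacological cost: price per cycle x cycles.

    The time-on-treatment fraction is deliberately NOT applied here: the
    per-patient annual cost is quoted for a full treatment year, and the
    57% expected exposure enters only in the budget aggregation.
    """
    return drug.cost_per_cycle * drug.cycles_per_year


def overall_annual_cost_per_patient(drug: DrugCostParams, profile: AEProfile) -> float:
    """Annual per-patient pharmacological plus adverse-event cost."""
    return annual_pharm_cost(drug) + ae_cost_per_patient(profile, drug.name)


def default_drugs() -> dict:
    """Both treatment arms at published Spanish ex-factory prices."""
    return {
        PAZOPANIB: DrugCostParams(PAZOPANIB, cost_per_cycle=4046.0),
        SUNITINIB: DrugCostParams(SUNITINIB, cost_per_cycle=4904.0),
    }


def _event(label, *bins):
    return AdverseEvent(
        label,
        tuple(
            GradeBin(grade, cost, {PAZOPANIB: paz, SUNITINIB: sun})
            for grade, cost, paz, sun in bins
        ),
    )


def default_ae_profile() -> AEProfile:
    """COMPARZ adverse-event incidences with Spanish unit management costs.

    Each bin is (grade, unit cost EUR, pazopanib incidence, sunitinib
    incidence); a zero incidence means the grade was not reported for that
    arm. Bins with identical unit costs are kept separate to mirror the
    grade structure of the source data.
    """
    return AEProfile(
        (
            _event("Anorexia",
                   ("I-II", 13.43, 0.36, 0.34),
                   ("III", 13.43, 0.01, 0.03)),
            _event("Diarrhea",
                   ("I-II", 6.05, 0.54, 0.49),
                   ("III", 1376.13, 0.09, 0.07),
                   ("IV", 6171.42, 0.00, 0.01)),
            _event("Fatigue",
                   ("I-II", 1.62, 0.44, 0.45),
                   ("III", 1.62, 0.10, 0.17),
                   ("IV", 1.62, 0.01, 0.01)),
            _event("Hand-foot syndrome",
                   ("I-II", 51.87, 0.23, 0.38),
                   ("III", 189.41, 0.06, 0.11),
                   ("IV", 1165.50, 0.00, 0.01)),
            _event("Hypertension",
                   ("I-II", 16.88, 0.30, 0.25),
                   ("III", 16.88, 0.15, 0.15),
                   ("IV", 2612.71, 0.01, 0.01)),
            _event("Nausea",
                   ("I-II", 31.24, 0.43, 0.44),
                   ("III", 1942.30, 0.02, 0.02)),
            _event("Anemia",
                   ("I-II", 200.26, 0.29, 0.53),
                   ("III", 261.70, 0.01, 0.06),
                   ("IV", 507.46, 0.01, 0.01)),
            _event("ALT elevation",
                   ("I-II", 119.30, 0.43, 0.38),
                   ("III", 236.16, 0.15, 0.04),
                   ("IV", 2498.64, 0.02, 0.01)),
            _event("Neutropenia",
                   ("I-II", 356.78, 0.32, 0.48),
                   ("III", 356.78, 0.04, 0.19),
                   ("IV", 955.53, 0.01, 0.01)),
            _event("Thrombocytopenia",
                   ("I-II", 139.29, 0.37, 0.56),
                   ("III", 449.54, 0.03, 0.18),
                   ("IV", 1380.29, 0.01, 0.04)),
        )
    )


def cost_breakdown_frame(profile: AEProfile, drugs: dict) -> pd.DataFrame:
    """Per-event and per-patient cost breakdown for both arms."""
    arms = list(drugs)
    rows = []
    for event in profile:
        row = {"item": event.label}
        for arm in arms:
            row[arm] = ae_cost_per_event(event, arm)
        rows.append(row)
    rows.append({"item": "AE management total",
                 **{a: ae_cost_per_patient(profile, a) for a in arms}})
    rows.append({"item": "Annual pharmacological cost",
                 **{a: annual_pharm_cost(drugs[a]) for a in arms}})
    rows.append({"item": "Overall annual cost per patient",
                 **{a: overall_annual_cost_per_patient(drugs[a], profile) for a in arms}})
    df = pd.DataFrame(rows)
    if len(arms) == 2:
        df["difference"] = df[arms[0]] - df[arms[1]]
    return df
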