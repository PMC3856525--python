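"""One-way (tornado) sensitivity analysis of the budget impact.

Each epidemiological parameter is moved in turn to its lower and upper
published bound while everything else — including the base population, which
is NOT recalibrated — stays at base case, the whole pipeline is re-run, and
the incremental cost of treating every eligible patient with pazopanib in
the output year is recomputed. Parameters are ranked by the swing (absolute
difference between the bound results) for a tornado display. The tied
progression probabilities (years 2-3, 4-5, 6-7 and 8-10) are perturbed as
grouped parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .budget_impact import BIASettings, incremental_cost
from .cost_model import AEProfile
from .demographics import DemographicsSeries
from .epi_model import EpiParams, simulate

__all__ = [
    "SensitivityRange",
    "TornadoEntry",
    "default_ranges",
    "run_univariate",
    "tornado_frame",
    "plot_tornado",
    "PARAMETER_SETTERS",
]


@dataclass(frozen=True)
class SensitivityRange:
    """Lower/upper bound for one model parameter (grouped parameters allowed)."""

    parameter: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError(f"{self.parameter}: lower bound exceeds upper bound")


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    base_result: float
    low_result: float
    high_result: float

    @property
    def swing(self) -> float:
        return abs(self.high_result - self.low_result)


def _set_progression(params: EpiParams, indices, value) -> EpiParams:
    probs = list(params.progression_prob)
    for i in indices:
        probs[i] = value
    return params.with_(progression_prob=tuple(probs))


#: parameter name -> function(EpiParams, value) -> EpiParams
PARAMETER_SETTERS = {
    "kidney_incidence_40plus": lambda p, v: p.with_(kidney_incidence_40plus=v),
    "rcc_fraction": lambda p, v: p.with_(rcc_fraction=v),
    "advanced_at_diagnosis_fraction": lambda p, v: p.with_(advanced_at_diagnosis_fraction=v),
    "localized_mortality": lambda p, v: p.with_(localized_mortality=v),
    "progression_year1": lambda p, v: _set_progression(p, [0], v),
    "progression_years2_3": lambda p, v: _set_progression(p, [1, 2], v),
    "progression_years4_5": lambda p, v: _set_progression(p, [3, 4], v),
    "progression_years6_7": lambda p, v: _set_progression(p, [5, 6], v),
    "progression_years8_10": lambda p, v: _set_progression(p, [7, 8, 9], v),
    "fav_int_risk_fraction": lambda p, v: p.with_(fav_int_risk_fraction=v),
}

_BASE_GETTERS = {
    "progression_year1": lambda p: p.progression_prob[0],
    "progression_years2_3": lambda p: p.progression_prob[1],
    "progression_years4_5": lambda p: p.progression_prob[3],
    "progression_years6_7": lambda p: p.progression_prob[5],
    "progression_years8_10": lambda p: p.progression_prob[7],
}


def default_ranges() -> list:
    """Published lower/upper bounds for the epidemiological parameters."""
    return [
        SensitivityRange("kidney_incidence_40plus", 17.82e-5, 21.78e-5),
        SensitivityRange("rcc_fraction", 0.85, 0.95),
        SensitivityRange("advanced_at_diagnosis_fraction", 0.15, 0.25),
        SensitivityRange("localized_mortality", 0.0149, 0.0183),
        SensitivityRange("progression_year1", 0.1186, 0.1449),
        SensitivityRange("progression_years2_3", 0.0411, 0.0502),
        SensitivityRange("progression_years4_5", 0.0173, 0.0211),
        SensitivityRange("progression_years6_7", 0.0148, 0.0181),
        SensitivityRange("progression_years8_10", 0.0113, 0.0138),
        SensitivityRange("fav_int_risk_fraction", 0.801, 0.979),
    ]


def _base_value(params: EpiParams, name: str) -> float:
    if name in _BASE_GETTERS:
        return _BASE_GETTERS[name](params)
    return getattr(params, name)


def _pipeline_result(params: EpiParams, demo: DemographicsSeries, drugs: dict,
                     profile: AEProfile, settings: BIASettings, year: int,
                     share: float, new_arm: str, ref_arm: str) -> float:
    traj = simulate(params, demo)
    n = traj.eligible(year)
    return incremental_cost(n, share, year, drugs[new_arm], drugs[ref_arm],
                            profile, settings)


def run_univariate(params: EpiParams, demo: DemographicsSeries, drugs: dict,
                   profile: AEProfile, settings: BIASettings,
                   ranges=None, output_year: int = 2013, share: float = 1.0,
                   new_arm: str = "pazopanib", ref_arm: str = "sunitinib") -> list:
    """Re-run the pipeline at each parameter bound; return sorted tornado entries.

    The base 40+ population series is held fixed so that perturbing an
    epidemiological parameter genuinely changes the modelled patient count
    rather than being absorbed by recalibration. Entries are sorted by
    descending swing (ties broken alphabetically), so the output does not
    depend on the order ranges are supplied.
    """
    if ranges is None:
        ranges = default_ranges()
    base = _pipeline_result(params, demo, drugs, profile, settings,
                            output_year, share, new_arm, ref_arm)
    entries = []
    for rng in ranges:
        if rng.parameter not in PARAMETER_SETTERS:
            raise KeyError(
                f"unknown sensitivity parameter {rng.parameter!r}; known: "
                f"{sorted(PARAMETER_SETTERS)}"
            )
        base_value = _base_value(params, rng.parameter)
        if not rng.lower <= base_value <= rng.upper:
            raise ValueError(
                f"{rng.parameter}: base value {base_value} outside "
                f"[{rng.lower}, {rng.upper}]"
            )
        setter = PARAMETER_SETTERS[rng.parameter]
        low = _pipeline_result(setter(params, rng.lower), demo, drugs, profile,
                               settings, output_year, share, new_arm, ref_arm)
        high = _pipeline_result(setter(params, rng.upper), demo, drugs, profile,
                                settings, output_year, share, new_arm, ref_arm)
        entries.append(TornadoEntry(rng.parameter, base, low, high))
    entries.sort(key=lambda e: (-e.swing, e.parameter))
    return entries


def tornado_frame(entries) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "base_result": e.base_result,
                "low_result": e.low_result,
                "high_result": e.high_result,
                "swing": e.swing,
            }
            for e in entries
        ]
    )


def plot_tornado(entries, path) -> None:
    """Horizontal-bar tornado chart of the sensitivity results."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    entries = list(entries)[::-1]  # largest swing on top
    fig, ax = plt.subplots(figsize=(8, 0.5 * len(entries) + 1.5))
    for i, e in enumerate(entries):
        lo, hi = sorted((e.low_result, e.high_result))
        ax.barh(i, hi - lo, left=lo, color="#4878b0", height=0.6)
    ax.axvline(entries[0].base_result if entries else 0.0, color="k", lw=1)
    ax.set_yticks(range(len(entries)))
    ax.set_yticklabels([e.parameter for e in entries])
    ax.set_xlabel("Incremental cost (EUR, negative = saving)")
    ax.set_title("One-way sensitivity of the budget impact")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
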