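"""Open-population Markov model of renal cell carcinoma natural history.

Thirteen health states, annual cycles: the general population aged 40+
(GP40+) feeds newly diagnosed RCC cases; a fraction is advanced at diagnosis
and enters the advanced-RCC state (ARCC) directly, the remainder is treated
surgically for localized disease and enters a ten-year sequence of tunnel
states (RCC1..RCC10, indexed by years since surgery). Each tunnel year a
patient may progress to advanced disease (with a probability that decays
with time since surgery), die of localized disease, or move on to the next
tunnel position; whoever leaves position 10 without progressing is
considered free of disease and exits the model. Advanced patients occupy
ARCC for a single cycle and then move to the absorbing post-advanced/death
state (PARCC/D).

Because the population is open (new diagnoses flow in every cycle), a
simulation warmed up from an empty tunnel over ten or more years yields, for
each calendar year, the number of incident advanced cases, the number of
post-surgical relapses ("progressions"), and the tunnel census from which
k-year disease prevalence is computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from math import floor

import numpy as np
import pandas as pd

from .demographics import DemographicsSeries

__all__ = [
    "EpiParams",
    "StateVector",
    "EpiTrajectory",
    "step",
    "simulate",
    "eligible_advanced",
    "prevalence",
    "validation_report",
    "round_patients",
    "GLOBOCAN_PREVALENCE_REFERENCE",
    "TUNNEL_YEARS",
]

TUNNEL_YEARS = 10

#: GLOBOCAN-derived adult RCC prevalence references (per 100,000) for the
#: 1-, 3- and 5-year windows, already scaled by the 90% RCC share of kidney
#: cancer. Used as external validation constants, never as model inputs.
GLOBOCAN_PREVALENCE_REFERENCE = {1: 7.6, 3: 20.2, 5: 31.1}

#: Default annual probability of progression to advanced RCC by years since
#: surgery (year 1, years 2-3, 4-5, 6-7 and 8-10 share published values).
DEFAULT_PROGRESSION_PROB = (
    0.1318,
    0.0457, 0.0457,
    0.0192, 0.0192,
    0.0164, 0.0164,
    0.0126, 0.0126, 0.0126,
)


def round_patients(x: float) -> int:
    """Round a patient count half-up to a whole patient (reporting only)."""
    return int(floor(x + 0.5))


@dataclass(frozen=True)
class EpiParams:
    """Epidemiological parameters of the RCC natural-history model.

    Rates are expressed per person per year (the kidney-cancer incidence
    default 19.8 per 100,000 is stored as 19.8e-5); fractions are
    dimensionless in [0, 1].
    """

    kidney_incidence_40plus: float = 19.8e-5
    rcc_fraction: float = 0.90
    advanced_at_diagnosis_fraction: float = 0.20
    localized_mortality: float = 0.0166
    progression_prob: tuple = field(default=DEFAULT_PROGRESSION_PROB)
    fav_int_risk_fraction: float = 0.89
    to_post_advanced_prob: float = 1.0
    # Timing switch: when True, the newly diagnosed localized cohort bears
    # its first-year progression/mortality risk during the diagnosis year
    # itself instead of entering tunnel position 1 for the next cycle.
    same_cycle_first_risk: bool = False
    # Census switch: count advanced (ARCC) occupancy as prevalent cases.
    prevalence_includes_advanced: bool = False

    def __post_init__(self) -> None:
        probs = tuple(float(p) for p in self.progression_prob)
        object.__setattr__(self, "progression_prob", probs)
        if len(probs) != TUNNEL_YEARS:
            raise ValueError(f"progression_prob must have {TUNNEL_YEARS} entries")
        scalars = {
            "kidney_incidence_40plus": self.kidney_incidence_40plus,
            "rcc_fraction": self.rcc_fraction,
            "advanced_at_diagnosis_fraction": self.advanced_at_diagnosis_fraction,
            "localized_mortality": self.localized_mortality,
            "fav_int_risk_fraction": self.fav_int_risk_fraction,
            "to_post_advanced_prob": self.to_post_advanced_prob,
        }
        for name, value in scalars.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
        for t, p in enumerate(probs, start=1):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"progression_prob year {t} outside [0, 1]")
            if p + self.localized_mortality > 1.0 + 1e-12:
                raise ValueError(
                    f"competing transitions exceed 1 in tunnel year {t}: "
                    f"{p} + {self.localized_mortality}"
                )

    @property
    def progression(self) -> np.ndarray:
        return np.asarray(self.progression_prob, dtype=float)

    def with_(self, **changes) -> "EpiParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


@dataclass(frozen=True)
class StateVector:
    """Occupancy of the 13 Markov states at the end of one annual cycle."""

    year: int
    gp40plus: float
    rcc_tunnel: np.ndarray  # positions 1..10, years since surgery
    arcc: float
    parcc_d: float
    cured: float = 0.0  # cumulative disease-free exits from tunnel position 10

    def __post_init__(self) -> None:
        tunnel = np.asarray(self.rcc_tunnel, dtype=float)
        object.__setattr__(self, "rcc_tunnel", tunnel)
        if tunnel.shape != (TUNNEL_YEARS,):
            raise ValueError(f"rcc_tunnel must have shape ({TUNNEL_YEARS},)")
        occupancies = np.concatenate([tunnel, [self.arcc, self.parcc_d, self.cured]])
        if (occupancies < -1e-9).any():
            raise ValueError("negative state occupancy")

    @classmethod
    def empty(cls, year: int, gp40plus: float) -> "StateVector":
        return cls(year=year, gp40plus=gp40plus, rcc_tunnel=np.zeros(TUNNEL_YEARS),
                   arcc=0.0, parcc_d=0.0, cured=0.0)


@dataclass
class EpiTrajectory:
    """Per-year flows and states from an open-population simulation.

    ``tunnel_census[i]`` holds the tunnel occupancies after year ``i``'s
    transitions but before the next cohort enters position 1 — the year-end
    census used for prevalence, in which position k holds the survivors of
    the cohort diagnosed k years before the census point.
    """

    years: np.ndarray
    states: list  # list[StateVector], end-of-year
    tunnel_census: list  # list[np.ndarray]
    incident_advanced: np.ndarray
    incident_localized: np.ndarray
    progressions: np.ndarray
    params: EpiParams

    def _index(self, year: int) -> int:
        i = int(year) - int(self.years[0])
        if not 0 <= i < len(self.years):
            raise KeyError(f"year {year} outside simulated span "
                           f"{self.years[0]}-{self.years[-1]}")
        return i

    def eligible(self, year: int, rounded: bool = False) -> float:
        """Advanced RCC patients of favorable/intermediate risk in ``year``."""
        i = self._index(year)
        value = eligible_advanced(
            self.incident_advanced[i], self.progressions[i],
            self.params.fav_int_risk_fraction,
        )
        return round_patients(value) if rounded else value

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "incident_localized": self.incident_localized,
                "incident_advanced": self.incident_advanced,
                "progressions": self.progressions,
                "eligible_advanced": [
                    self.eligible(y) for y in self.years
                ],
            }
        )

    def occupancy_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.states:
            row = {"year": s.year, "gp40plus": s.gp40plus}
            for k in range(TUNNEL_YEARS):
                row[f"rcc{k + 1}"] = s.rcc_tunnel[k]
            row.update({"arcc": s.arcc, "parcc_d": s.parcc_d, "cured": s.cured})
            rows.append(row)
        return pd.DataFrame(rows)


def step(state: StateVector, params: EpiParams, pop40plus_this_year: float):
    """Advance the model by one annual cycle.

    Returns ``(new_state, incident_advanced, incident_localized,
    progressions)``. Within the cycle: new RCC diagnoses are drawn from the
    40+ population at the crude incidence rate; the advanced fraction flows
    straight into ARCC, the localized remainder is scheduled into tunnel
    position 1 (next cycle by default, or at immediate risk under the
    same-cycle switch); each occupied tunnel position sends its progression
    share to ARCC, its mortality share to PARCC/D and the remainder one
    position down the tunnel, with position 10's remainder exiting as cured;
    the previous ARCC occupancy moves on to PARCC/D.
    """
    if pop40plus_this_year < 0:
        raise ValueError("population must be non-negative")
    p = params.progression
    m = params.localized_mortality

    incident_rcc = pop40plus_this_year * params.kidney_incidence_40plus * params.rcc_fraction
    incident_advanced = incident_rcc * params.advanced_at_diagnosis_fraction
    incident_localized = incident_rcc - incident_advanced

    at_risk = state.rcc_tunnel.copy()
    if params.same_cycle_first_risk:
        at_risk[0] = at_risk[0] + incident_localized

    progressions = float(at_risk @ p)
    tunnel_deaths = float(at_risk.sum() * m)
    survivors = at_risk * (1.0 - p - m)

    new_tunnel = np.zeros(TUNNEL_YEARS)
    new_tunnel[1:] = survivors[:-1]
    cured_exit = float(survivors[-1])
    if not params.same_cycle_first_risk:
        new_tunnel[0] = incident_localized

    q = params.to_post_advanced_prob
    new_arcc = state.arcc * (1.0 - q) + incident_advanced + progressions
    new_parcc_d = state.parcc_d + state.arcc * q + tunnel_deaths

    new_state = StateVector(
        year=state.year + 1,
        gp40plus=pop40plus_this_year,
        rcc_tunnel=new_tunnel,
        arcc=new_arcc,
        parcc_d=new_parcc_d,
        cured=state.cured + cured_exit,
    )
    if (new_tunnel < -1e-9).any() or new_arcc < -1e-9 or new_parcc_d < -1e-9:
        raise ArithmeticError("negative occupancy after cycle arithmetic")
    return new_state, incident_advanced, incident_localized, progressions


def simulate(params: EpiParams, demo: DemographicsSeries) -> EpiTrajectory:
    """Run the annual-cycle simulation over the demographic span.

    Starts from an empty tunnel in the first year of ``demo`` (by default
    2003, giving ten warm-up years before the 2013 report year) and records
    per-year flows and the year-end tunnel census. Deterministic.
    """
    if demo.n_years < TUNNEL_YEARS + 1:
        warnings.warn(
            f"demographic span of {demo.n_years} years is shorter than the "
            f"{TUNNEL_YEARS}-year tunnel plus one report year; early report "
            "years will draw on a partially warmed tunnel",
            stacklevel=2,
        )
    state = StateVector.empty(int(demo.years[0]) - 1, float(demo.pop40plus[0]))
    states, censuses = [], []
    inc_adv = np.zeros(demo.n_years)
    inc_loc = np.zeros(demo.n_years)
    progs = np.zeros(demo.n_years)
    p = params.progression
    m = params.localized_mortality
    for i, year in enumerate(demo.years):
        pop = float(demo.pop40plus[i])
        at_risk = state.rcc_tunnel.copy()
        state, ia, il, pr = step(state, params, pop)
        if params.same_cycle_first_risk:
            at_risk[0] += il
        # year-end census: this year's survivors, before next cohort entry
        censuses.append(at_risk * (1.0 - p - m))
        states.append(state)
        inc_adv[i], inc_loc[i], progs[i] = ia, il, pr
    return EpiTrajectory(
        years=demo.years.copy(),
        states=states,
        tunnel_census=censuses,
        incident_advanced=inc_adv,
        incident_localized=inc_loc,
        progressions=progs,
        params=params,
    )


def eligible_advanced(incident_advanced: float, progressions: float,
                      fav_int_risk_fraction: float) -> float:
    """Advanced RCC patients eligible for first-line anti-VEGF therapy.

    Sum of the year's incident advanced diagnoses and post-surgical
    relapses, scaled by the favorable/intermediate-risk fraction. Returns
    the unrounded value; use :func:`round_patients` for reporting.
    """
    if incident_advanced < 0 or progressions < 0:
        raise ValueError("patient counts must be non-negative")
    if not 0.0 <= fav_int_risk_fraction <= 1.0:
        raise ValueError("fav_int_risk_fraction must be in [0, 1]")
    return (incident_advanced + progressions) * fav_int_risk_fraction


def prevalence(trajectory: EpiTrajectory, demo: DemographicsSeries,
               year: int, window_years: int) -> float:
    """k-year adult RCC prevalence per 100,000 at the end of ``year``.

    Counts post-surgical patients diagnosed within the last ``window_years``
    years who are alive at the year-end census (tunnel positions
    1..window_years after the year's transitions), divided by the adult
    population. Survivors of advanced disease are excluded unless the
    ``prevalence_includes_advanced`` switch is set.
    """
    if not 1 <= window_years <= TUNNEL_YEARS:
        raise ValueError(f"window_years must be in 1..{TUNNEL_YEARS}")
    i = trajectory._index(year)
    count = float(trajectory.tunnel_census[i][:window_years].sum())
    if trajectory.params.prevalence_includes_advanced:
        count += trajectory.states[i].arcc
    return 1e5 * count / demo.pop_adult_in(year)


def validation_report(trajectory: EpiTrajectory, demo: DemographicsSeries,
                      year: int = 2013) -> pd.DataFrame:
    """Model prevalence vs GLOBOCAN-derived references, per 100,000 adults."""
    rows = []
    for window, ref in GLOBOCAN_PREVALENCE_REFERENCE.items():
        model = prevalence(trajectory, demo, year, window)
        rows.append(
            {
                "window_years": window,
                "model_per_100k": model,
                "reference_per_100k": ref,
                "relative_difference": model / ref - 1.0,
            }
        )
    return pd.DataFrame(rows)
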