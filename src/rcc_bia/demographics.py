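"""Population denominators for the open-population disease model.

The epidemiological model needs two annual population series for Spain:
persons aged 40 and above (the pool exposed to kidney-cancer incidence) and
the adult population (the denominator for prevalence per 100,000). This
module provides a synthetic stand-in built from a single base value and a
constant geometric growth rate, plus a calibration helper that inverts the
incidence chain so the base population reproduces a target count of incident
advanced cases in an anchor year. Real series can be substituted from a CSV
with columns ``year,pop40plus,pop_adult``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DemographicsSeries",
    "generate_series",
    "calibrate_population",
    "series_from_csv",
    "DEFAULT_GROWTH_RATE",
    "DEFAULT_ADULT_RATIO",
]

#: Annual growth of the 40+ population implied by the year-on-year growth of
#: incident advanced cases under a constant incidence rate (~1.4 %/year).
DEFAULT_GROWTH_RATE = 0.01405

#: Ratio of the adult (15+) to the 40+ Spanish population.
DEFAULT_ADULT_RATIO = 1.653


@dataclass(frozen=True)
class DemographicsSeries:
    """Annual population series indexed by calendar year.

    Attributes
    ----------
    start_year : int
        First calendar year of the series.
    pop40plus : numpy.ndarray
        Persons aged >= 40, one value per year.
    pop_adult : numpy.ndarray
        Adult persons (>= 15 by default convention), one value per year.
    growth_rate : float or None
        Annual multiplicative growth used to generate the series; ``None``
        when the series was loaded from external data.
    """

    start_year: int
    pop40plus: np.ndarray
    pop_adult: np.ndarray
    growth_rate: float | None = field(default=None)

    def __post_init__(self) -> None:
        p40 = np.asarray(self.pop40plus, dtype=float)
        pad = np.asarray(self.pop_adult, dtype=float)
        object.__setattr__(self, "pop40plus", p40)
        object.__setattr__(self, "pop_adult", pad)
        if p40.ndim != 1 or p40.size < 1 or pad.shape != p40.shape:
            raise ValueError("population series must be equal-length 1-d arrays")
        if not (p40 > 0).all() or not (pad > 0).all():
            raise ValueError("population values must be strictly positive")
        if (pad < p40 - 1e-9).any():
            raise ValueError("adult population cannot be smaller than the 40+ population")

    @property
    def n_years(self) -> int:
        return self.pop40plus.size

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.start_year + self.n_years)

    def _index(self, year: int) -> int:
        i = int(year) - self.start_year
        if not 0 <= i < self.n_years:
            raise KeyError(f"year {year} outside series {self.start_year}-{self.start_year + self.n_years - 1}")
        return i

    def pop40plus_in(self, year: int) -> float:
        return float(self.pop40plus[self._index(year)])

    def pop_adult_in(self, year: int) -> float:
        return float(self.pop_adult[self._index(year)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"year": self.years, "pop40plus": self.pop40plus, "pop_adult": self.pop_adult}
        )


def generate_series(
    base_pop40plus: float,
    adult_ratio: float,
    growth_rate: float,
    start_year: int,
    n_years: int,
    anchor_year: int | None = None,
) -> DemographicsSeries:
    """Build a geometric population series.

    ``pop40plus`` grows by ``(1 + growth_rate)`` per year from
    ``base_pop40plus`` at ``anchor_year`` (default: ``start_year``); years
    before the anchor are obtained by backward extrapolation.
    ``pop_adult = adult_ratio * pop40plus`` throughout. Deterministic.
    """
    if base_pop40plus <= 0:
        raise ValueError("base_pop40plus must be positive")
    if adult_ratio < 1:
        raise ValueError("adult_ratio must be >= 1 (adults include the 40+ population)")
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    anchor = start_year if anchor_year is None else int(anchor_year)
    years = np.arange(start_year, start_year + n_years)
    p40 = base_pop40plus * (1.0 + growth_rate) ** (years - anchor)
    return DemographicsSeries(
        start_year=int(start_year),
        pop40plus=p40,
        pop_adult=adult_ratio * p40,
        growth_rate=float(growth_rate),
    )


def calibrate_population(epi, target_incident_advanced: float, target_year: int | None = None) -> float:
    """Invert the incidence chain to find the 40+ population.

    Returns the population aged 40+ such that

    ``pop40plus * kidney_incidence * rcc_fraction * advanced_at_diagnosis_fraction``

    equals ``target_incident_advanced`` — a closed-form division. ``epi`` is
    an :class:`~rcc_bia.epi_model.EpiParams` (or anything exposing the three
    rate attributes). ``target_year`` is informational only.
    """
    if target_incident_advanced <= 0:
        raise ValueError("target_incident_advanced must be positive")
    denom = (
        epi.kidney_incidence_40plus
        * epi.rcc_fraction
        * epi.advanced_at_diagnosis_fraction
    )
    if denom <= 0:
        raise ZeroDivisionError("incidence chain has a zero factor; cannot calibrate")
    return target_incident_advanced / denom


def series_from_csv(path, growth_rate: float | None = None) -> DemographicsSeries:
    """Load an external population series from ``year,pop40plus,pop_adult`` CSV.

    Years must be consecutive. Intended for substituting real national-
    statistics data for the synthetic geometric series.
    """
    df = pd.read_csv(path)
    required = {"year", "pop40plus", "pop_adult"}
    if not required.issubset(df.columns):
        raise ValueError(f"demographics CSV must have columns {sorted(required)}")
    df = df.sort_values("year").reset_index(drop=True)
    years = df["year"].to_numpy()
    if not np.array_equal(years, np.arange(years[0], years[0] + len(years))):
        raise ValueError("demographics CSV must cover consecutive years")
    return DemographicsSeries(
        start_year=int(years[0]),
        pop40plus=df["pop40plus"].to_numpy(dtype=float),
        pop_adult=df["pop_adult"].to_numpy(dtype=float),
        growth_rate=growth_rate,
    )
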