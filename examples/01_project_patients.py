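"""Project the advanced-RCC patient population in Spain, 2013-2015.

Calibrates the 40+ population so that 2013 yields 854 incident advanced
cases, warms the ten-year post-surgery tunnel from 2003, and prints the two
streams that feed first-line therapy: patients diagnosed with advanced
disease and patients relapsing after surgery for localized disease.
"""

from rcc_bia import EpiParams, calibrate_population, generate_series, simulate
from rcc_bia.demographics import DEFAULT_ADULT_RATIO, DEFAULT_GROWTH_RATE
from rcc_bia.epi_model import round_patients

params = EpiParams()
base_pop = calibrate_population(params, target_incident_advanced=854, target_year=2013)
print(f"40+ population calibrated for 2013: {base_pop:,.0f} persons")

demo = generate_series(base_pop, DEFAULT_ADULT_RATIO, DEFAULT_GROWTH_RATE,
                       start_year=2003, n_years=13, anchor_year=2013)
trajectory = simulate(params, demo)

print(f"\n{'year':>4}  {'advanced at dx':>14}  {'relapses':>9}  {'eligible (fav/int)':>18}")
for year in (2013, 2014, 2015):
    i = trajectory._index(year)
    print(f"{year:>4}  {trajectory.incident_advanced[i]:>14.0f}  "
          f"{trajectory.progressions[i]:>9.0f}  "
          f"{trajectory.eligible(year, rounded=True):>18d}")

n = round_patients(trajectory.eligible(2013))
print(f"\n{n:,} patients with favorable/intermediate-risk advanced RCC are the")
print("2013 candidates for first-line anti-VEGF therapy: the sum of the two")
print("streams above scaled by the 89% favorable/intermediate-risk fraction.")
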