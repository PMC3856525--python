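"""Budget impact for the Spanish NHS of switching first-line therapy to
pazopanib, 2013-2015, discounted at 3% to 2013.

Pharmacological spending is weighted by the 57% expected time on treatment
(patients discontinue at progression); adverse-event management costs apply
once per treated patient-year.
"""

from rcc_bia import (
    BIASettings,
    EpiParams,
    calibrate_population,
    default_ae_profile,
    default_drugs,
    generate_series,
    incremental_cost,
    run_bia,
    simulate,
)
from rcc_bia.demographics import DEFAULT_ADULT_RATIO, DEFAULT_GROWTH_RATE

params = EpiParams()
demo = generate_series(calibrate_population(params, 854, 2013),
                       DEFAULT_ADULT_RATIO, DEFAULT_GROWTH_RATE, 2003, 13,
                       anchor_year=2013)
trajectory = simulate(params, demo)
drugs, profile, settings = default_drugs(), default_ae_profile(), BIASettings()

result = run_bia(trajectory, drugs, profile, settings)
print(f"{'year':>4} {'arm':<10} {'patients':>8} {'overall cost (discounted)':>26}")
for _, row in result.by_year.iterrows():
    print(f"{row['year']:>4} {row['arm']:<10} {row['patients']:>8.0f} "
          f"{row['overall_cost']:>24,.0f}€")

print(f"\nfull substitution saves, by year: "
      + ", ".join(f"{y}: {s:,.0f}€" for y, s in result.saving_at_full_share.items()))
print(f"three-year discounted saving:      {result.cumulative_saving:,.0f}€")
print(f"saving per 1-point share increase: {result.per_point_saving:,.0f}€")

share = 0.30
inc = incremental_cost(trajectory.eligible(2013), share, 2013,
                       drugs["pazopanib"], drugs["sunitinib"], profile, settings)
print(f"\nAt a {share:.0%} pazopanib market share the 2013 budget impact is "
      f"{inc:,.0f}€ —\nnegative values are savings, and the impact is exactly "
      "linear in the share.")
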