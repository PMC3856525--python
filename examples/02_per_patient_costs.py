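"""Per-patient annual costs of first-line pazopanib vs sunitinib.

Prints the grade-weighted adverse-event management cost per event, the
annual pharmacological cost (8 six-week cycles at ex-factory prices), and
the overall per-patient difference between the arms.
"""

from rcc_bia import (
    ae_cost_per_event,
    ae_cost_per_patient,
    annual_pharm_cost,
    default_ae_profile,
    default_drugs,
    overall_annual_cost_per_patient,
)

drugs = default_drugs()
profile = default_ae_profile()

print(f"{'adverse event':<20} {'pazopanib':>10} {'sunitinib':>10}")
for event in profile:
    paz = ae_cost_per_event(event, "pazopanib")
    sun = ae_cost_per_event(event, "sunitinib")
    print(f"{event.label:<20} {paz:>9.2f}€ {sun:>9.2f}€")
print(f"{'AE total':<20} {ae_cost_per_patient(profile, 'pazopanib'):>9.2f}€ "
      f"{ae_cost_per_patient(profile, 'sunitinib'):>9.2f}€")

paz, sun = drugs["pazopanib"], drugs["sunitinib"]
print(f"\nannual pharmacological cost: pazopanib {annual_pharm_cost(paz):,.0f}€, "
      f"sunitinib {annual_pharm_cost(sun):,.0f}€")
o_paz = overall_annual_cost_per_patient(paz, profile)
o_sun = overall_annual_cost_per_patient(sun, profile)
print(f"overall per patient:         pazopanib {o_paz:,.0f}€, sunitinib {o_sun:,.0f}€")
print(f"\nA treatment year costs {o_sun - o_paz:,.0f}€ "
      f"({(o_sun - o_paz) / o_sun:.0%}) less per patient with pazopanib —")
print("the drug is cheaper per cycle and its adverse-event profile (less")
print("myelosuppression) is cheaper to manage despite more liver-enzyme work-ups.")
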