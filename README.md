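# rcc-bia

A deterministic, open-population Markov model of the natural history of
renal cell carcinoma (RCC) in Spain, coupled to a cost model and a
budget-impact analysis (BIA) of first-line **pazopanib vs sunitinib** for
advanced RCC under the national health system perspective. It is written
for health-economics and HTA analysts who want a transparent, fully
configurable re-implementation of a published budget-impact model — every
parameter is an editable config value, every result a reproducible
computation.

## The model

Thirteen health states evolve in annual cycles over 2003–2015:

```
GP40+  →  RCC1 → RCC2 → ... → RCC10  → (disease-free)
   \          ↓ p_t per tunnel year
    \________ ARCC ______→  PARCC/D
```

* **GP40+** — general population aged ≥40, exposed to a crude kidney-cancer
  incidence of 19.8/100,000/year, of which 90% is RCC and 20% is advanced
  at diagnosis.
* **RCC1…RCC10** — tunnel states counting years since surgery for localized
  disease. Tunnel states give the memoryless chain a memory: the annual
  probability of relapse to advanced disease depends on time since surgery
  (13.18% in year 1, decaying to 1.26% in years 8–10), alongside a 1.66%
  annual localized-disease mortality. After ten relapse-free years patients
  are considered cured and leave the model.
* **ARCC** — advanced RCC (at diagnosis or by relapse), occupied for exactly
  one cycle; 89% of these patients have favorable/intermediate prognostic
  risk and are eligible for first-line anti-VEGF therapy.
* **PARCC/D** — absorbing post-advanced/death state.

The population is *open*: each cycle new diagnoses flow in, so the model
projects calendar-year patient counts rather than following a closed
cohort. The 40+ denominator is a synthetic geometric series calibrated in
closed form so that 2013 produces 854 incident advanced cases
(≈23.96 million persons, growing 1.4%/year).

On the cost side, each arm's annual cost per patient is

    cost_per_cycle × 8 cycles          (pharmacological, ex-factory prices)
  + Σ_events Σ_grades incidence × unit_cost   (adverse-event management)

and the budget for year *y* with pazopanib market share *s* is

    n_y × [ s·c_paz + (1−s)·c_sun ] × (1.03)^−(y−2013)

where the pharmacological component of each `c` is weighted by the 57%
expected time on treatment before progression. The *budget impact* is the
difference against the all-sunitinib scenario; it is linear in the share.
A one-way sensitivity analysis re-runs the whole pipeline at each
epidemiological parameter's published bounds and ranks them by swing
(tornado ordering).

## Worked example

```bash
python examples/01_project_patients.py
```

```
40+ population calibrated for 2013: 23,961,841 persons

year  advanced at dx   relapses  eligible (fav/int)
2013             854        926                1584
2014             866        939                1606
2015             878        952                1629
```

854 patients are diagnosed with advanced disease in 2013 (by calibration)
and 926 relapse from the post-surgical tunnel; 89% of the 1,780 total —
1,584 patients — are eligible for first-line therapy. Costs
(`examples/02_per_patient_costs.py`): a treatment year costs €33,030 with
pazopanib and €40,206 with sunitinib — €7,177 (18%) less per patient, from
a cheaper cycle price (€4,046 vs €4,904) and a cheaper-to-manage
adverse-event profile (€661.57 vs €974.08 per patient-year). Aggregated
(`examples/03_budget_impact.py`): full substitution of sunitinib by
pazopanib would save the NHS €6,691,438 in 2013 — €66,914 per point of
market share — and €19.8 million (discounted at 3%) over 2013–2015. The
tornado analysis (`examples/04_sensitivity_tornado.py`) shows the saving
stays negative-cost at every published parameter bound, driven mostly by
kidney-cancer incidence, the favorable/intermediate-risk fraction, the
advanced-at-diagnosis fraction and the RCC fraction.

As external validation, the modelled 1/3/5-year adult RCC prevalence
(7.2 / 20.1 / 31.6 per 100,000 in 2013) sits within 5% of GLOBOCAN-derived
references (`rcc-bia validate`).

## Command line

```bash
rcc-bia run      --out results/          # full pipeline + reproduction report
rcc-bia bia      --share 0.5             # budget impact at one market share
rcc-bia tornado  --out results/ --chart  # sensitivity analysis
rcc-bia validate                         # prevalence vs GLOBOCAN references
```

All subcommands accept `--config config.yaml`; any subset of the default
configuration (see `rcc_bia.config.default_config()`) can be overridden,
including substituting a real demographic series via a
`year,pop40plus,pop_adult` CSV.

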