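# Methods

## Model structure

The epidemiological core is a deterministic, open-population state-transition
model with annual cycles. States: the general population aged 40+ (`GP40+`),
ten tunnel states `RCC1…RCC10` indexed by years since surgery for localized
RCC, a one-cycle advanced-disease state (`ARCC`) and an absorbing
post-advanced/death state (`PARCC/D`). Each cycle:

1. New RCC diagnoses = `pop40plus × kidney_incidence × rcc_fraction`. A
   fraction `advanced_at_diagnosis_fraction` enters `ARCC` directly; the
   remainder is treated surgically and enters the tunnel.
2. Tunnel position *t* sends `progression_prob[t]` of its occupancy to
   `ARCC` (relapse), `localized_mortality` to `PARCC/D`, and the remainder
   to position *t+1*. The three competing transitions are additive
   probabilities applied to the same start-of-cycle occupancy, guarded by a
   validation that progression + mortality never exceeds one. Whatever
   leaves position 10 without progressing is cured and exits the model (it
   is not returned to the at-risk pool; re-incidence at this scale is
   negligible).
3. The previous `ARCC` occupancy moves to `PARCC/D` with probability
   `to_post_advanced_prob` (1.0 by default, so the advanced count for a year
   equals that year's inflow: incident advanced + relapses).

The simulation starts from an empty tunnel in 2003; the ten years before
the 2013 report year fill all ten tunnel positions, so 2013 relapse counts
draw on a complete ten-cohort history. Everything is linear in the
population inflows — there is no randomness anywhere, and doubling the
population exactly doubles every flow (a property the tests exploit).

### Cycle timing

Two timing conventions are implemented for the first tunnel year:

* **default** (`same_cycle_first_risk: false`): the newly diagnosed
  localized cohort enters tunnel position 1 at the start of the *next*
  cycle, so its 13.18% first-year relapse risk applies during its first
  full year after surgery;
* **same-cycle** (`true`): the cohort bears the first-year risk during the
  diagnosis year itself.

Both reproduce the projected relapse counts to within ±1%; the default is
the more conservative reading of "probability per year since surgery".

### Prevalence census

k-year prevalence counts post-surgical patients diagnosed within the last
k years who are alive at the **year-end census** — the tunnel occupancies
*after* the year's transitions, excluding the cohort entering position 1
for the next cycle — divided by the adult population, per 100,000. Taking
the census before the year's transitions would count each cohort one
attrition step too early and overstates 1-year prevalence by ~13%; the
year-end convention reproduces the external GLOBOCAN-derived references
(7.6 / 20.2 / 31.1 per 100,000) within 5%. Survivors of advanced disease
are not counted as prevalent by default (first-line progression takes them
out of scope within a year); a `prevalence_includes_advanced` switch is
provided.

## Demographics

The paper's setting uses national-statistics population series; the package
ships a synthetic stand-in: a single 40+ base value with constant geometric
growth, and `pop_adult = adult_ratio × pop40plus`. Defaults:

| parameter | default | units | rationale |
|---|---|---|---|
| base_pop40plus | calibrated (≈23,961,841) | persons | closed-form inversion of 854 incident advanced cases in 2013 |
| growth_rate | 0.01405 | /year | implied by the 854 → 866 growth of incident advanced cases |
| adult_ratio | 1.653 | — | public 15+/40+ population ratio; only enters the prevalence denominator |

Years before the 2013 anchor are backward geometric extrapolations, which
keeps the warm-up period self-consistent without external data. The
synthetic series has no age structure, migration or background mortality —
incidence is a crude rate on the 40+ pool — so the stand-in matches real
demographics only in level and trend. Tests passing against it demonstrate
the model arithmetic, not Spanish demography; a real series can be
substituted via CSV (`year,pop40plus,pop_adult`) and everything downstream
is unchanged.

## Epidemiological parameters

All Table-style inputs are config values (decimals; per-100,000 inputs via
an explicit `per_100k: true` flag). Defaults: kidney-cancer incidence 40+
19.8/100,000/yr; RCC share 90%; advanced at diagnosis 20%; localized
mortality 1.66%/yr; relapse probabilities by year since surgery 13.18%,
4.57% (yrs 2–3), 1.92% (4–5), 1.64% (6–7), 1.26% (8–10);
favorable/intermediate risk 89%.

## Costs

* Pharmacological: €4,046 (pazopanib) and €4,904 (sunitinib) per 6-week
  cycle, 8 cycles/year. The annual per-patient figures are quoted for a
  full treatment year; the 57% expected time on treatment (progression-free
  survival-based) multiplies the pharmacological component **only at budget
  level**. Applying it to adverse-event costs as well would double-count:
  the aggregate figures are only internally consistent with AE costs
  charged once per treated patient-year.
* Adverse events: per event and grade bin, `incidence × unit_cost`, summed.
  `ae_cost_per_patient` rounds each event's cost to the cent before summing
  (the construction used when such tables are tabulated; the difference
  from the unrounded sum is < €0.02/patient). An unrounded mode
  (`round_events=False`) backs the exact additivity/linearity property
  tests. Trial incidences over median exposures of 8–10 months are used as
  annual rates — a simplification that slightly overstates both arms
  symmetrically.

## Budget impact

For year *y* and pazopanib share *s*, with eligible count `n_y`:

    impact(s, y) = s · n_y · (c_paz − c_sun) · (1 + 0.03)^−(y − 2013)

where `c_arm = annual_pharm × 0.57 + ae_cost`. The comparator scenario is
100% sunitinib; the discount factor is 1 in 2013 (back-derived from the
aggregate arithmetic). Eligible counts default to the model's unrounded
values; `run_bia(..., eligible_override=...)` accepts externally fixed
counts, used when checking against published aggregates that were computed
from rounded patient numbers.

## Sensitivity analysis

One parameter at a time is set to its published lower/upper bound, the full
demographics→epidemiology→budget pipeline is re-run (the base population is
**not** recalibrated, so epidemiological perturbations genuinely move the
patient count) and the 2013 full-substitution incremental cost is
recomputed. Progression probabilities tied across years (2–3, 4–5, 6–7,
8–10) move as grouped parameters. Entries are sorted by descending swing,
ties broken alphabetically, so output is independent of input order. Only
epidemiological parameters are varied by default (no published cost
bounds); cost ranges could be added via the same mechanism.

## Numerical choices

* All internal arithmetic is unrounded double precision; patient counts are
  rounded half-up only for reporting, currency to 2 decimals only at
  serialization.
* Mass conservation (occupancy + cumulative exits grows exactly by the
  incident inflow) holds to 1e-9 relative per cycle and is tested, as is
  equivalence with a brute-force per-cohort survival-table oracle.
* Degenerate inputs fail loudly: negative occupancies, probabilities
  outside [0,1], competing transitions summing past one, calibration
  against a zero incidence chain, horizon years before the reference year.
* A demographic span shorter than tunnel length + 1 triggers a warm-up
  warning rather than an error (early report years simply draw on a
  partially filled tunnel).

## Scope and limitations

* Advanced-disease survival beyond first-line progression, second-line
  therapy, QALYs and cost-effectiveness are out of scope; the model prices
  drug acquisition and adverse-event management only, with follow-up costs
  assumed equal across arms.
* The model is a deterministic cohort projection — no probabilistic
  sensitivity analysis, no age/sex stratification, no uptake curves (market
  share is constant within a scenario).
* Default problem sizes are tiny (13 annual cycles, 10 tunnel states, 101
  share points, 21 pipeline re-runs for the tornado); the entire pipeline
  including tests runs in seconds.
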