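# Model and methods

This note documents the model implemented in `oamarkov`: its structure,
the conventions chosen where the source material left room, what the
synthetic inputs do and do not emulate, and known limitations. Every
number quoted here is computed by the package's tests or analysis drivers.

## Cohort model

**States.** Healthy, KL I, KL II, KL III, KL IV, TKR, TKRR, Death.
Severity is ordered along that chain; Death is absorbing. The cohort
enters entirely in KL II at age 45 and is propagated through 40 one-year
cycles. Internally the engine expands this space:

* **TKR tunnel states**, one per year since surgery up to the last year
  tabulated in the revision-risk table, plus a terminal copy. The yearly
  revision probability X(t) applies to tunnel year t; beyond the table the
  terminal copy either keeps the last X (`terminal_rule="persist"`,
  default) or drops it to zero.
* **TKRR entry vs post-operation copies**, so the one-off operation
  mortality excess and the operation-cycle utility attach to the entry
  year only.
* **An ever-treated stratum** duplicating the pre-surgical states when
  re-treatment is disallowed (scenario 1), which keeps once-only semantics
  Markovian.
* **A "lingering" KL II copy** holding patients whose entry treatment
  failed (see *Treatment* below).

**Row assembly** (per source state, per cycle): start from the published
raw row; fold any ≥2-grade decline onto the one-step decline (the
published worked example 0.1 + 0.05 → 0.15 is a unit test); add the
treatment-success entry where applicable; append the death probability;
divide the row by its sum. The raw rows do not sum to one (e.g. the
Healthy row sums to 1.0563) and the death entry varies with age, so the
renormalisation is per-cycle, exactly as the source prescribes. Assembled
rows are checked to sum to 1 within 1e-12; cohort mass is conserved within
1e-9 over the horizon.

**Mortality layering.** Background q(age) from an age-indexed table;
+0.0012 while in KL II–IV (chronic OA-drug use); +0.002 in the first cycle
after TKR or TKRR surgery. Ages beyond the table reuse its last entry;
ages below its first entry are an error.

## Treatment semantics

Treated arms administer one treatment unit to every patient **entering**
KL II (including the initial cohort at cycle 0). With probability *e*
(0.69 base case) the patient regresses to Healthy (KL I in scenario 4);
otherwise they move to the lingering KL II copy and follow standard-of-care
transitions until they leave KL II — they are re-treated only on a
subsequent entry. Both the effect and the per-unit cost attach to entries.

Two conventions were open and are config switches; the defaults were
fixed by an identity that is independent of the mortality and revision
tables — the spacing of the printed per-arm costs divided by the spacing
of the per-unit prices, which equals the discounted number of
administrations per patient (≈ 2.02 in the published base case, ≈ 2.25 in
scenario 4):

* `treatment_frequency` — `"per_entry"` (default) vs `"per_cycle"`
  (treat and bill every cycle spent in KL II). Per-cycle billing implies
  ≈ 5.7 administrations and makes the dearest production route more
  expensive than standard care, contradicting the published dominance of
  all four arms; per-entry reproduces ≈ 2.02.
* `effectiveness_is_absolute` — `True` (default): the success probability
  stays at its stated value, the death entry stays at q, and the remaining
  destinations share 1 − e − q. `False`: the success entry joins the row
  and is scaled by the row sum like every other entry. The absolute
  convention reproduces the published incremental effect (ΔQALY 0.817 vs
  printed 0.818) and TKR reduction (30.5 % vs printed 30.0 %); the scaled
  convention roughly halves the per-entry success rate. A third
  composition considered — mixing e·(cure) with (1−e)·(renormalised
  standard-of-care row) — overshoots the incremental effect (ΔQALY 0.93)
  and was rejected.

A consequence of the default composition: setting e = 0 leaves the death
entry outside the renormalisation, so the "null treatment equals standard
of care" identity holds exactly only under
`effectiveness_is_absolute=False`; under the default the aggregate
outcomes agree to ~1e-3 relative. The test suite asserts both forms.

## Accrual and discounting

Per cycle k = 0..39: state costs and utilities accrue on the occupancy at
the start of the cycle, discounted by (1+r)^−k with cycle 0 undiscounted
(r = 4 %/year for costs, 1.5 %/year for effects, per Dutch guidance).
One-time event costs — TKR operation €16,565.05, TKRR operation
€27,608.42, death €1,082.28 — attach to the probability mass newly
entering the state, at that cycle's discount factor. Operation-cycle
utilities (0.76 TKR, 0.73 TKRR) are carried by the entry-year states.
Treatment units are billed at the cycle of entry into KL II. No half-cycle
correction is applied by default (`half_cycle_correction` trapezoids the
state accrual when enabled). Surgery counts are cumulative inflow into TKR
(tunnel year 1) and TKRR over the horizon, ×1,000, rounded half away from
zero only at reporting time.

KL IV has no published cost or utility; it is unreachable in the base case
(the KL III row carries no KL IV mass) and defaults to the KL III values,
configurable. Results are insensitive to this default in every shipped
configuration.

## Manufacturing unit costs

Per-unit cost = (facility + staffing + equipment depreciation +
consumables + quality control) / units-per-year; the automated facility
runs 330 manufacturing days per year (750 hiMSC units, 1,500 combined
hiMSC+EV units), the manual one 250 (480 and 960). Reported prices are
rounded to whole euros; the engine consumes the unrounded value
(`use_printed_unit_costs` forces the rounded price list).

## Sensitivity and scenarios

The tornado sweeps every parameter in the bounds registry one at a time —
published 95 % CIs where printed, otherwise ±20 % of base — re-running the
full model at each bound and ranking by the width of the discounted
per-patient cost range (net monetary benefit at €20,000/QALY is available
as a metric switch). Ties break alphabetically; parameters that cannot
move the metric (pinned zero-cost states, utilities under a cost metric)
get range 0 and sink to the bottom. The re-treatment flag is swept as a
binary (off at the low bound). Varying one raw transition probability
re-applies the renormalisation, so coupled mid-table ranks can legitimately
differ from rankings produced under other renormalisation scopes.

Scenarios: (1) treatment once per patient (ever-treated stratum);
(2) Healthy→KL I raw probability 0.04345 (general-population incidence);
(3) effectiveness 0.76 (small-animal studies); (4) successful treatment
regresses to KL I. Overrides are pure (deep copies).

The €20,000/QALY willingness-to-pay check passes dominant interventions
outright and otherwise requires 0 ≤ ICER ≤ threshold with a positive
health gain; the bound is inclusive.

## Synthetic inputs and what they stand for

Two published inputs live in supplementary appendices that are not
bundled: the Dutch age-indexed annual death probabilities and the
registry-based revision risk by year after TKR. The package ships
synthetic stand-ins, generated by `oamarkov.synthetic` and frozen as CSVs:

* **Mortality**: Gompertz q(a) = min(1, 1.13e-5 · exp(0.102 a)) over ages
  45–110, a least-squares fit through representative western-European
  life-table anchors (q ≈ 0.0012 at 45, 0.007 at 65, 0.07 at 85). It
  reproduces the smooth exponential rise of adult mortality but not
  old-age deceleration or cohort effects.
* **Revision risk**: 1.0 % in year 1 declining to 0.3 % by year 10
  (≈ 5 % cumulative at ten years, the order reported by arthroplasty
  registries), persisting at 0.3 %/year thereafter.

Consequently the *structure-driven* outputs are faithful — dominance
patterns, cost-driver rankings, relative surgery reductions, the
incremental effect — while *absolute levels* (total costs, total QALYs,
surgery counts per 1,000) reflect the stand-ins: e.g. the persisting
revision tail yields more lifetime revisions than the published 30/1,000.
Passing tests therefore certify the engine and the published-parameter
arithmetic, not agreement with Dutch registry data; substituting the real
tables via `mortality_csv=`/`tkrr_csv=` changes only the inputs, not the
code path.

`synth_model(seed)` additionally generates random progressive-only
disease models (mass on self, one-step decline and surgery only; costs
rising and utilities falling with severity) used by the property tests;
its defaults put roughly 60 % of an untreated cohort through TKR within
40 cycles, the regime of the published standard-of-care arm.

## Microsimulation oracle

`microsim(arm, params, n, seed)` samples n independent patient
trajectories from exactly the per-cycle rows the cohort engine assembles
(patient memory — tunnel year, treatment history — lives in the same
expanded state space) and accrues identically. Since the cohort model is
the expectation of the individual process, the two must agree within
sampling error; the suite checks |cohort − microsim| ≤ 3 SE at n = 200,000
for costs, QALYs and both surgery rates, on the base case, the once-only
scenario and five seeded random models. Draws come from one seeded
generator with vectorised per-state sampling each cycle: results are
exactly reproducible given (seed, n), though unlike per-patient
substreams a run at different n is not a superset of a smaller run — a
deliberate trade for simulating 200,000 × 40 patient-cycles in under a
second.

## Numerical choices

Row-stochasticity tolerance 1e-12 (hard error beyond); occupancy
conservation 1e-9; zero row sums and ages below the mortality table are
errors; probabilities produced by layering are clamped to [0, 1]. ICERs
are computed from unrounded totals and undefined at ΔE = 0; dominance
means strictly cheaper and strictly more effective. Counts round half away
from zero. Euro amounts serialise with two decimals, probabilities with
six significant digits; the published death-cost lower bound above its
base value (hospital perspective) is loaded verbatim and surfaced as a
validation warning, and is used as printed in the tornado.

## Limitations

* The stand-in mortality and revision tables bound what absolute levels
  can mean (above); conclusions about the Dutch setting require the real
  supplementary tables.
* Constant treatment effectiveness over 40 years; no waning, no adverse
  events beyond the operation mortality excess.
* No probabilistic (second-order) sensitivity analysis, CEAC curves or
  value-of-information — the underlying analysis performs none.
* Single comparator (standard of care); no cross-arm frontier.
* One-year cycles without half-cycle correction by default; both are
  explicit configuration.
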