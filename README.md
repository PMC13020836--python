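# oamarkov

A Markov cohort cost-effectiveness model of regenerative cell therapy for
knee osteoarthritis, with one-way sensitivity analysis, scenario analyses
and an individual-level microsimulation cross-check.

## The problem

Knee osteoarthritis (OA) is managed symptomatically — physiotherapy,
analgesics, and ultimately total knee replacement (TKR) — none of which
regenerates cartilage. Mesenchymal stromal cells derived from induced
pluripotent stem cells (hiMSCs), and the extracellular vesicles (EVs) they
secrete, are candidate disease-modifying treatments. Whether they could be
*cost-effective* depends on manufacturing cost (automated vs manual
production), how often patients are treated, and how much surgery they
avoid. This package implements the full decision model for a Dutch
Kellgren–Lawrence (KL) grade II cohort, for health-economics analysts who
want to inspect, re-parameterise or extend the published analysis.

## The model

A deterministic state-transition (Markov cohort) model over eight health
states — Healthy, KL I–IV, TKR, TKR revision (TKRR), Death — with one-year
cycles, a 40-year horizon and entry at age 45 in KL II. Each cycle's
transition matrix is assembled from published raw per-cycle probabilities
$p_{ij}$ by:

1. **collapse rule** — mass for declining ≥ 2 KL grades in one cycle is
   folded onto the one-step decline (patients worsen at most one grade per
   year);
2. **treatment** — in treated arms, patients *entering* KL II are treated
   once per entry; with probability $e$ (0.69 base case) they regress to
   Healthy, and the per-unit production cost is billed;
3. **mortality layering** — the age-specific annual death probability
   $q(a)$, plus an OA-drug excess (0.0012, KL II–IV) and a first-cycle
   operation excess (0.002, TKR/TKRR);
4. **proportional renormalisation** — each row is divided by its sum
   (the published raw rows do not sum to 1, and $q(a)$ varies per cycle).

Time-dependent revision risk $X(t)$ (by year $t$ since TKR) is made
Markovian with tunnel states; the once-only-treatment scenario uses an
ever-treated stratum. Costs discount at 4 %/year and health effects at
1.5 %/year (cycle 0 undiscounted). The primary outcome is the incremental
cost-effectiveness ratio
$\mathrm{ICER} = \Delta C / \Delta E$ (€ per QALY) against standard of
care; secondary outcomes are TKR and TKRR operations per 1,000 patients.

The per-unit treatment cost is a facility's five annual cost components
(facility, staffing, equipment depreciation, consumables, quality control)
divided by its yearly unit output: €1,539 (automated hiMSC), €2,183
(manual hiMSC), €770 (automated hiMSC+EV), €1,092 (manual hiMSC+EV).

**Data note.** The published age-indexed Dutch life table and the
registry revision-risk-by-year table live in supplementary appendices that
are not bundled here. The package ships clearly-labelled *synthetic*
stand-ins (`src/oamarkov/data/synthetic_*.csv`): a Gompertz life table
($q = 1.13\times10^{-5} e^{0.102\,a}$) and a ~5 %-at-10-years revision
table. Every `paper_baseline()` call warns about this; pass
`mortality_csv=` / `tkrr_csv=` (or the `--mortality-csv` / `--tkrr-csv`
CLI flags) to substitute the real tables. Structure-driven results
(dominance, rankings, reductions) are robust to the stand-ins; absolute
cost/QALY levels are not. See `docs/methods.md`.

## Worked example

```python
from oamarkov import paper_baseline, run_arm, compute_icer

soc = run_arm("SoC", paper_baseline("hospital", "SoC"))
trt = run_arm("hiMSC_auto", paper_baseline("hospital", "hiMSC_auto"))
res = compute_icer(trt, soc)
print(f"SoC      : {soc.total_qalys:.3f} QALYs, {soc.total_cost:,.2f} EUR, "
      f"TKR/1000 {soc.tkr_per_1000}")
print(f"treated  : {trt.total_qalys:.3f} QALYs, {trt.total_cost:,.2f} EUR, "
      f"TKR/1000 {trt.tkr_per_1000}")
print(f"ICER {res.icer:,.2f} EUR/QALY ({res.dominance})")
```

prints (with the packaged synthetic stand-in tables):

```
SoC      : 21.684 QALYs, 44,655.21 EUR, TKR/1000 607
treated  : 22.501 QALYs, 40,698.53 EUR, TKR/1000 422
ICER -4,842.81 EUR/QALY (dominant)
```

Automated hiMSC treatment adds 0.82 discounted QALYs per patient, saves
about €3,957 over 40 years from the hospital perspective, and avoids 30.5 %
of knee replacements — it *dominates* standard of care (cheaper and more
effective; the negative ICER reports savings per QALY gained).

The same pipeline is scripted as numbered drivers:

```bash
python analysis/01_base_case.py      # Table of all 5 arms x 2 perspectives
python analysis/02_sensitivity.py    # tornado tables (top cost driver: c_KLII)
python analysis/03_scenarios.py      # the four scenario analyses
python analysis/04_microsim_check.py # cohort vs 200k-patient microsimulation
```

each writing CSVs under `results/`. The equivalent CLI:

```bash
oamarkov run --arm all --perspective hospital --out results
oamarkov tornado --arm hiMSC_auto --out results
oamarkov scenario --id 1 --out results
oamarkov validate
```

## Layout

```
src/oamarkov/        the library: parameters, engine, economics, analyses,
                     synthetic data + microsimulation, CLI
analysis/            numbered narrative drivers writing results/ tables
tests/               pytest suite (unit, property and end-to-end checks)
docs/methods.md      model documentation: assumptions, conventions, limits
```
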