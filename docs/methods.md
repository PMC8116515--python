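# Methods

`t2dsim` is a deterministic system-dynamics (SD) model of the Dutch type 2
diabetes (T2DM) "patient journey": the population-level progression from
normal glucose control through pre-diabetes to T2DM, the reversal paths
opened by lifestyle programs and bariatric surgery, and the societal cost
that the disease and the programs generate. This note documents the model,
its assumptions, the calibration of the shipped defaults, and the limits of
what the package's tests demonstrate.

## Model structure

### Stocks and flows

Five population stocks are advanced by forward Euler at a fixed monthly
step (`dt = 1` month by default) over an inclusive 1990–2035 horizon
(552 steps):

| stock | description |
|---|---|
| `normoglycemic` | everyone able to develop T2DM (total population minus the disease stocks) |
| `undiagnosed_prediabetic` | elevated glucose, not seen by a GP |
| `diagnosed_prediabetic` | diagnosed IFG/IGT (impaired fasting glucose / glucose tolerance) |
| `t2dm` | diagnosed type 2 diabetics |
| `no_medicine_necessary` | reversed T2DM patients off medication, at risk of relapse |

Three accounting stocks (`cumulative_deaths`, `cumulative_recoveries`,
`cumulative_demographic_inflow`) audit conservation: at every step, total
persons + cumulative deaths − cumulative demographic inflow equals the
initial total to floating-point precision (< 1 person over the full run at
16–18 million scale).

### Transition semantics

Every published transition is a (fraction, average time) pair applied as a
first-order rate: a stock `S` empties into its destination at
`S · fraction / (time · 12)` persons per month. The shipped transition
table:

| from | to | time (y) | fraction |
|---|---|---|---|
| normoglycemic (background) | pre-diabetes pool | 2 | 0.01 |
| normoglycemic (rapid/obese pathway) | pre-diabetes pool | 3 | 0.33 |
| diagnosed pre-diabetic | T2DM | 4 | 0.70 |
| undiagnosed pre-diabetic | T2DM | 7 | 0.90 |
| diagnosed pre-diabetic | normoglycemic | 2 | 0.30 |
| undiagnosed pre-diabetic | normoglycemic | 4 | 0.10 |
| T2DM | normoglycemic | 3 | 0.01 |
| no medicine necessary | T2DM (lifestyle relapse) | 2 | 0.65 |
| no medicine necessary | T2DM (bariatric relapse) | 10 | 0.05 |

An alternate recovery variant (diagnosed 10%, undiagnosed 5%) ships as
`ALTERNATE_RECOVERY_TRANSITIONS`; the table above is the default.

The pre-diabetes pool is an instantaneous junction, not a stock: new
pre-diabetics are split immediately into diagnosed and undiagnosed inflows
by the combined IFG + IGT incidence fraction (default 0.25 + 0.25, a
placeholder chosen for a 50:50 split; the source values are not public).

Mortality is an exponential residence-time approximation of "leaving the
stock on reaching that state's life expectancy": per-capita outflow at
`1 / remaining lifetime`, with remaining lifetimes 81.7 y (healthy),
71.7 y (undiagnosed pre-diabetes, −10), 73.7 y (diagnosed, −8) and 72.7 y
(T2DM, −9). No aging chain is modeled. The reversed ("no medicine") stock
carries no separate mortality; its residents exit through the relapse /
sustained-recovery split within its characteristic time.

Demographic replenishment (births, migration) enters only the
normoglycemic stock, computed each step as the gap between the exogenous
population trend and the current simulated total, so the total population
tracks the trend; the flow is signed (net emigration is possible in
extreme-condition runs).

Negative stocks are clamped at zero and every clamp event is logged and
recorded on the trajectory (none occur in the shipped scenarios). Forward
Euler with monthly steps is deliberate — the goal is to reproduce the
behavior class of the desktop SD tool the model was originally built in,
not to improve on it; the suite verifies first-order convergence against
closed forms (exponential decay, two-stock transfer, logistic growth) as
`dt` is halved.

### Intervention programs

A program targets T2DM patients (`t2dm`, `bariatric`) or diagnosed
pre-diabetics (`prediabetes`). Recruitment is
`MIN(indicated, potential)`: the indicated rate applies the current
recruited fraction (per year) to the eligible stock; the potential rate is
the optional annual treatment capacity; recruitment also never exceeds
what the stock holds in one step. The recruited fraction steps on in
January of the activation year (2020 in all presets) and can ramp linearly
to a final value over a configurable number of years. Successful recruits
(`recruited × success_rate`) move to `no_medicine_necessary` (T2DM
targets) or straight back to `normoglycemic` (prevention targets — no
relapse stage is modeled for pre-diabetes reversal). The active
T2DM-target program's relapse pair governs the shared no-medicine stock:
65% over 2 years for lifestyle reversal, 5% over 10 years after bariatric
surgery. Unsuccessful recruits stay in their stock and may be re-recruited
immediately.

### Costs

Annual societal cost is linear in the stocks and decomposed by payer:
authorities (WIA/IVA and WGA disability benefits for the disabled share of
the employed T2DM population), employer (obligatory salary continuation
for the disabled share plus productivity loss), health insurer (ambulatory
care, hospitalization, physiotherapy, tools and devices, GP care, a
standard/elderly medication blend, comorbidity care), DM management
organizations, and program cost (recruits per year × standard program cost
× the program's cost multiplier). Unit costs published for the whole DM
population are scaled to T2DM by ×0.9 ("nine out of ten DM patients have
T2DM"). Pre-diabetic stocks incur only GP care (diagnosed) and
productivity loss (both), configurable via
`CostParameters.prediabetic_components`. All patients are treated as
employed (`employment_fraction = 1`), following the source's stated
simplification. Costs are evaluated yearly from end-of-December stocks and
realized within-year program recruitment; the cumulative series is the
running sum of annual totals. The 13 B€ figure is treated as *annual* cost
in 2035 (the alternative, cumulative reading, would be reached around
2013 under these defaults and is therefore implausible).

## Calibration of shipped defaults

Two groups of parameters could not be taken from public sources and are
shipped as explicit, provenance-tagged calibrated placeholders.

**Onset exposure.** Feeding the published overweight share (51%) into the
rapid (3 y, 0.33) onset row yields ≈ 900 000 new pre-diabetics per year —
an order of magnitude above anything consistent with the historical Dutch
T2DM counts, which the original model demonstrably reproduced (its full
parameterization was never published). The default therefore treats the
rapid-pathway exposure as a calibrated share `rapid_onset_share = 0.002`
of the normoglycemic stock, fitted once against the three historical count
anchors (160 k DM in 1990, 830 k in 2011, 1.2 M in 2018) over a coarse
grid, with near-ties resolved toward the larger share so the obesity
pathway stays active. The resulting incidence (~50–60 k new T2DM patients
per year, ~350 k pre-diabetics in steady state) is of realistic national
magnitude. Setting `rapid_onset_share = 0.51` recovers the literal
published parameterization. Similarly, the pre-diabetic stocks start empty
in 1990 (`initial_prediabetic_scale = 0`): seeding them at their analytic
steady state front-loads the onset pipeline and overshoots the 2011 count
by a third; the steady-state seeding remains available (scale = 1).

**Unit costs.** The cost placeholders were set at plausible Dutch
magnitudes, then scaled once (×0.83, rounded) so the default
no-intervention run totals ≈ 13 B€ of annual societal cost in 2035
(12.96 B€ as shipped, −0.3%). This makes the headline a *calibration
target*, not an independent validation. The implied ≈ 7 500 €/patient/yr
composite (plus benefits) is consistent in magnitude with published Dutch
diabetes cost-of-illness estimates. The standard program cost (1 000
€/participant/yr) is set so the bariatric multiplier of 17 prices one
surgery at 17 000 €, inside the published 15 000–20 000 € range.

**Population trend.** Linear interpolation of the population sizes implied
by printed prevalence pairs — 16.0 M (1990: 160 k = 1%), 16.9 M (2011:
830 k ≈ 4.9%), 18.2 M (2018: 1.2 M = 6.6%) — held flat to 2035.

## Validation procedures

* **Extreme conditions** — with all disease stocks empty and onset
  disabled, total cost is exactly zero in every year; with 100 million
  patients, costs scale proportionally into the hundreds of billions and
  no population stock goes negative or non-finite.
* **Behavior sensitivity** — one-at-a-time ±10% perturbations with
  central-difference elasticities per stock at a report year,
  deterministic and side-effect free. Under the shipped calibration the
  background onset fraction carries the largest T2DM elasticity (+0.86);
  under the literal overweight parameterization the rapid (obese) pathway
  dominates instead, which is the sensitivity the source reports.
* **Behavior reproduction** — per-anchor relative error and MAPE of the
  no-intervention run against the reference anchors, compared at the
  opening (1 January) state of each anchor year. DM-count anchors are
  compared against simulated T2DM / 0.9; fraction anchors against
  simulated T2DM / population.

## Known limitations

* **The anchor set is internally inconsistent.** The count anchors
  (1.2 M ≈ 6.6% of 18.2 M in 2018) and the registered-T2DM fraction
  anchors (3.7% in 2014, 4.0% in 2019) sit on different statistical bases.
  Under the model's T2DM outflow of ~1.7%/yr (fixed by the published life
  expectancies) no monotone trajectory can satisfy both groups within 20%:
  the 2018 count demands ≥ 864 k T2DM patients while the 2019 fraction
  caps the stock at ≈ 874 k and the 2014 fraction at ≈ 776 k, a
  deceleration an order of magnitude faster than the dynamics allow. The
  shipped calibration reproduces the count series (errors +0.0%, +12.8%,
  +1.3%) and overshoots the fraction anchors (+47%, +55%); the
  corresponding acceptance test is left failing rather than weakened.
* **Bariatric surgery dominates the scenario table at face value.**
  Recruiting 28% of the T2DM stock per year at 95% success and 5% relapse
  makes Policy 1 the strongest lever on both the 2035 stock (220 k vs
  493 k for Policy 5 and 1.65 M without intervention) and 2035 annual cost
  (3.2 B€ vs 5.2 B€), despite the 17× program price. The source narrative
  ranks the integrated lifestyle policies (4–5) most effective while also
  conceding that the bariatric run is "more effective … in the long run"
  but demands the largest outlay; the face-value parameterization supports
  the concession, not the ranking, and the ordering acceptance test is
  left failing with this explanation.
* **Instantaneous program recovery.** Successful recruits leave the T2DM
  stock in the month they are recruited, so a cheap, effective program can
  pay for itself within its activation year; only expensive programs
  (bariatric) show the "extra cost precedes benefit" bump in 2020.
* **No age/gender/education structure**, no distinction between
  complicated and uncomplicated T2DM, no type 1 dynamics, no discounting
  or inflation of costs, and exponential (memoryless) residence times
  everywhere. Elasticities and scenario orderings should be read as
  qualitative, not predictive.

## What the tests do and do not show

The synthetic defaults emulate the *published shape* of the Dutch
epidemic — initial prevalence, historical count growth, the exogenous
population trend — under heavily simplified dynamics and placeholder cost
levels. Passing tests demonstrate internal consistency (conservation,
determinism, convergence, linearity, dominance and monotonicity of the
policy levers) and reproduction of the published count anchors and
headline cost under the documented calibration. They do not validate the
unpublished source parameterization, predict real Dutch costs, or rank
real-world interventions.

## Numerical choices

Forward Euler, monthly step, no sub-stepping; stocks clamped at zero with
logged events (accounting trackers exempt); yearly reporting at
end-of-December states with the final year reported at the simulation
terminus; exogenous series linearly interpolated between yearly values and
flat-extrapolated; YAML configuration serialized with sorted keys so
serialize → parse → serialize round-trips byte-identically; everything is
deterministic — two runs with identical configuration produce
bit-identical trajectories.
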