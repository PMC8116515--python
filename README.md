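# t2dsim

A system-dynamics simulator of the Dutch **type 2 diabetes (T2DM) patient
journey**: the population-level flow from normal glucose control through
(un)diagnosed pre-diabetes to T2DM and back — via spontaneous recovery,
lifestyle-intervention programs and bariatric surgery — coupled to the
societal cost the disease and the programs generate. It is a policy
"what-if" tool for health-economic modellers and public-health analysts:
activate a program, set its reach, success rate and price, and compare the
resulting T2DM and cost trajectories against current policy.

## Model

Five stocks — normoglycemic *N*, undiagnosed pre-diabetic *U*, diagnosed
pre-diabetic *D*, type 2 diabetic *T*, and reversed-without-medication
*M* — evolve by forward Euler at a monthly step over 1990–2035. Each
published transition is a (fraction *f*, average time *τ*) pair applied as
a first-order rate *f·S/τ*; for example the diagnosed→T2DM flow is
0.70·*D*/4 per year. Deaths leave each stock at 1/(remaining lifetime),
with lifetimes 81.7 y (healthy) shortened by 10/8/9 y for *U*/*D*/*T*;
demographic replenishment pins the total population to the national trend.
A program recruits `min(indicated, capacity)` patients per month from its
target stock, moves `recruited × success_rate` of them onto the recovery
path, and bills `recruits/yr × standard cost × multiplier`; reversed
patients relapse back to *T* (65% over 2 y for lifestyle programs, 5% over
10 y after bariatric surgery). Annual societal cost is linear in the
stocks, split across Dutch authorities (WIA/IVA/WGA disability benefits),
employers (salary continuation, productivity loss), health insurers
(care, medication, comorbidities) and program budgets.

The six shipped scenario presets mirror the published policy experiments
(no intervention; bariatric surgery 0.28/0.95/×17; ReverseDiabetes2Now
0.002→0.30 over 10 y at 28% success; and three hypothetical lifestyle
policies, two of them paired with a pre-diabetes program). Validation
utilities implement extreme-condition tests, one-at-a-time sensitivity
elasticities, and behavior reproduction against the historical CBS
reference points. See `docs/methods.md` for assumptions, the calibration
of the shipped placeholder parameters, and known limitations.

## Worked example

```sh
t2dsim run no_intervention
```

prints one row per simulated year (end-of-December stocks):

```
 year         t2dm   cost_total  cost_cumulative
 1990 1.468681e+05 1.208166e+09     1.208166e+09
 1991 1.594618e+05 1.381442e+09     2.589608e+09
 ...
 2034 1.626464e+06 1.276092e+10     3.239051e+11
 2035 1.652901e+06 1.295936e+10     3.368645e+11
```

Under current policy the simulated T2DM population grows from ~147 k at
the end of 1990 to ~1.65 million in 2035, and annual societal cost reaches
~12.96 B€ (the shipped unit costs are placeholders calibrated to the
~13 B€ headline; see `docs/methods.md`). The same run from Python:

```python
from t2dsim import fixtures as fx
from t2dsim.scenarios import load_preset, run_scenario

journey, costs, clock = (fx.default_parameters(),
                         fx.default_cost_parameters(), fx.default_clock())
result = run_scenario(load_preset("policy5"), journey, costs, clock)
print(result.t2dm_at(2035), result.total_cost_at(2035))
```

Activating the integrated Policy 5 (60%/50% T2DM program at triple price
plus a 40%/50% pre-diabetes program) cuts the 2035 stock to ~493 k and
annual cost to ~5.2 B€. Other entry points:

```sh
t2dsim presets                       # list scenario presets and run aliases
t2dsim compare no_intervention policy3 policy5 --report-years 2035
t2dsim validate --tolerance 0.2      # extreme / sensitivity / reproduction checks
t2dsim fixtures out/                 # write default config + demographic series
t2dsim run out/default_config.yaml --out run.csv
```

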