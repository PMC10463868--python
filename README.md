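# hnc-cea

Markov cohort cost-effectiveness analysis of **intensity-modulated
radiotherapy (IMRT)** versus **three-dimensional conformal radiotherapy
(3D-CRT)** for head-and-neck cancer, from the societal perspective.

The package is aimed at health economists and HTA analysts who want the
full decision-analytic pipeline as reusable, tested code rather than a
spreadsheet or a TreeAge project: bottom-up micro-costing, EQ-5D-3L
utility scoring, a six-state toxicity Markov engine, ICER/dominance
ranking, and deterministic and probabilistic sensitivity analysis. A
synthetic-data module generates study-shaped inputs (97 respondents in
two arms) with known ground truth, so every stage is testable end to end
without access to the original patient-level data.

## The model

Radiotherapy for head-and-neck cancer trades tumour control against two
chronic toxicities: xerostomia (dry mouth) and dysphagia (swallowing
difficulty). The cohort model tracks a treated cohort across discrete
cycles over six health states — composite toxicity severities LXLD,
LXHD, HXLD, HXHD (low/high xerostomia × low/high dysphagia), a
lost-to-follow-up (LTF) state, and absorbing Death. Patients lost to
follow-up are assumed to die at the same per-cycle rate as the rest of
the cohort; every transition matrix is validated against this rule.

Per strategy *s*, with row-stochastic transition matrix **P**ₛ and
occupancy row vector **x**ₜ = **x**ₜ₋₁**P**ₛ, discounted totals over a
horizon of *n* cycles of length *c* years are

```
Cost(s)  = Σₜ xₜ · cost_per_cycle · (1+r)^(−tc)      t = 1…n
QALY(s)  = Σₜ xₜ · utility · c · (1+r)^(−tc)
```

with an optional half-cycle correction (averaging adjacent occupancy
rows). Strategies are compared by the incremental cost-effectiveness
ratio ICER = ΔCost/ΔQALY with strict and extended dominance, and by net
monetary benefit NMB = λ·QALY − Cost at willingness-to-pay λ.

Costs are aggregated bottom-up per patient into direct medical (visits,
laboratory, diagnosis, radiotherapy), direct non-medical (transport,
lodging) and indirect groups; indirect costs use the human-capital
approach (days absent × daily wage, for patient, companion and home
nursing), and Rial-denominated records are converted at a fixed
study-period rate (36,692 IRR/USD). Utilities come from EQ-5D-3L
profiles scored with a pluggable additive TTO value set
(U = 1 − constant − Σ dimension decrements − N3 term).

## Worked example

```python
from hnc_cea.synthetic import gen_calibrated_fixture

fixture = gen_calibrated_fixture()       # two-arm model at the published base case
results = fixture.model.fit()
print(results.summary())
```

```
Cost-effectiveness analysis
  strategies: 3D-CRT, IMRT
  states: Alive, Death
  horizon: 5 cycles x 1.0 y = 5 y; discount 0.0%/y; half-cycle correction off
strategy  effectiveness  incremental_effectiveness     cost  incremental_cost  icer dominance
  3D-CRT           3.63                             9209.76                         reference
    IMRT           3.17                      -0.46 12562.90           3353.14       dominated
```

3D-CRT yields 3.63 QALYs at $9,209.76; IMRT yields 3.17 QALYs at
$12,562.90, i.e. it costs $3,353.14 more and produces 0.46 fewer QALYs,
so it is strictly dominated — no ICER is quoted for a dominated
strategy, the status column carries the verdict. Propagating parameter
uncertainty:

```python
psa = fixture.model.psa(fixture.psa_params, n_draws=1000, seed=42)
print(psa.summary())
```

```
PSA: 1000 draws (0 rejected), IMRT vs 3D-CRT
  quadrant shares (ΔQALY, Δcost): I=0.048, II=0.001, III=0.005, IV=0.946
  mean Δcost 3358.90, mean ΔQALY -0.4557
```

94.6% of draws fall in quadrant IV of the cost-effectiveness plane
(IMRT more costly *and* less effective), and `psa.ceac()` shows the
3D-CRT acceptability curve above 0.5 at every willingness-to-pay level.
`hnc_cea.plots` renders the CE plane, CEAC and tornado figures from
these objects.

The same workflow is available from the shell:

```sh
hnc-cea generate --seed 1 --out-dir inputs/
hnc-cea cost --costs inputs/costs.csv --absenteeism inputs/absenteeism.csv --out table1.csv
hnc-cea utilities --responses inputs/eq5d.csv --value-set inputs/value_set.csv --out utilities.csv
hnc-cea run --config inputs/model.yaml --out-dir base/
hnc-cea dsa --config inputs/model.yaml --params inputs/params_dsa.csv --out-dir dsa/
hnc-cea psa --config inputs/model.yaml --params inputs/params_psa.csv --seed 4 --out-dir psa/
```

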