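# Methods

## Decision problem and model structure

The package compares two radiotherapy strategies for head-and-neck
cancer — IMRT and 3D-CRT — on discounted lifetime-horizon costs (USD,
societal perspective) and QALYs, using a discrete-time Markov cohort
model. The default state space is the composite toxicity reading
{LXLD, LXHD, HXLD, HXHD, LTF, Death}: the four alive toxicity states
cross low/high xerostomia with low/high dysphagia (severity split at
grade 2), LTF is lost-to-follow-up, Death is absorbing. State names are
configurable labels, so a four-toxicity reading (LX/HX/LD/HD) runs
unchanged; the composite default was chosen because it reconciles a
six-state structure with sensitivity-analysis parameters expressed per
composite state (e.g. "QALY of LXLD patients").

Structural assumptions enforced by validation rather than convention:

- every transition row sums to 1 within 1e-9 and is non-negative;
- Death is absorbing (its row is the identity);
- the LTF state's per-cycle death probability equals the cohort death
  rate. The rate can be configured explicitly (`cohort_death_prob`);
  otherwise it is inferred from the non-LTF alive rows, which must then
  agree among themselves — unequal alive-row death probabilities without
  an explicit rate are reported as a configuration error, not guessed.

Strategies are fully independent model instances sharing only the state
structure; nothing is pooled between arms unless the caller shares
objects deliberately.

## Run controls and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| cycle length | 0.25 | years | quarterly cycles suit acute-to-chronic toxicity transitions |
| horizon | 20 cycles (5 y) | — | base-case QALYs of 3.2–3.6 require a multi-year horizon |
| discount rate | 0.03 | per year, costs and QALYs | standard HTA practice; configurable incl. 0 |
| half-cycle correction | off | — | cycle-end accrual is the reference convention; the flag is tested separately |
| exchange rate | 36,692 | IRR per USD | fixed study-period average; applied once at ingestion |

Accrual conventions: rewards accrue from cycle 1; cycle-0 payoffs are
never accrued on their own (an `upfront_cost` per strategy covers
one-off treatment delivery). The half-cycle correction averages
occupancy rows t−1 and t; a start-of-cycle convention exists for oracle
comparisons. The fundamental-matrix helper
(`expected_time_in_states`) counts occupancy from cycle 0, i.e. it
equals the infinite-horizon sum of start-of-cycle occupancies — the
closed form used to cross-check undiscounted QALY accumulation.

## Costing

Costs are aggregated bottom-up into per-patient means per arm:
direct medical (visits, laboratory, diagnosis, radiotherapy), direct
non-medical (transport, lodging), indirect (productivity loss via the
human-capital approach: patient days + companion days + home-nursing
days, each times its daily rate; wages are per-record inputs with no
national-wage default). Category sums use a sorted `fsum` reduction so
totals are exactly invariant to record order. Whole-dollar reporting
figures are produced by truncation (floor) of the full-precision
totals, and full precision is retained internally; reported figures
that disagree with their own recomputed sums by more than half a cent
are flagged in a validation log rather than adopted.

## Utilities

EQ-5D-3L profiles are scored with an additive TTO value set
(full-health value, a constant decrement for any problem, per-dimension
level-2/3 decrements, and an N3 term applied once if any dimension is
at level 3). Value sets are data (CSV), not code: the shipped
`synthetic_tto_value_set.csv` is a fully synthetic, plausible set used
by tests and demos — it is *not* the Iranian TTO tariff, whose
coefficients are not publicly available in machine-readable form and
are deliberately not fabricated. Utilities below 0 are permitted and
flow through the payoff layer unchanged. Per-state utilities are sample
means over responses labelled with an explicit `state_label`, since the
mapping from respondent to Markov state is an input, not an inference.

## Ranking

Strategies sort by ascending cost (ties by descending QALY). Strict
dominance requires weak improvement in both coordinates and strict in
one; two identical (cost, QALY) points do not dominate each other.
Extended dominance removes frontier candidates whose incoming ICER
exceeds their outgoing ICER, iterated to convergence — equivalent to
the convex-blend definition, which the tests verify against a
brute-force blend oracle. Dominated rows keep incremental cost/effect
versus the reference but no ICER: a negative ratio is ambiguous between
"dominant" and "dominated", so the categorical status column carries
the verdict instead.

## Sensitivity analysis

**One-way / tornado.** Each parameter is evaluated at its low and high
bound with everything else at base; bars sort by descending swing with
stable ties. Perturbing a single transition probability rescales the
remaining non-Death entries of its row proportionally and keeps the
Death entry fixed, preserving row-stochasticity and the LTF mortality
rule; whole-row targets are rejected for one-way analysis.

**Probabilistic.** Default distribution families follow standard HTA
practice: gamma for costs, beta for utilities and scalar probabilities,
Dirichlet for whole transition rows, all moment-matched (beta:
α = m(m(1−m)/s² − 1); gamma: shape = (m/s)², scale = s²/m; Dirichlet:
α = concentration × mean row). One seeded generator drives everything,
parameters drawn in declaration order with draws as the outer loop, so
a run is reproducible and the first n draws of a longer run are
identical. Draws whose matrices fail validation (e.g. a Dirichlet row
breaking the LTF rule) are rejected and redrawn, capped at 100× the
requested draws. The CE-plane quadrant convention puts ΔQALY on x and
Δcost on y (comparator minus reference), numbered I=(+,+), II=(+,−),
III=(−,−), IV=(−,+), so quadrant IV means "more costly and less
effective"; zero deltas go to the adjacent lower-numbered quadrant and
are flagged. CEAC probabilities are the fraction of draws with the
strictly highest NMB, ties split equally; the default WTP grid spans 0
to 3× the largest base-case strategy cost in 101 steps.

## Synthetic data

The generator emulates the study's data shape: 97 respondents (48
3D-CRT / 49 IMRT by default — the true split is unpublished), category
costs gamma-distributed around the published per-arm means with CV 0.4
(dispersion is unpublished; CV is a config knob, never a claim),
productivity loss decomposed into patient/companion/nursing absenteeism
at fixed daily wages so its human-capital value has the configured
mean, and EQ-5D responses sampled per dimension independently from
configurable level probabilities (no cross-dimension correlation — a
documented simplification; real EQ-5D dimensions correlate positively,
so synthetic utility SDs are mildly understated). Transition matrices
are constructed to satisfy every validation rule by construction.
Passing tests on these data demonstrate that the pipeline recovers
known ground truth under the stated noise model; they do not validate
the clinical realism of any particular transition matrix.

The calibrated fixture is the package's reference model: a single
always-alive state over five undiscounted one-year cycles with
per-cycle payoffs equal to the published totals divided by five, so the
engine reproduces the base-case cells (9209.76, 3.63) and (12562.90,
3.17) exactly. It exists because the study's own transition
probabilities are taken from literature it does not reprint, making the
published cells unreproducible from printed inputs; the fixture pins
the engine's arithmetic to the published numbers without claiming to
replicate the original model. Its PSA parameters put beta noise
(sd 0.04) on the per-cycle utilities and gamma noise (sd 8% of base) on
the per-cycle costs — modest uncertainty centred on the base case. The
six-state demo model (`gen_demo_model`) carries wider DSA ranges on the
reference arm's LXLD and HXLD utilities so the tornado's qualitative
ordering (those two parameters first) holds by construction.

Known arithmetic quirks of the published figures, reproduced
deliberately: the 3D-CRT direct-medical column sums to 9772.91 while
the printed subtotal reads 9772.92 (the validation log flags it); the
printed incremental effectiveness (−0.45) and ICER (−7367.27) are
consistent with neither the printed cells (which give −0.46 and
−7289.43) nor each other, so the package recomputes from full precision
and reports the dominance verdict categorically instead of
force-matching the printed ratio.

## Numerical choices and limitations

- Tolerances: row-stochasticity, initial-distribution and CEAC
  probability sums 1e-9; cost-table internal consistency 1e-9 (half a
  cent for reported-figure flagging); fundamental-matrix cross-checks
  1e-6 at long horizons.
- Ties: equal-cost strategies order by descending QALY; equal NMBs
  split CEAC weight equally; tornado ties keep input order.
- The acceptance script sizes its computations to run in seconds
  (1000 PSA draws, 10,000 synthetic patients per arm) while keeping
  Monte-Carlo error well inside the stated bands.
- Out of scope: microsimulation, time-varying matrices, tunnel states,
  survival extrapolation, EVPI, correlated parameters, friction-cost
  valuation, inflation adjustment, EQ-5D-5L/crosswalks.
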