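# Methods

## Disease model

The clinical course is represented by three mutually exclusive states:
progression-free on maintenance therapy (PFS), progressed disease on
salvage chemotherapy (PD), and death. The whole cohort starts
progression-free; movement is irreversible (PFS → PD → death, with direct
PFS → death allowed). Cycles are one month; the default horizon is 120
cycles (10 years), by which point the extrapolated overall-survival curves
leave under 10% of either cohort alive.

Arm-specific survival is described by two-parameter Weibull curves in
scale/shape form, `S(t) = exp(−λ t^γ)` with `t` in months. The packaged
configuration carries four fitted parameter sets (PFS and OS for each arm)
together with their standard errors and 95% CIs. The per-cycle event
probability implied by a curve is the conditional probability
`P(t) = 1 − S(t)/S(t−1) = 1 − exp[λ(t−1)^γ − λ t^γ]`.

### Engine modes

**Partitioned survival (default).** Membership is read directly off the
curves: `pfs(t) = min(S_pfs(t), S_os(t))`, `dead(t) = 1 − S_os(t)`, and
`pd(t)` is the remainder, floored at zero. Curve crossing (fitted PFS
above OS) is resolved by capping PFS at OS; a warning fires if the floor
triggers in more than 5% of cycles. Because the trial OS curve already
counts death from every cause, **no additional background mortality is
layered onto the partitioned trace**: adding the general-population rate on
top would double-count deaths, and in our development runs it shifted the
base-case ICER by ≈8% while every published-style target then fell outside
a 5% band. The literal alternative — multiplying `S_pfs` by a cumulative
general-population survival factor — remains available via
`ModelConfig(background_mortality_in_partitioned=True)`.

**State transition.** An explicit Markov chain using per-cycle
probabilities: PFS → death at the monthly general-population mortality
(annual 0.707% converted by `1 − (1 − p)^{1/12}`), PFS → PD at the PFS
curve's transition probability net of background death, PD → death at the
OS curve's transition probability, death absorbing.

The two modes encode the same curves under different assumptions and are
*not* numerically identical: applying the population-level OS transition
probability to the PD compartment understates the conditional death hazard
of progressed patients, so the chain keeps them alive longer (≈9% more
undiscounted life-years for the placebo arm with background mortality
off). Tests assert agreement within 10% and exact structural invariants
(conservation, monotonicity) in both modes. A vectorised individual-level
microsimulation (`microsim_oracle`) reproduces the deterministic chain to
within Monte-Carlo error and serves as an independent check of the cohort
arithmetic.

## Accrual conventions

* **Half-cycle correction** (default on): occupancy credited to cycle `t`
  is the trapezoidal mean of the memberships at its boundaries `t−1` and
  `t`. Summed over cycles this equals the trapezoidal area under the
  membership curve.
* **Discounting**: per-cycle factor `(1 + r)^{−t/12}` at annual rate
  `r = 3%` (range 0–8% in sensitivity analysis), applied at the end
  boundary of each cycle to both costs and QALYs.
* **Recurring costs**: drug (olaparib arm only), routine follow-up, and
  radiology accrue in PFS; salvage chemotherapy accrues in PD. The drug
  cost per cycle is `unit price per 150 mg × 4 tablets/day × 30.4375
  days` (365.25/12). Body surface area enters only by scaling the salvage
  cost linearly against the 1.72 m² reference patient, which makes it a
  pure sensitivity parameter (factor 1 at base case).
* **One-off costs**: BRCA1/2 testing and expected serious-adverse-event
  management costs (incidence × unit cost, summed over anemia,
  neutropenia, nausea, fatigue) are charged undiscounted at model entry in
  both arms, booked under the PFS column. SAE disutility is not modelled;
  the state utilities are taken to absorb it.
* **Terminal care** is valued once per incident death
  (`dead(t) − dead(t−1)`) at that cycle's discount factor, booked under
  the PD column.
* **QALYs**: occupancy × state utility × discount / 12 per monthly cycle
  (utilities: PFS 0.81, PD 0.74).

Where a convention was genuinely open — whether one-off costs are
discounted or half-cycle corrected, which column absorbs terminal care,
which states carry follow-up versus salvage — the choices above were fixed
once, as the combination that reproduces the published per-state cost and
QALY decomposition, and are exercised by the acceptance tests.

## Curve fitting

Two routes, matching the two kinds of input a practitioner has:

* **Pseudo-IPD** (time, event indicator): right-censored Weibull maximum
  likelihood, optimised over `(log λ, log γ)`; standard errors from the
  finite-difference observed information with delta-method transfer to the
  natural scale. Cross-checked in the test suite against an independent
  survival library on identical data (agreement to 4+ significant digits).
* **Digitized curve points** (time, survival): least squares on the
  complementary-log-log scale, `log(−log S) = log λ + γ log t`, weighted
  by at-risk counts when present. Noiseless points generated from a known
  Weibull are recovered to at least four significant digits.

Fitting requires ≥10 observations, ≥1 event (IPD), and ≥2 distinct time
points with `S ∈ (0,1)` (curve route).

## Synthetic data

`simulate_ipd` draws event times by inverse CDF
(`t = (−ln U / λ)^{1/γ}`), applies optional exponential random censoring
and administrative censoring (default cut-off 65 months, beyond both
arms' median OS), and is bit-reproducible per seed. Defaults mirror the
source trial's arm sizes (196 olaparib / 99 placebo). `km_estimate` is a
vectorised product-limit estimator with at-risk counts;
`make_digitized_fixture` reads the step function on a regular grid and
rounds survival to two decimals to emulate plot digitization (no
pixel-noise model).

What this generator does *not* emulate: patient covariates, informative
censoring, delayed accrual, or the hazard-ratio structure between arms —
each arm/endpoint is an independent Weibull. Passing recovery tests
therefore demonstrates correctness of the fitting and pipeline machinery
under the model's own assumptions, not robustness to real-world
digitization artefacts or model misspecification.

## Sensitivity analyses

* **One-way**: every economic parameter (six costs, four SAE unit costs,
  eight SAE risks, two utilities, BSA, discount rate) is set to its lower
  and upper bound with all else at base; bounds are ±20% of base for costs
  and risks and 0–8% for the discount rate. Rows are sorted by ICER
  spread for tornado display.
* **Scenario**: the olaparib unit price is scaled by a multiplier in
  (0, 1] and the full two-arm model re-run.
* **PSA** (default 1,000 iterations): costs and BSA are drawn from
  triangle distributions (min = low, mode = base, max = high) by inverse
  CDF; utilities and SAE risks from beta distributions with mean = base
  and SD = (high − low)/3.92 (the range read as a 95% interval),
  shapes by method of moments. Infeasible beta moments
  (σ² ≥ μ(1−μ)) and zero-width ranges collapse to constants, with a
  warning in the former case. The discount rate is held fixed. Survival
  parameters are not varied by default (their uncertainty is carried in
  the config but the published PSA parameter list excludes them). Because
  the sampled quantities do not affect the traces, the cohort model runs
  once per arm and only accrual repeats per iteration.
* **CEAC**: per willingness-to-pay λ on a grid (default $0–150k in $1k
  steps), the probability of cost-effectiveness is the fraction of draws
  with non-negative net monetary benefit `λ·ΔQALY − ΔC ≥ 0`; the NMB
  criterion avoids ratio instability when ΔQALY is near zero.

All randomness flows through one seeded `numpy` generator per analysis;
identical seeds give byte-identical exports.

## Numerical notes and limitations

* Survival is evaluated in log space; underflow at large `t` is benign.
* `Δqaly = 0` yields an explicit undefined-ICER flag; strict dominance
  (cheaper and more effective, or dearer and less) is flagged rather than
  reported as a ratio.
* Money is serialised with 2 decimals and probabilities with 6; internal
  computation is full precision.
* Only the Weibull family is implemented; log-logistic/log-normal/gamma
  extrapolations, piecewise fits, covariate adjustment, treatment
  discontinuation before progression, and time-varying utilities are out
  of scope. Costs reflect a single salvage regimen priced per cycle at
  the reference BSA.
* The deterministic test problem is desk-scale: a full two-arm run takes
  milliseconds, the complete tornado under a second, and a 1,000-iteration
  PSA a few seconds.
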