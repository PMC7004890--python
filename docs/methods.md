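# Methods

## Model and assumptions

`retikin` implements a six-component model of whole-body vitamin A
metabolism in children. Components 3 and 8 are **pure transport delays**
(exact time shifts), not compartments: a delay holds material for a fixed
time DT and releases it unchanged. This distinction matters — a
chain-of-compartments approximation would smear the absorption front,
whereas the observed plasma appearance after an oral dose is abrupt. For a
bolus dose the delay is a closed-form time shift; the content of delay 8 is
the trailing-window integral L(8,5)·∫F₅ over the last DT(8) days of plasma
history, and everything leaving it is irreversible loss.

L(4,3) and L(0,3) are interpreted as **split fractions** applied at the exit
of delay 3 (they sum to 1; 0.8 is the assumed absorption efficiency), not as
competing first-order rates.

The exchanging subsystem {4,5,6,7} is linear and time-invariant, so the
tracer solution is the matrix exponential of a 4×4 Metzler matrix applied to
the post-delay state (L(4,3), 0, 0, 0). The implementation diagonalizes the
matrix when the eigenvector basis is well conditioned (condition number
< 1e10) and falls back to per-time `scipy.linalg.expm` otherwise. Cumulative
integrals (needed for delay-8 content and loss accounting) use the identity
∫₀^τ x = A⁻¹(x(τ) − x₀) when A is invertible, with an augmented-matrix
exponential fallback for closed systems. Mass balance closes to better than
1e−8 at every output time and is asserted in the tests.

Assumptions inherited from the study design: tracee steady state over the
study window (intake balances disposal at the time scale of the
observations); kinetic linearity (no saturable transport); a single
well-mixed plasma pool; and no recycling from component 8 (L(10,8) = 1 is
structural).

## Steady state and derived statistics

With M(5) fixed at its measured geometric mean and intake U(3) entering
through the absorption delay, each compartment's own balance gives its mass
in closed form (see README). When fitted parameters are reported at three
significant figures the plasma balance itself closes only within rounding;
masses are deliberately taken from the per-compartment balances rather than
a global least-squares mass solve, because that is the arithmetic a
steady-state solver performs with M(5) clamped, and it reproduces the
published tables exactly. `check_plasma_balance` reports the residual
inconsistency (≈1e−3 relative for printed parameter sets) rather than hiding
it. The predicted intake DR/L(4,3) is exposed as a first-class output
because the fit uses it as the model prediction for the intake datum.

Transit, residence and recycling statistics are computed two independent
ways — Markov-chain closed forms (return probability per plasma exit,
geometric-series recycling number, visits × per-visit transit) and the
mean-residence-time matrix Θ = −A⁻¹ — and the two must agree (property-
tested at 1e−8 relative over random positive-rate models). Residence in the
delay elements is excluded from the system residence time T̄(SYS), matching
the convention of the published tables (T̄(SYS) = T̄(5,5)+T̄(6,5)+T̄(7,5)).
The recycling time is (T̄(6,5)+T̄(7,5))/ν(5); all published values match
this definition within rounding. Days of stores are reported in days
(30.44 d/mo is used only for display conversions).

## RID coefficients

Fa(t) = F(6)+F(7) and S(t) = [F(5)/M(5)] / {Fa/[M(6)+M(7)]}, so
FaS(t) = F(5)(t)·TBS/M(5) as an algebraic identity; the tests assert it to
1e−10 and assert that applying TBS = FaS/SA_p to the model's own plasma
curve returns the model's own TBS to 1e−6 at any time where Fa > 0. SA_p is
fraction of dose per μmol plasma retinol — the only convention that makes
the equation dimensionally correct in μmol. Coefficients are tabulated on
integer days 4–28 by default and always computed, never hard-coded.

## Fitting

Weighted least squares with observed-value-based sigma (FSD·y_obs): this is
the standard fractional-standard-deviation weighting convention and keeps
the objective comparable across iterations (model-based sigma would rescale
the objective as the fit moves). Composite FD_p points carry FSD 0.05,
except the anchor time (4 d, where most children are sampled) at 0.025 —
i.e. 4× the weight in the weighted sum of squares. The group intake is one
extra residual (U(3) − predicted intake)/(0.05·U(3)); it anchors the
terminal slope, which 28-day studies do not otherwise resolve (the slow
pool's turnover time is ~100–500 d).

Rates span four orders of magnitude (0.001–14 /d), so the optimiser works on
log-transformed parameters — positivity by construction and well-scaled
steps — with `scipy.optimize.least_squares` (trust-region reflective,
ftol = xtol = gtol = 1e−10), bounds 1e−6–1e3 /d for rates and 1e−3–2 d for
delays. Parameter FSDs come from the Gauss–Newton covariance on the log
scale, where SE(log p) = FSD(p) directly; the variance scale is
2·cost/(n − p). Degrees of freedom are reported as n − p (the legacy
kinetic-modelling software this field historically used applies a different,
undocumented convention, which is not reproduced). Rank deficiency of the
Jacobian is detected with a √ε-scaled singular-value cutoff (the Jacobian
comes from forward differences, so directions below ~1e−8 of the leading
singular value are numerically null); parameters with mass in the null space
get FSD = ∞ and a `singular` flag instead of a crash. FSD > 0.5 is flagged
as poorly identified. An optional multistart (seeded ±perturbation of the
start, best objective wins) is available; single-start is the default.

The sharing map expresses the partially parallel design: each adjustable
parameter is shared by all groups, independent in every group, or
independent for a named subset (the remaining groups sharing one value).
The packaged pattern shares DT(3) and L(6,5) across all three groups, makes
L(10,6) independent everywhere, and frees L(5,4), L(7,5), L(5,7), L(5,6)
for the Bangladeshi group.

## Synthetic super-child generator

The generator emulates the structure of the field studies so that fitting
and RID stages are testable without any external data: per-child kinetic
parameters are the group values times log-normal factors (defaults: GSD 1.2
on L(10,6), L(5,6) and L(5,4); 1.0 — no variation — elsewhere, so group
values are population medians); body weight is normal (group mean, SD);
plasma volume is a required linear-in-weight model with **no default
coefficients** (the anthropometric regression in use must always be
explicit; the presets carry per-group slopes back-solved from
M(5)/(retinol concentration × mean weight), a synthetic calibration);
plasma tracer concentration gets multiplicative log-normal measurement
noise (default CV 0.10); and compositing takes geometric means of actual
times and FD_p per nominal time, with the group pool as the geometric mean
over all samples — exact for log-normal noise (median-unbiased on the log
scale, verified by Monte Carlo).

Designs: the two-sample pattern (every child at the 4-d anchor plus one
extra time spread evenly over 6 h–28 d) for the Philippine (n = 120) and
Guatemalan (n = 135) presets; the Bangladeshi one-sample pattern (40
children at 4 d, 5–6 at each remaining time) emulated as 91 single-sample
children (the cohort's 87 children included 4 sampled twice late); and a
recommended future design (60 children, 13 times from 5 h to 42 d, anchor
7 d) as a named preset. Sub-day times are encoded as 0.25/0.375/0.5 d.

What the generator does **not** emulate: assay physics (isotopomer
corrections, LC-MS calibration), covariate effects (breastfeeding,
supplementation), dropout, or any real-data model misspecification. Passing
recovery tests therefore shows the estimation pipeline is correct and
well-conditioned under the stated design and noise — not that the
six-component model is the true data-generating process for any cohort.
Group constants not printed anywhere (body-weight SDs 1.3/1.3/2.2 kg,
retinol-concentration GSD 1.15) were chosen once as ~15% coefficients of
variation, typical anthropometric spread at these ages.

## Validation experiments (what the acceptance tests compute)

* Steady-state and derived-kinetics tables and the 4-d FaS coefficients are
  recomputed from the preset parameters and compared at 2%/3% relative —
  the slack covers three-significant-figure rounding of the printed inputs.
* The simulator is verified against an independent adaptive ODE integration
  (`solve_ivp`, rtol 1e−11) at 1e−6 relative over 0–60 d for all groups.
* Parameter recovery: 20 replicates of the full three-group design with 5%
  log-normal measurement noise (between-child variability off, so the
  composite's generating truth is exactly the group model), partially
  parallel fit started at ±30% seeded perturbations of the truth. Median
  TBS error and per-parameter median errors are well inside 10%/15%.
* Noise-free self-consistency: a fit started at twice the truth returns to
  it to ~1e−15; the intake datum is made self-consistent (set to the truth
  model's own predicted intake) because the printed parameter set leaves a
  ~0.4% plasma/intake imbalance, so the raw intake is not the exact argmin.
* Intake-datum effect: omitting the intake residual on 28-d data leaves the
  terminal slope nearly unconstrained; over 20 seeds the stores estimate
  moves opposite to the terminal-slope shift (steeper slope → smaller TBS)
  in ≥15/20 replicates (observed 20/20), the mechanism by which intake data
  stabilize TBS. The *direction* of the drift in any one study depends on
  that study's noise realization, which is why both inflation and deflation
  occur.
* The CLI pipeline under a fixed seed is asserted byte-identical across
  runs (artifacts carry version/seed/config-hash provenance, no
  timestamps).

Problem sizes were chosen so the full suite runs in well under a minute on
one CPU.

## Known limitations

* No tracee (cold retinol) dynamics away from steady state; no depletion
  trajectories.
* No per-child nonlinear mixed-effects estimation — the design composites
  to group means by construction.
* The delay representation assumes bolus input; continuous (dietary) tracee
  inflow through the delays is only used via its steady-state flux.
* FSDs are asymptotic Gauss–Newton quantities; with 11–12 composite points
  per group they understate uncertainty for strongly nonlinear parameters.
* The plasma-volume presets are calibrations, not anthropometric truth;
  users with real cohorts must supply their own regression coefficients.
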