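# Methods

## Model and assumptions

The model describes a spatially homogeneous multispecies biofilm as four
volume fractions — live bacteria `L`, dead bacteria `D`, EPS `E`, solvent
`T` — and three dissolved concentrations: antibacterial agent `A`,
quorum-sensing signal `H`, growth-factor proxy `Q`. Its assumptions:

* the bacterial community is coarse-grained into two phenotypes (live,
  dead); species composition is not resolved;
* nutrient is constant and absorbed into the rate constants; there is no
  explicit nutrient variable;
* the functional solutes occupy negligible volume, so the closure
  `L + D + E + T = 1` involves only the four material phases;
* spatial diffusion of the agent is replaced by the dimensionless
  relaxation factor `γ = [1/(T + E/D_pr)] · [2(T+E)/(2+L+D)]`; there is no
  spatially resolved (PDE) variant;
* live-cell proliferation and signal production are gated by squared Hill
  functions of `Q`; EPS production by a squared Hill function of `H`; all
  production terms saturate logistically at carrying capacities;
* the agent kills at rate `c3 γ A` and *slows dead-cell degradation*
  through `k13/(k13 + A)` — treatment stress delays disintegration, which
  is what makes the live ratio keep falling for a while after treatment;
* treatment immersion and rinse are protocol events: the agent is hard-set
  to the pulse level at immersion and to the residual "leaked" level
  `A_residual` at the rinse, after which it decays by consumption and
  self-degradation (the post-antibiotic effect).

## Units and conventions

Internal time unit is seconds, reporting unit days (week *k* = 7 *k*
days). Volume fractions are dimensionless; `A`, `H`, `Q` and all Hill
constants are in kg/m³. The characteristic scales are `t0 = 1 s` and
`C = 8.24e-3 kg/m³`; a pulse at dimensionless level 1 means `A = C`.
`c_a` and `c_q` carry kg·m⁻³·s⁻¹ — the only reading under which `dH/dt`
and `dQ/dt` have concentration-per-time units. `T` is always recomputed
from the closure after every solver step, never integrated, so the volume
balance holds exactly.

## Parameters

Parameters fall into three classes: (I) donor- and agent-independent
(`H_max, Q_max, c5, c_a, k_9, k_q, E_max`), (II) donor-dependent
(`c2, c_q, r_bs, r_dp, L_max`), (III) agent-specific
(`c3, c8, r_a, k_13, D_pr, A_residual`). The shipped sets live in
`src/oralbiofilm/data/*.yaml`, one per study, checksum-frozen. The aged
study ships `A_residual = 0`: its readout is immediately post-pulse, so a
residual never enters, and no value was measured for it.

Defaults that define the study conditions: 5% live-cell inoculum
(`L = 0.05`, everything else zero), 21-day growth before treatment,
600-second pulses at level `C` for the recovery study, 60/180-second
pulses for the age study over ages 1–56 days, 105-day recovery horizon,
viability sampling at weeks {0, 1, 3, 8, 11, 15} post-treatment.

## Numerics

* Integrator: `scipy.integrate.solve_ivp` with LSODA, `rtol 1e-8`,
  `atol 1e-12` (rates span 1e-7–1e-2 s⁻¹ over 1e7-second horizons);
  calibration uses `rtol 1e-6` / `atol 1e-10` for speed.
* Output grids only select reported points; the solution is independent of
  grid density. Recovery trajectories use a 0.25-day grid.
* Negative components smaller in magnitude than 1e-12 are clipped to zero
  as integrator roundoff; anything larger raises, distinguishing roundoff
  from misuse.
* Degenerate states (`T + E/D_pr = 0`, or `L + D = 0` in the live ratio)
  raise named errors rather than returning NaN.
* The untreated steady state has the closed form `Q = Q_max`, `H = H_max`,
  `E = E_max`, `L_ss = L_max (1 − r_bs/(c2 h(Q_max,k_q)))`,
  `D_ss = (r_bs/r_dp) L_ss`; if natural death exceeds saturated growth the
  fixed point is extinction. A 500-day integration from the inoculum
  reproduces it to better than 1e-4 relative, and recomputing
  `r_dp D_ss/L_ss` returns the shipped death rates to ~1e-10.

## Calibration

`r_bs` is pinned first from the control-group live ratio through
`r_bs = r_dp (1/ratio − 1)`. The remaining parameters are then refined
one at a time by an interval search on the sum-of-squares live-ratio
misfit. Because a best-fit problem offers no sign change to bisect on,
the interval-halving step is implemented as a golden-section reduction —
the deterministic minimisation analogue — returning the midpoint of the
final interval. Design choices, open where the procedure itself is
underdetermined:

* search intervals default to (1e-3×, 10×) the shipped value for the
  matching agent, overridable;
* fit order: non-agent parameters first, agent-specific (class III) last;
  within a block, parameters can be ordered by finite-difference
  sensitivity of the objective (largest first);
* 3 outer passes by default, stopping when a pass improves the objective
  by less than 1e-8; a refined value is kept only if it does not worsen
  the objective, making the objective non-increasing by construction;
* the objective uses the live ratio only — the sole fitted observable —
  with replicates entering individually.

### Identifiability

Ratio-only observations at six timepoints identify *combinations* rather
than all factors. The week-0 kill pins the product `c3·γ(D_pr)` at the
treatment state, and the recovery shape pins the joint agent-depletion
rate of (`r_a`, `c8`); along these ridges the coordinate search stalls at
a small but nonzero misfit regardless of pass count. Consequently the
package treats `c3` recovery (with the co-factors held at reference
values) and the kill-product `c3·γ` as the meaningful recovery targets:
at the study design (6 timepoints × 2 discs, ratio noise sd 0.03) `c3`
is recovered within 25% in 10/10 seeds (median error 2.3%), and in joint
five-parameter fits the kill product is recovered to ~2% even while the
individual factors wander by tens of percent. Full joint recovery of all
agent-specific parameters from such data is not attainable and is not
claimed.

## Synthetic observations

The generator emulates the confocal viability measurements the model is
fitted to: live ratio sampled at weeks {0, 1, 3, 8, 11, 15}
post-treatment, two discs per group and time, additive Gaussian noise on
the ratio truncated to [0, 1]. The sd default 0.03 is a representative
error-bar half-width, a modelling choice rather than a measured quantity.
A counter-based stream keyed on (seed, group, time, replicate) makes
draws independent of insertion order. The generator does **not** emulate
imaging physics (voxel volumes, staining efficiency), field-to-field
variance within a disc, or any disc-level random effect — one variance
component only. Passing tests therefore demonstrate correctness of the
pipeline and identifiability under idealised noise, not robustness to
structured measurement error in real CLSM data.

## Study-condition findings the tests encode

* The treated live ratio reaches its minimum about one week
  post-treatment (CHX, donor 1) and all six donor × agent groups return
  to within 2% of their pretreatment ratio by week 15 (most by weeks
  8–11).
* Week-0 kill severity ranks exactly as the parameter-implied exposure
  `c3·γ` per donor, with NaOCl strongest.
* Recovery *speed* is governed by the residual agent level and its decay,
  not by kill strength: with the shipped sets IPI (largest residual)
  recovers slowest, so only the NaOCl-vs-CHX ordering is asserted.
* Under 3-minute CHX pulses the post-pulse ratio becomes age-insensitive
  (<5% change per weekly age step) from week 3 — the maturation age; the
  NaOCl response saturates one week later.
* The late recovery tail approaches the steady ratio from above (the
  21-day pretreatment state slightly overshoots the asymptotic
  `r_dp/(r_dp+r_bs)`), so monotone recovery holds for the climb out of
  the nadir, after which the ratio is pinned at the steady value.

## Problem sizes

Steady-state checks integrate 500 days; recovery studies 21 + 105 days on
a 0.25-day grid (200 days for the tail property); the age sweep covers 8
ages × 3 agents × 2 durations; calibration harnesses use 10 seeds per
noise level with search depth 25–30. These sizes make every result
reproducible in seconds while leaving all reported quantities well inside
their numerical tolerances.

## Known limitations

* No spatial structure: γ is a proxy, not a diffusion solution; channel
  and surface effects are out of reach.
* Two-phenotype coarse-graining: no species succession, persister states
  or tolerance evolution.
* Constant nutrient; weekly medium changes are absorbed into rates.
* The noise model is a single truncated-Gaussian variance component.
* The growth factor `Q` is a proxy for unidentified regulatory proteins;
  its parameters are only meaningful jointly with the Hill constants.
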