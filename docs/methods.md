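# Methods

This note documents the models behind `zflume`, the defaults and why they
were chosen, the numerical conventions, and what the simulations can and
cannot say about a physical flume.

## Pump and meter models

**Pump ground truth.** The only published description of the bench pumps
is the fitted quadratic relating working-section velocity *v* (cm s⁻¹) to
the PWM command: PWM = *c*₀ + *c*₁*v* + *c*₂*v*², with
(244.4, −1.374, −0.021) for the unrestricted fast configuration and
(242.8, −8.430, −1.042) for the restricted slow configuration. The
simulator defines the pump's truth as the analytic inverse of this
polynomial — the root of *c*₂*v*² + *c*₁*v* + (*c*₀ − PWM) on the physical
branch (v ≥ 0, velocity decreasing in PWM), clamped to zero for
PWM ≥ *c*₀. This makes the printed polynomials exactly recoverable by the
calibration procedure, which is the property the toolkit is for. Each pump
additionally has:

- `share` — its fraction of the section velocity (0.5 per pump when both
  run; the split is not documented, and symmetry is the simplest contract
  consistent with the two near-identical meter calibrations);
- `restriction` ∈ (0, 1] — a multiplicative outlet-valve factor;
- `stall_pwm` (default 250) — commands at or above it stall the impeller
  and flow snaps to 0;
- `noise_sd` (default 0.005) — multiplicative Gaussian noise per 1 s tick.
  Only aggregate tracking deviations are published, so the scale was fixed
  once at 0.5 %, which keeps the simulated trial-mean deviation at the
  magnitude reported for the physical rig (≈ 0.1 cm s⁻¹).

**Meters.** Each turbine rotation is one pulse. Over a counting window the
meter reports ⌊carry + window·(flow − offset)/ml_per_pulse⌋ pulses and
carries the fractional remainder forward, so concatenated windows conserve
pulses and the long-run rate is unbiased. Truth values (2.44 ml/pulse,
0.79 ml s⁻¹) and (2.38, 1.55) mirror the two bench meters. The published
intercept is nominally "in ml"; dimensional analysis of the conversion
formula (*p*/*s*)·*m* + *x* requires ml s⁻¹, and it is treated as a flow
offset throughout.

**Time base.** Discrete 1 s ticks. The 4 s count window and 5 s cycle are
integer multiples; the trailing second of each cycle is idle processing
time during which pulses are not counted (the turbine still spins — those
rotations are simply unobserved, as on the physical counter).

## Calibration

The meter fit is ordinary least squares on (pulse rate, flow) pairs from a
simulated bucket test (default 60 s collections at 10 rates). The PWM fit
is least-squares of PWM on measured velocity over a 10-level descending
sweep from `stall_pwm − 10` down to PWM 45, 30 s per level with the final
15 s averaged; velocities come through the meter calibration, never from
simulator truth, so the quantization the real firmware sees is present in
the calibration data. Stalled levels (zero pulses in the averaging window)
are flagged and excluded — zero-flow points do not lie on the quadratic
branch. Fitting PWM-on-velocity (rather than inverting a velocity-on-PWM
fit) is deliberate: the run-time needs a PWM for a target velocity, and the
fitted direction is then exact where it is used.

Because meter pulses are quantized, a sweep-based fit recovers the
constant *c*₀ to about 10⁻³ relative but the velocity-dependent
coefficients only to a few percent in the slow regime (flows there are a
handful of pulses per window). On exact quadratic points the fitter is
exact to machine precision; the unit tests check both regimes separately
and compare against an explicit normal-equations solve.

The integer lookup rounds half away from zero and clamps to [0, 255];
out-of-range targets evaluate at the nearest range edge with a warning.
255 is the unconditional shut-off command and bypasses the calibration.

## Controller semantics

- Stages are right-open: stage *k* covers [(k−1)·*T*, k·*T*). Stage
  duration must divide by the cycle period, so boundaries fall on cycle
  boundaries.
- The kill switch latches and forces PWM 255 from the next acquisition
  cycle in every mode; a protocol run ends on its first killed record.
- Slow regime: pump 2 is powered down with its valve closed, so the
  controller trusts only meter 1 and reports *F*₂ = 0. (Converting a
  0-pulse meter-2 count through its calibration would inject the 1.55
  ml s⁻¹ intercept — a 0.3 cm s⁻¹ phantom velocity.) Switching regime
  invalidates the PWM calibration until a new sweep is fitted, and
  calibrations carry their regime so a stale fast calibration is rejected
  outright.
- Fish exhaustion is evaluated every tick against the true (noisy)
  section velocity. When the fish fails, the trial stops on the spot: the
  in-progress data package is never completed, so a nine-stage larval
  trial writes exactly 54 records, and the exact failure time is kept in
  the log header (`exhaustion_time_s`).
- Mode time-outs (not published) default to 30 min and are configurable.

## Synthetic fish

The threshold model (default) exhausts the first instant velocity exceeds
the sustainable limit; it is deterministic, which makes protocol durations
exactly reproducible. The reservoir model adds an anaerobic store (default
capacity 15 cm of excess-velocity·time, refill 0.5 s⁻¹ below the limit)
for fish that partially swim their final stage; it always exhausts strictly
later than the same threshold fish. Cohort cells draw SL and relative
performance from Gaussians around the cell means; the absolute limit is
relative·SL with SL in mm converted to cm (adult SL ≈ 25–30 mm rules out
cm as the growth model's unit). Stock cell means: 12.1 SL s⁻¹ at 14 dpf;
adults 15.9/13.0 (young m/f) and 13.6/10.4 (old m/f) SL s⁻¹, with young
and old mean SL set to 27 and 29 mm. The developmental trajectory
generator uses a continuous piecewise mean anchored at the 14 dpf
performance, breakpoint 28 dpf, slopes 0.698 and 0.344 cm s⁻¹ dpf⁻¹, with
residual sd 0.5 cm s⁻¹ and the 5,5,5,6,6 per-age design.

What the generator does *not* emulate: temperature dependence, gravidity,
tail-beat biomechanics, behavioural refusals (fish resting on the screen
early), or day-to-day variance components. Passing tests therefore
demonstrate that the pipeline recovers its own generating parameters under
realistic noise — not that a physical rig meets the same numbers.

## Statistics

**Tracking deviation.** Per completed stage, records beginning ≥ 5 s into
the stage are averaged (the step transient and the partial final stage are
excluded) and |mean − target| is averaged unweighted across stages.
Absolute deviation is the conservative reading of an "average difference"
reported with a positive mean and small SE.

**Segmented regression.** The mean function is the hinge model
β₀ + β₁x + β₂(x − ψ)₊, continuous at ψ. With ψ free, a grid search
(default 0.25 dpf) minimizes RSS over candidates having at least two
distinct x strictly on each side, ties to the smaller ψ; slope CIs are the
t-based intervals of the linear model at the chosen ψ (conditional on it).
If a single line fits no worse than the best hinge, the breakpoint is
flagged unidentifiable. A stricter three-per-side candidate rule would
leave exactly one admissible ψ for the stock five-age design and reduce
"estimation" to a fixed fit, so two per side is used.

**Factorial analysis.** `statsmodels` OLS with `C(sex)*C(age_group)` and
`anova_lm`. Type II sums of squares are the default because the adult
design (9/8/3/3) is unbalanced and Type II main effects are invariant to
level ordering; Type I (the `aov` default in R) is available via
`ss_type=1`. Marginal effects are differences of *unweighted* cell means,
so the reported sex and age effects are not biased by cell sizes. With a
constant response all sums of squares are defined as exactly zero rather
than ratios of rounding error.

## Problem sizes and determinism

All simulations are desk-scale: sweeps are 300 virtual seconds, the
longest no-fish schedule ~750 s, cohorts tens of fish (the convergence
check uses 10⁴ draws). The full test suite and the acceptance script each
run in seconds. Every noise source is an explicitly seeded
`numpy.random.Generator`; noiseless runs are bit-identical, and the trial
conditions used by the acceptance script (pump noise 0.5 % with seed 1,
developmental cohort seed 7, adult cohort seed 11) are fixed study
conditions, so its output is reproducible run to run.

## Known limitations

- No hydrodynamics: the working section is a velocity, not a flow field;
  turbulence, boundary layers, the bubble trap and reservoir dynamics are
  out of scope.
- The pump inverse is exact where the real pump curve is only locally
  quadratic; extrapolation outside the calibrated range is clamped, not
  modeled.
- The slow-regime restriction is a multiplicative flow factor; the real
  valve also reshapes the pump curve (which is why the slow configuration
  carries its own measured characteristic).
- U_crit-style long protocols are expressible through `Protocol` but no
  presets or validation data are provided for them.
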