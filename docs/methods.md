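# Methods

`pumptwin` models the accuracy stack of a plunger-type insulin pump at
five levels: dose regimen, drive mechanics, motor speed control,
gravimetric deviation statistics, and learned deviation compensation.
This note records the models, their assumptions, the tunable parameters
that matter, and the choices made where the design was genuinely open.

## Dose regimen

The total daily insulin requirement for an insulin-naive patient uses
the weight/fasting-glucose rule of thumb

    U_total = 6 K (P − 100) / 2000        [U/day]

with K the body weight (kg), P the fasting glucose (mg/dL) and 100 the
normal-glucose reference.  Glucose below 100 mg/dL is rejected rather
than returning a negative dose.  The daily total splits into a basal
fraction delivered as micro-doses on a fixed interval inside clock
windows, and a bolus fraction split equally across pre-meal
deliveries.  The basal fraction is an explicit parameter: clinical
practice quotes 40–60%, and the shipped 27 U reference schedule uses
15/27 ≈ 55.6% (three 5 U basal windows at 0.1 U per 6 min plus three
4 U boluses delivered as 2 U events).  Clock arithmetic wraps at
midnight, so a 20:00–01:00 window is a valid 5-hour span.  Schedules
conserve dose exactly: the event table must sum to the daily total
within 1e-9 U, enforced at construction.

No glucose dynamics or pharmacokinetics are modelled; the regimen is
an open-loop delivery plan.

## Screw-drive mechanics

A commanded dose maps to encoder pulses through the physically forced
chain

    volume = dose / concentration              (mL; U-100 default)
    advance = 4·volume / (π d²)                (mm, reservoir bore d)
    pulses = quadrature · N0 · i · advance / p

with screw pitch p (mm/rev), gear reduction i, code-disc line count N0
and quadrature factor 4.  The map is exactly linear in dose with zero
intercept; fractional pulses are kept as reals, with quantisation
(floor) a separate explicit call so both can be tested.

Small commanded volumes produce no liquid at the needle because of
reservoir/line elasticity, friction and transmission backlash.  These
are lumped into a single dead volume per configuration; the minimum
effective dose is the dose whose volume equals dead volume plus one
pulse quantum.  It is nondecreasing in dead volume and nonincreasing
in pulse resolution.  The two shipped presets (`one_stage`,
`two_stage`; the two-stage build has a 5× finer transmission) have
their dead volumes **calibrated** so the minimum effective doses are
0.095 U and 0.047 U — bench-anchored calibration fixtures, not
measurements of any particular device.  The relative reduction between
them computes to 50.53%.

## Motor speed loop

The motor's speed-vs-voltage response is a first-order lag with static
gain 100 rpm/V and time constant 50 ms, discretised exactly under a
zero-order hold at 1 ms:

    y[k+1] = a·y[k] + (1−a)(gain·u[k] − load_gain·load[k]),  a = e^(−Ts/T).

Load torque enters as an additive speed offset with `load_gain` =
800 rpm/(N·m) open loop, chosen so the packaged 1 → 1.5 N·m load step
at 0.5 s dips a 1000-rpm loop by about 2.8% — enough to leave the ±2%
settling band and make recovery time a meaningful metric.  No per-phase
electromagnetics, torque ripple or firmware timing is modelled.

The fixed controller is an incremental (velocity-form) PID,

    Δu = kp (e − e₁) + ki e + kd (e − 2e₁ + e₂),

with output clamping to [0, 24] V; the velocity form carries no
integral state and therefore cannot wind up.  The shipped tuning
(kp = 0.02, ki = 0.03, kd = 0) gives ≈ 4% overshoot on the default
scenario.

The adaptive controller (BP-PID) emits kp/ki/kd each step from a
4–5–3 perceptron: inputs (setpoint, measurement, error, bias) scaled
by a fixed 1000-rpm normalisation, tanh hidden layer, sigmoid outputs
scaled by per-gain ceilings (kp ≤ 1, ki ≤ 0.2, kd ≤ 0 — the derivative
channel is disabled by default, matching the common finding that the
speed loop needs no derivative action).  Online training is gradient
descent with momentum on the squared tracking error, using
sign(Δy/Δu), ε-guarded, as the plant-sensitivity surrogate.  Weights
initialise uniform(−0.5, 0.5) from a seeded generator, so traces are
reproducible; a non-finite weight aborts the run with a distinct
error.

With the learning rate at zero the controller is defined to be static:
the gain schedule freezes at its first evaluation, so the loop
degenerates bit-for-bit to a fixed-gain PID with those gains.  This is
a deliberate definition — the forward pass depends on the measurement,
so without it a "no-learning" controller would still vary its gains —
and it gives the no-learning limit an exact, testable meaning.

Step metrics: overshoot as percent of setpoint; settling as first
entry into the ±2% band without leaving (measured before the
disturbance); recovery as the time from the disturbance to re-entering
and holding the band; never-settling reported as +inf.  The ±2% band
is the common control convention.

## Deviation statistics

Single-infusion deviation is |theoretical − actual| / theoretical ×
100.  The absolute-value convention is used because over-deliveries
must count against accuracy for maxima and means to be coherent; a
signed variant is available behind a flag.  Mean deviation is the
arithmetic mean of single deviations; reports carry unrounded values
and round half-away-from-zero to two decimals only for display.
Basal-rate accounting applies the same ratio to cumulative dose at a
read time versus rate × time; it is memoryless in the sense that each
read depends only on the reading and rate·t.

The paired t-test is the classical one on differences, with two-sided
p from the Student-t distribution (scipy) and a symmetric 95% CI; a
summary-statistics entry point covers the common case where only n,
mean difference and SD are reported.  Zero variance with nonzero mean
yields a ±inf t and p = 0 sentinel.

## Synthetic data

The generator emulates the statistical texture of gravimetric bench
runs: delivered = commanded·(1 − bias) − drift·index + N(0, σ), clipped
at zero.  Defaults: 120 infusions of 2 U, bias 3.5% (mean deviations in
the bench-typical 2.5–4% range), no drift, σ = 0.01 U (a 10 mg-scale
weighing error; Gaussian chosen as the standard model for balance
noise).  Basal runs deliver per-interval micro-doses with the same bias
and independent noise, accumulated and forced nondecreasing.  All
generators are bit-reproducible under a fixed seed.

What the generator does **not** emulate: evaporation, needle viscous
retention, balance drift, bubble formation, or dose-dependent bias
structure.  Passing tests therefore demonstrate the pipeline's
correctness and sensitivity under an idealised error model, not
performance on any physical pump.

Two printed bench tables ship verbatim as regression fixtures
(repeated 1–10 U infusions; a 24 h, 0.5 U/h basal run at 14 read
times).  Two of the ten repeated-infusion rows (2 U, 3 U) are
internally inconsistent in the source table — their printed aggregates
do not follow from their own printed actuals — and are retained for
reference but excluded from numeric checks.

## Deviation forecasting and compensation

The forecaster is a stack of gated recurrent (LSTM) and dense layers
built from a pattern string ("LDL" by default: recurrent–dense–
recurrent, each 32 units, topped by a linear one-unit head), written
directly in numpy with full backpropagation through time.  Training is
plain SGD on mini-batches with global-norm gradient clipping at 1.0;
everything is deterministic given the spec seed.

The prediction target is the cumulative-deviation trajectory, one step
ahead from a sliding window of 10 values.  Internally the network is
fed the series' first differences (per-infusion increments),
standardised by training-split statistics, and the cumulative
prediction is reconstructed as last-observed + predicted increment.
This detrending is essential: a cumulative series trends upward, so a
network regressed directly on cumulative values must extrapolate
beyond its training range on the test split and systematically
under-predicts there; on increments the problem is stationary.

The train/test split is chronological (no shuffling — shuffling would
leak the drift structure), boundary at floor(n·fraction), default
fraction 0.85.  Metrics are computed on the original cumulative scale:
MAPE excludes zero-valued targets (undefined otherwise) and RMSE is in
U.  "Accuracy" curves report the fraction of predictions within a 5%
relative band of the target, configurable.

Grid search fits every cell of a lattice (default 16 cells: epochs
{100, 300, 500, 700} × batch {128, 256} × hidden {32, 64}) and ranks by
MAPE, ties broken by RMSE then fewer epochs; diverged cells rank last,
flagged.

Compensation spreads the predicted final cumulative deviation
uniformly: per-infusion add-on = predicted total / n.  `apply_plan`
raises each commanded dose by that amount; both retrospective
(re-deliver the same run) and prospective (apply to the next run) uses
are supported, since the plan itself is just a per-event increment.  On
the shipped synthetic scenario the recovered add-on matches the true
per-infusion bias within two standard errors of the noise, and
re-delivery with raised commands cuts the mean deviation roughly
tenfold (from ≈3.5% to ≈0.4%).

## Problem sizes and numerical choices

The packaged experiments use a 1 s, 1000-step speed-loop simulation and
120-infusion deviation series with 300-epoch training — a few seconds
per fit on one CPU core, which is ample for series of this length.
Tolerances: printed-percent comparisons at ±0.005 pp (half a display
digit); exact-arithmetic claims at 1e-9–1e-12; closed-loop closed forms
at 0.5%.  Ties in the grid ranking are broken deterministically.
Degenerate inputs (empty lists, zero variance, sub-reference glucose,
stroke-exhausting doses, non-monotone cumulative readings) raise typed
errors rather than returning sentinels, except where a sentinel is the
documented contract (+inf settling time, ±inf t-statistic).

## Known limitations

- The mechanics presets are calibrated, not measured; pulse counts for
  a given dose depend on geometry constants that vary by device.
- The speed loop is a first-order abstraction; conclusions about
  overshoot/recovery compare controllers on the same abstract plant and
  do not transfer to a specific motor without re-identifying gain, time
  constant and load sensitivity.
- The adaptive controller's dominance over the fixed tuning is a
  property of the shipped default tuning, scenario and seeds, verified
  by simulation, not a theorem.
- The forecaster assumes an approximately constant (or slowly drifting)
  per-infusion deficit; abrupt regime changes (reservoir swap, line
  refill) violate the stationarity of increments and would need
  retraining.
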