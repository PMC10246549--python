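# Methods

This note records the models, the numerical choices and the open design
decisions behind `ventcontrol`, and what the test suite does and does not
establish.

## Plant model

The hose-patient circuit is a single-state linear system: lung pressure is
the state, blower outlet pressure the input, and airway pressure plus
patient flow the outputs. All pressures are in mbar, flows in l/s, time in
seconds. Lung compliance is stored in ml/mbar, as quoted clinically, and
converted to l/mbar internally; the reference set (r_lungs = 5 mbar·s/l,
c_lungs = 20 ml/mbar) therefore has a lung filling time constant of 0.1 s.
Two conventions are deliberate:

- The input matrix of the hose-patient model carries a **positive** sign:
  a positive blower pressure charges the lungs. This is required for the
  plant's positive DC gain and is the physically causal choice.
- The hose parameter is a **resistance** (4.5 mbar·s/l). The model has no
  hose compliance state; hose dynamics are out of scope.

The blower is a critically damped second-order actuator with unit DC gain
(ω_n = 2π·30 rad/s, ζ = 1 by default); its poles at −188.5 rad/s are the
fastest dynamics in the loop and set the integration-step requirement.

Transfer-function objects keep their coefficient arrays exactly as
computed: no pole-zero cancellation is ever performed (a pure-proportional
PID deliberately remains s/s), so assembled polynomials can be compared
coefficient-by-coefficient against independent convolutions.

## Fuzzy gain scheduling

Inputs e (error, mbar) and ce (error rate, mbar/s) are scaled by
configurable gains (defaults 1.0 and 0.01 respectively — the error-rate
scale is a declared choice, since a raw backward difference is three orders
of magnitude larger than the error) and clamped onto normalized universes
[−1, 1]. Outputs live on [0, 1] and map affinely onto physical gain ranges,
default k_p ∈ [0, 2], k_i ∈ [0, 250] 1/s, k_d ∈ [0, 0.02] s; the ranges
cover every benchmark gain row shipped in the fixtures.

The default membership geometry is the standard complete partition: seven
triangles with uniformly spaced apexes, feet on the neighbouring apexes,
and saturated shoulders at both ends. It is a partition of unity and is
fully overridable through the config; it is this package's declared
default, since no numeric breakpoints are published for the original
geometry. Operators are classical Mamdani: AND = min, implication = min,
aggregation = max, rule weight 1.

**Defuzzification is exact, not grid-based.** The aggregate of clipped
piecewise-linear membership functions is itself piecewise linear, so the
centroid is computed by collecting every kink abscissa (membership
breakpoints, clip-level crossings, pairwise intersections of linear
pieces), evaluating the aggregate there, and integrating in closed form —
the area by the trapezoid identity (exact for piecewise-linear integrands)
and the first moment by the per-segment quadratic antiderivative. This
removes the grid-resolution error (a 1001-point uniform grid is only
accurate to ~1e-4 near kinks) and makes the output directly checkable
against brute-force dense integration, which the tests do at 1e-6.

If no rule fires (possible only with user-supplied incomplete partitions,
against which construction warns), the output falls back to the universe
midpoint and the result is flagged.

A property worth recording: raising every consequent by one label is *not*
guaranteed to raise the defuzzified output. When two labels collide after
the shift, their mass lumps merge under max-aggregation and the centroid
can drop by more than 0.15 on a unit universe. For interior labels the
shift is an exact translation of the aggregated set and the centroid moves
by exactly one apex spacing; that is the form the tests assert.

## Closed-loop simulation

Fixed-step simulation with the blower and plant combined into one linear
state equation advanced by classical fourth-order Runge-Kutta under
zero-order-hold input; for a linear time-invariant system with held input
this reduces to constant transition matrices, precomputed once. The default
step is 1e-4 s (the blower mode at −188.5 rad/s is then resolved ~50×; the
guideline dt ≤ 1/(20 ω_n) ≈ 2.7e-4 s is the coarsest recommended step).
A fixed step keeps ITAE values comparable across optimizer candidates.

The discrete PID integrates by trapezoid and differentiates by backward
difference through a first-order low-pass (cutoff N = 100 rad/s by
default) so the derivative term survives measurement noise; the filter can
be disabled, which is how the simulation is compared against the ideal
closed-loop transfer function (agreement within 1e-3 at dt = 1e-5 over a
unit step). The loop starts at rest with zero pre-start error, so a
reference stepping at t = 0 produces the dt-wide derivative pulse that
approximates the ideal controller's impulse. Optional saturation clamps
the blower command with clamping anti-windup (integral frozen while
saturated); it is off by default.

Disturbances are additive on the *measured* airway pressure (sensor side),
scaled by the breathing-pattern step height — the published scenario of a
1 % disruption for 0.5 s names no injection point, so this is a declared
choice. Measurement noise is zero-mean Gaussian with standard deviation
equal to a fraction of the current reference amplitude, seeded, and
bit-reproducible. Non-finite states abort with the divergence time.

Reference patterns: a 50 %-duty square pulse (`low` for the first half
period — the published "initial value 0, final value 1, period 2" profile)
and a PEEP/PIP cycle holding PIP for the inspiration time, then PEEP for
the expiration time. The fixture for the 2 s-cycle PEEP/PIP scenario uses
a symmetric 1 s / 1 s split, since no split is published.

Step metrics are read from the true (noise-free) airway pressure:
fractional overshoot relative to the step height, peak time, settling time
into a 2 % band (the band is configurable; no published value exists), and
ITAE integrated by trapezoid over the record. The CLI windows the metrics
to the plateau after the first rising edge so later cycle edges do not
contaminate the settling time.

## Rule-base optimization

The classical class-topper optimizer is retained for continuous problems:
section toppers accelerate toward the class topper and students toward
their section topper, with inertia weights (default 0.7) and acceleration
factors (default 2), fresh uniform random gains per member per iteration,
and box clipping. On the 2-D sphere function (N = 20, 4 sections, 100
iterations) it localizes the optimum to 1e-2 in ≥ 8/10 seeded runs.

For the 147 integer consequents the continuous update is meaningless, so
the reshaped variant uses selection plus two-level block crossover only:
per iteration each non-topper member receives one contiguous block of
`segment_len` rule positions (default 10, per 49-rule grid, uniformly
random start, no wrap-around) from the class topper and an independently
placed block from its section topper. The class topper survives unchanged,
making the best-so-far fitness provably non-increasing. Population and
iteration defaults (N = 20, 4 sections dealt round-robin, 50 iterations)
are declared values; none are published. Fitness evaluations during
optimization require a deterministic (noise-free) scenario; diverged
simulations receive a 1e9 mbar·s² penalty, dominating any feasible ITAE.

A random-reset mutation flag exists but defaults off, matching the
published operator set. Its absence has a hard consequence: crossover can
only recombine consequent values already present somewhere in the
population, so a value missing at a given position at initialization can
never appear. With N = 20 the probability that all 147 positions cover any
given target value is ≈ 1e-3, which bounds what rule-base recovery
experiments can achieve regardless of iteration count; empirically the
best Hamming distance to a planted 147-gene target after 200 iterations is
~85–103 (and ~40–57 even with mutation at rate 1/147).

## Stability analysis

The scheduled controller is linearized by freezing the gains at one
operating triple (for a FIS controller, the schedule at e = ce = 0); no
claim is made beyond the frozen-gain loop. The open loop always carries the
PID's integrator pole, handled analytically: the winding of 1 + L over the
full right-indented Nyquist contour equals twice the unwrapped phase change
along the positive frequency axis (conjugate symmetry) minus π per origin
pole (the indentation arc), so no near-zero frequency evaluation is needed
beyond the grid's low end. The default grid is 2000 log-spaced points over
[1e-3, 1e6] rad/s, spanning the plant (5.4 rad/s) and blower (188 rad/s)
dynamics with wide margins. Poles strictly in the right half-plane or on
the imaginary axis away from the origin are outside the supported contour
and raise an error. Every Nyquist verdict is cross-checked against the
closed-loop characteristic roots; disagreement raises a diagnostic error
rather than returning either verdict.

The blower-sensitivity sweep runs the closed loop per grid point and
reports metrics plus the frozen-gain pole verdict; divergence is flagged in
the row, never raised.

## What the tests show — and do not show

Tests verify the package against published desk-scale quantities (plant
and blower transfer-function coefficients, the assembled closed-loop
coefficients, the stability verdict), against independent oracles
(symbolic circuit elimination, dense-grid centroids, linear step
responses, hand convolutions), and against structural invariants
(partition of unity, reflection symmetry, elitism monotonicity,
determinism). The published step-metric table for the fuzzy controller
depends on unpublished membership breakpoints, solver settings and
error-rate scaling, and is deliberately **not** asserted; the closed-loop
property checks above are the substitute. Simulation-based tests use
shortened horizons (0.1–2 s) and steps of 1e-5–5e-4 s, chosen to resolve
the blower mode while keeping the suite fast; they exercise the same code
paths as full-length runs.

The synthetic scenarios emulate an ideal linear, passive, sedated patient:
no spontaneous breathing effort, no nonlinear (flow-dependent) resistance,
no hose compliance, and sensor-side disturbances only. Results on these
scenarios bound what can be claimed about real ventilation hardware.
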