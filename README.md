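# ventcontrol

Pressure-control toolkit for a blower-driven, patient-hose mechanical
ventilator operating in pressure-controlled ventilation (PCV) mode. It is
aimed at control engineers and researchers who want a self-contained,
scriptable model of the pressure loop: the respiratory-mechanics plant, a
fuzzy-scheduled PID controller, a metaheuristic that learns the fuzzy rule
base, and a stability analysis of the resulting loop.

## The model

**Plant.** The pneumatic path is the standard RC analogue of passive
respiratory mechanics. The blower outlet pressure `p_out` crosses the hose
resistance `r_hose` to the airway node (`p_airway`), where flow splits
between the exhalation leak `r_leak` and the airway resistance `r_lungs`
charging the lung compliance `c_lungs`:

    dp_lungs/dt = (p_airway − p_lungs) / (r_lungs · c_lungs)

With the reference parameters (`r_lungs` = 5 mbar·s/l, `c_lungs` = 20
ml/mbar, `r_hose` = 4.5 mbar·s/l, `r_leak` = 60 mbar·s/l) this gives the
one-state transfer function

    G(s) = (0.5063 s + 5.063) / (s + 5.443)

from blower outlet to airway pressure. The blower itself is a
critically-damped second-order actuator, `ω_n²/(s² + 2ζω_n s + ω_n²)` with
`ω_n = 2π·30` rad/s and `ζ = 1`.

**Controller.** A PID `C(s) = k_p + k_i/s + k_d s` whose three gains are
scheduled on-line by a Mamdani fuzzy inference system. The FIS inputs are
the tracking error `e` and its rate `ce`, each covered by seven membership
functions (NL, NM, NS, ZE, PS, PM, PB); each output gain therefore has a
7×7 rule grid, 147 integer consequents in total. Inference is min/min/max
with rule weight 1 and exact centroid defuzzification.

**Rule-base learning.** A reshaped class-topper optimizer (RCTO) searches
over the 147 integer consequents: the population is split into sections,
each non-topper member receives a contiguous block of rules from the class
topper and another from its section topper each iteration (elitism keeps
the class topper), and fitness is the closed-loop ITAE `∫ t·|e| dt` of a
noise-free tracking scenario. The classical continuous class-topper update
is also provided for real-valued problems.

**Stability.** The scheduled loop frozen at one gain triple is analyzed two
independent ways — Nyquist encirclements of (−1, j0) with the integrator
pole handled analytically, and closed-loop characteristic roots — and the
two verdicts are cross-checked.

## Worked example

Simulate the unit-pulse tracking scenario (0 → 1 mbar, period 2 s) with the
optimal fixed gains:

```sh
$ cat pulse.yaml
controller: {type: pid, kp: 0.289085, ki: 62.8799, kd: 0.000480583}
scenario:
  pattern: {kind: pulse, low: 0.0, high: 1.0, period: 2.0}
  duration: 4.0
  dt: 1.0e-4

$ ventcontrol simulate --config pulse.yaml --out run1
simulate: ITAE 0.0390471 mbar*s^2 -> run1

$ cat run1/metrics.json
{
  "itae": 0.039047135726530666,
  "mp": 0.06945622428420761,
  "step_edge": 1.0,
  "tp": 0.1149,
  "ts": 0.24819999999999998
}
```

The loop overshoots the 1 mbar step by 6.9 %, peaks 0.115 s after the
rising edge and settles into the 2 % band 0.248 s after it; the
time-weighted absolute error over the plateau is 0.039 mbar·s².

```sh
$ ventcontrol stability --gains optimal --out stab
stable
```

confirms zero Nyquist encirclements and all closed-loop poles
(−229.5, −115.1, −33.9, −12.6 rad/s) in the left half-plane.

The same objects are available from Python:

```python
>>> import ventcontrol as vc
>>> plant = vc.build_hose_patient_ss(vc.LungHoseParams())
>>> vc.ss_to_tf(plant, "p_airway").num
array([0.50632911, 5.06329114])
>>> vc.gains_from_fis(vc.FISConfig(), e=0.5, ce=0.0)
PIDGains(kp=1.3333333333333324, ki=166.66666666666654, kd=0.013333333333333324)
```

Other CLI subcommands: `optimize-rules` (run the RCTO over a scenario),
`sweep` (blower-parameter sensitivity table), `fixtures` (write the
reference parameter/gain/scenario files).

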