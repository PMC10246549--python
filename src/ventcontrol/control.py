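"""Closed-loop pressure-tracking simulation and step-response metrics.

The loop follows the usual pressure-controlled ventilation structure: a
breathing-pattern reference r(t) (square pulse, or a PEEP/PIP cycle with
separate inspiration and expiration times) is compared with the *measured*
airway pressure; the error drives a discrete PID whose gains are either
fixed or scheduled on-line by the fuzzy inference system; the PID output is
the blower command, and the blower + hose-patient plant are integrated with
a fixed-step 4th-order Runge-Kutta scheme under zero-order-hold input.

Disturbances are injected additively on the measured airway pressure
(sensor side), scaled by the breathing-pattern step height; measurement
noise is zero-mean Gaussian with standard deviation proportional to the
current reference amplitude, seeded and therefore bit-reproducible.

Performance is summarized by the classical step metrics — fractional peak
overshoot Mp, peak time tp, settling time ts (2 % band by default) — and by
the time-weighted absolute error integral ITAE = int t |e| dt, which is
also the fitness the rule-base optimizer minimizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

from .fuzzy import FISConfig, infer_and_defuzzify
from .plant import StateSpaceModel, TransferFunction

__all__ = [
    "PIDGains",
    "BreathingPattern",
    "ScenarioConfig",
    "SimResult",
    "PerformanceMetrics",
    "SimulationDivergedError",
    "MetricDomainError",
    "reference_signal",
    "simulate_closed_loop",
    "compute_metrics",
]


class SimulationDivergedError(RuntimeError):
    """The closed-loop state became non-finite (instability overflow)."""

    def __init__(self, time: float):
        super().__init__(f"simulation diverged at t = {time:.6g} s")
        self.time = time


class MetricDomainError(ValueError):
    """Metrics requested on an empty or degenerate window."""


@dataclass(frozen=True)
class PIDGains:
    """PID gains: kp (dimensionless), ki (1/s), kd (s); all nonnegative."""

    kp: float
    ki: float
    kd: float

    def __post_init__(self) -> None:
        for name in ("kp", "ki", "kd"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0.0):
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")


@dataclass(frozen=True)
class BreathingPattern:
    """Reference pressure profile.

    kind='pulse': 50 %-duty square wave, `low` for the first half period
    then `high` (the unit pulse of the tracking experiments: 0 -> 1 with
    period 2 s).  kind='peep_pip': `high` (PIP) held for t_insp seconds then
    `low` (PEEP) for t_exp seconds, repeating.
    """

    kind: str
    low: float = 0.0
    high: float = 1.0
    t_insp: Optional[float] = None
    t_exp: Optional[float] = None
    period: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("pulse", "peep_pip"):
            raise ValueError(f"unknown pattern kind {self.kind!r}")
        if not self.high > self.low >= 0.0:
            raise ValueError("pattern requires high > low >= 0")
        if self.kind == "pulse":
            if self.period is None or self.period <= 0:
                raise ValueError("pulse pattern requires period > 0")
        else:
            if not (self.t_insp and self.t_insp > 0 and self.t_exp and self.t_exp > 0):
                raise ValueError("peep_pip pattern requires t_insp, t_exp > 0")
            object.__setattr__(self, "period", self.t_insp + self.t_exp)

    @property
    def height(self) -> float:
        return self.high - self.low


@dataclass(frozen=True)
class Disturbance:
    """Additive sensor-side pulse: magnitude is a fraction of the step height."""

    magnitude: float
    start: float
    duration: float


@dataclass(frozen=True)
class Noise:
    """Measurement noise: std is a fraction of the current reference amplitude."""

    std: float
    seed: int


@dataclass
class ScenarioConfig:
    """Everything one closed-loop run needs besides the physical models."""

    pattern: BreathingPattern
    duration: float
    dt: float = 1e-4
    disturbance: Optional[Disturbance] = None
    noise: Optional[Noise] = None
    controller: Union[PIDGains, FISConfig] = None  # type: ignore[assignment]
    deriv_filter_n: Optional[float] = 100.0  # rad/s; None = unfiltered derivative
    saturation: Optional[tuple[float, float]] = None  # blower command limits, mbar

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.duration < self.pattern.period:
            raise ValueError("duration must cover at least one pattern period")
        if self.controller is None:
            raise ValueError("a controller (PIDGains or FISConfig) is required")


@dataclass
class SimResult:
    """Closed-loop trajectories on a common fixed-step time grid."""

    t: np.ndarray
    r: np.ndarray
    p_airway: np.ndarray
    p_lungs: np.ndarray
    u: np.ndarray
    kp: np.ndarray
    ki: np.ndarray
    kd: np.ndarray
    e: np.ndarray
    ce: np.ndarray
    y_meas: np.ndarray
    fallback_count: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t, "r": self.r, "p_airway": self.p_airway,
                "p_lungs": self.p_lungs, "u": self.u, "kp": self.kp,
                "ki": self.ki, "kd": self.kd, "e": self.e, "ce": self.ce,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SimResult":
        df = pd.read_csv(path)
        arr = {c: df[c].to_numpy() for c in df.columns}
        return cls(
            t=arr["t"], r=arr["r"], p_airway=arr["p_airway"],
            p_lungs=arr["p_lungs"], u=arr["u"], kp=arr["kp"], ki=arr["ki"],
            kd=arr["kd"], e=arr["e"], ce=arr["ce"], y_meas=arr["p_airway"],
        )


@dataclass(frozen=True)
class PerformanceMetrics:
    """Step metrics: Mp (fraction of step height), tp (s), ts (s), ITAE (mbar*s^2)."""

    mp: float
    tp: float
    ts: float
    itae: float

    def as_dict(self) -> dict:
        return {"mp": self.mp, "tp": self.tp, "ts": self.ts, "itae": self.itae}


def reference_signal(pattern: BreathingPattern, t):
    """Reference pressure at time(s) t >= 0; periodic by construction."""
    t = np.asarray(t, dtype=float)
    phase = np.mod(t, pattern.period)
    if pattern.kind == "pulse":
        out = np.where(phase < pattern.period / 2.0, pattern.low, pattern.high)
    else:
        out = np.where(phase < pattern.t_insp, pattern.high, pattern.low)
    return out if out.ndim else float(out)


def _rk4_zoh(a: np.ndarray, b: np.ndarray, dt: float):
    """One-step RK4 transition matrices for x' = Ax + Bu with u held constant:
    x+ = Phi x + Gamma u."""
    n = a.shape[0]
    m = dt * a
    m2 = m @ m
    m3 = m2 @ m
    phi = np.eye(n) + m + m2 / 2.0 + m3 / 6.0 + m3 @ m / 24.0
    gamma = dt * (np.eye(n) + m / 2.0 + m2 / 6.0 + m3 / 24.0) @ b
    return phi, gamma


def _combined_system(plant: StateSpaceModel, blower: TransferFunction):
    """Stack blower (command -> p_out) in front of the hose-patient plant.

    Returns A, B, output rows for p_airway and p_out, and the index of the
    lung-pressure state.
    """
    from scipy.signal import tf2ss

    ab, bb, cb, db = tf2ss(blower.num, blower.den)
    if db.size and np.any(db != 0.0):
        raise ValueError("blower model must be strictly proper")
    nb = ab.shape[0]
    idx_air = plant.output_index("p_airway")
    ap = plant.A
    bp = plant.B
    cp_air = plant.C[idx_air : idx_air + 1, :]
    dp_air = plant.D[idx_air : idx_air + 1, :]
    npl = ap.shape[0]

    n = nb + npl
    a = np.zeros((n, n))
    a[:nb, :nb] = ab
    a[nb:, :nb] = bp @ cb
    a[nb:, nb:] = ap
    b = np.zeros((n, 1))
    b[:nb] = bb
    c_air = np.zeros(n)
    c_air[:nb] = (dp_air @ cb).ravel()
    c_air[nb:] = cp_air.ravel()
    c_pout = np.zeros(n)
    c_pout[:nb] = cb.ravel()
    return a, b, c_air, c_pout, nb


def simulate_closed_loop(
    plant: StateSpaceModel,
    blower: TransferFunction,
    scenario: ScenarioConfig,
) -> SimResult:
    """Fixed-step closed-loop simulation of the pressure-tracking loop.

    At every step: the measured airway pressure (true output plus optional
    disturbance pulse and seeded noise) is subtracted from the reference to
    give the error e; ce is its backward difference divided by dt; gains are
    either the fixed PIDGains or scheduled by the FIS; the PID (trapezoidal
    integral, optionally low-pass-filtered backward-difference derivative,
    optional saturation with clamping anti-windup) commands the blower; the
    combined linear blower+plant state advances by one RK4 step under
    zero-order hold.

    Raises
    ------
    SimulationDivergedError
        If any state or control value becomes non-finite, carrying the time
        of divergence.
    """
    dt = scenario.dt
    n_steps = int(round(scenario.duration / dt)) + 1
    t = np.arange(n_steps) * dt
    pat = scenario.pattern
    r = np.asarray(reference_signal(pat, t), dtype=float)

    a, b, c_air, c_pout, _ = _combined_system(plant, blower)
    phi, gamma = _rk4_zoh(a, b, dt)
    gamma = gamma.ravel()
    n_lung = a.shape[0] - 1  # lung pressure is the last state

    dist = scenario.disturbance
    noise_vals = np.zeros(n_steps)
    if scenario.noise is not None:
        rng = np.random.default_rng(scenario.noise.seed)
        noise_vals = rng.standard_normal(n_steps) * (scenario.noise.std * np.abs(r))

    fis = scenario.controller if isinstance(scenario.controller, FISConfig) else None
    fixed = scenario.controller if isinstance(scenario.controller, PIDGains) else None

    tf_d = None if scenario.deriv_filter_n is None else 1.0 / scenario.deriv_filter_n
    sat = scenario.saturation

    x = np.zeros(a.shape[0])
    integ = 0.0
    dfilt = 0.0
    # the loop starts at rest with zero pre-start error, so a reference that
    # steps at t=0 produces the same derivative kick (a dt-wide pulse of
    # height e/dt) that the ideal continuous PID would inject as kd*delta
    e_prev = 0.0
    fallback_count = 0

    tr = {k: np.empty(n_steps) for k in
          ("p_airway", "p_lungs", "u", "kp", "ki", "kd", "e", "ce", "y_meas")}

    for k in range(n_steps):
        tk = t[k]
        y_true = float(c_air @ x)
        y_meas = y_true + noise_vals[k]
        if dist is not None and dist.start <= tk < dist.start + dist.duration:
            y_meas += dist.magnitude * pat.height
        e = r[k] - y_meas
        de = 0.0 if e_prev is None else (e - e_prev) / dt

        if fis is not None:
            res = infer_and_defuzzify(fis, e * fis.e_gain, de * fis.ce_gain)
            fallback_count += sum(res.fallback)
            gains = []
            for name, y in zip(("kp", "ki", "kd"), (res.kp, res.ki, res.kd)):
                lo_u, hi_u = fis.out_vars[name].universe
                lo_g, hi_g = fis.gain_ranges[name]
                gains.append(lo_g + (y - lo_u) / (hi_u - lo_u) * (hi_g - lo_g))
            kp, ki, kd = gains
        else:
            kp, ki, kd = fixed.kp, fixed.ki, fixed.kd

        # trapezoidal integral, backward-difference derivative (optionally
        # first-order filtered so the derivative survives measurement noise)
        integ_cand = integ + (0.0 if e_prev is None else 0.5 * dt * (e + e_prev))
        if tf_d is None:
            dfilt = de
        else:
            dfilt = dfilt + (dt / (tf_d + dt)) * (de - dfilt)
        with np.errstate(over="ignore", invalid="ignore"):
            u = kp * e + ki * integ_cand + kd * dfilt
        if sat is not None and not sat[0] <= u <= sat[1]:
            # clamping anti-windup: freeze the integral while saturated
            u = min(max(u, sat[0]), sat[1])
        else:
            integ = integ_cand

        if not (np.isfinite(u) and np.all(np.isfinite(x))):
            raise SimulationDivergedError(tk)

        tr["p_airway"][k] = y_true
        tr["p_lungs"][k] = x[n_lung]
        tr["u"][k] = u
        tr["kp"][k], tr["ki"][k], tr["kd"][k] = kp, ki, kd
        tr["e"][k] = e
        tr["ce"][k] = de
        tr["y_meas"][k] = y_meas
        e_prev = e

        x = phi @ x + gamma * u

    if not np.all(np.isfinite(tr["p_airway"])):
        raise SimulationDivergedError(t[-1])

    return SimResult(
        t=t, r=r, p_airway=tr["p_airway"], p_lungs=tr["p_lungs"], u=tr["u"],
        kp=tr["kp"], ki=tr["ki"], kd=tr["kd"], e=tr["e"], ce=tr["ce"],
        y_meas=tr["y_meas"], fallback_count=fallback_count,
    )


def compute_metrics(
    result: SimResult,
    step_edge: float,
    settling_band: float = 0.02,
) -> PerformanceMetrics:
    """Step metrics over the window after `step_edge` plus whole-record ITAE.

    Mp is the fractional overshoot of the true airway pressure beyond the
    post-edge reference, relative to the step height and floored at zero;
    tp the time of the overall post-edge peak; ts the first time after
    which |p_airway - r| stays inside the settling band (a fraction of the
    step height, 2 % by default); ITAE integrates t*|r - p_airway| by the
    trapezoid rule over the whole record with t measured from the record
    start.
    """
    t = result.t
    if not t[0] <= step_edge <= t[-1]:
        raise MetricDomainError(f"step_edge {step_edge} outside the time grid")
    i0 = int(np.searchsorted(t, step_edge))
    if i0 >= len(t):
        raise MetricDomainError("empty post-edge window")
    r_hi = result.r[i0]
    r_lo = result.r[i0 - 1] if i0 > 0 else 0.0
    height = r_hi - r_lo
    if height <= 0:
        raise MetricDomainError("step height at step_edge is not positive")

    y = result.p_airway[i0:]
    ipk = int(np.argmax(y))
    mp = max(0.0, (float(y[ipk]) - r_hi) / height)
    tp = float(t[i0 + ipk] - step_edge)

    err = np.abs(y - result.r[i0:])
    outside = err > settling_band * height
    if not np.any(outside):
        ts = 0.0
    else:
        last = int(np.max(np.nonzero(outside)[0]))
        if last == len(y) - 1:
            ts = float(t[-1] - step_edge)  # never settles within the record
        else:
            ts = float(t[i0 + last + 1] - step_edge)

    e_true = result.r - result.p_airway
    itae = float(np.trapezoid(t * np.abs(e_true), t))
    return PerformanceMetrics(mp=mp, tp=tp, ts=ts, itae=itae)
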