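"""Nyquist and pole-location stability analysis of the frozen-gain loop.

The gain-scheduled controller is linearized by freezing the PID gains at
one operating triple; the open loop is then L(s) = G_PID(s) G_blower(s)
G(s) with the PID in the standard (kd s^2 + kp s + ki)/s form, i.e. always
one pole at the origin.  Closed-loop stability of the unity-negative-
feedback loop is decided two independent ways and cross-checked: by
counting net clockwise encirclements of the critical point (-1, j0) along
the right-indented Nyquist contour, and by the sign of the real parts of
the closed-loop characteristic roots.  For an open loop whose only
closed-right-half-plane poles are at the origin, stability is exactly zero
encirclements.

The origin pole is handled analytically: the indentation semicircle of a
type-n0 system contributes -pi*n0 to the winding of 1 + L, and the two
frequency half-axes contribute twice the unwrapped phase change measured on
the positive half, so no numerically delicate near-zero evaluation is
needed beyond the configured low-frequency end of the grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .control import (
    MetricDomainError,
    PIDGains,
    ScenarioConfig,
    SimulationDivergedError,
    compute_metrics,
    simulate_closed_loop,
)
from .fuzzy import FISConfig, infer_and_defuzzify
from .plant import BlowerParams, StateSpaceModel, TransferFunction, blower_tf, series_tf


class DegenerateControllerError(ValueError):
    """All three PID gains are zero: no controller."""


class UnsupportedContourError(ValueError):
    """Open-loop poles on the imaginary axis away from the origin (or in the
    open right half-plane) are outside the supported Nyquist contour."""


class StabilityDiagnosticError(RuntimeError):
    """Nyquist and pole verdicts disagree — contour resolution artifact."""


@dataclass
class NyquistResult:
    omega: np.ndarray  # rad/s, positive half-axis
    response: np.ndarray  # complex open-loop samples L(j omega)
    encirclements: int  # net clockwise encirclements of (-1, j0)
    stable: bool


def pid_tf(gains: PIDGains) -> TransferFunction:
    """G_PID(s) = (kd s^2 + kp s + ki) / s, never cancelled."""
    if gains.kp == 0.0 and gains.ki == 0.0 and gains.kd == 0.0:
        raise DegenerateControllerError("all PID gains are zero")
    return TransferFunction([gains.kd, gains.kp, gains.ki], [1.0, 0.0])


def closed_loop_tf(
    pid: TransferFunction, blower: TransferFunction, plant: TransferFunction
) -> TransferFunction:
    """Unity-negative-feedback closed loop L/(1+L) with L = pid*blower*plant,
    returned with monic denominator."""
    loop = series_tf(series_tf(pid, blower), plant)
    if not loop.proper:
        raise ValueError("open loop must be proper (deg num <= deg den)")
    num = loop.num
    den = np.polyadd(loop.den, num)
    if len(den) < len(loop.den):
        raise ValueError("degenerate feedback interconnection")
    return TransferFunction(num, den).monic()


def poles(tf: TransferFunction) -> np.ndarray:
    """All denominator roots; the system is stable iff all real parts < 0."""
    return np.roots(tf.den)


def _classify_open_loop_poles(den: np.ndarray) -> int:
    """Number of origin poles; raises for unsupported pole locations."""
    rts = np.roots(den)
    if rts.size == 0:
        return 0
    scale = max(1.0, float(np.max(np.abs(rts))))
    tol = 1e-7 * scale
    n_origin = int(np.sum(np.abs(rts) < tol))
    others = rts[np.abs(rts) >= tol]
    if np.any(others.real > tol):
        raise UnsupportedContourError("open-loop pole in the right half-plane")
    if np.any(np.abs(others.real) <= tol):
        raise UnsupportedContourError("open-loop pole on the imaginary axis")
    return n_origin


def nyquist_check(
    open_loop: TransferFunction,
    freq_range: tuple[float, float] = (1e-3, 1e6),
    n_points: int = 2000,
    cross_check: bool = True,
) -> NyquistResult:
    """Count net clockwise encirclements of (-1, j0) by L(j omega).

    The winding of 1 + L over the full right-indented contour is assembled
    from the unwrapped phase change over the positive half-axis (counted
    twice, by conjugate symmetry) plus the analytic -pi per origin pole from
    the indentation arc.  The verdict (stable iff zero encirclements, valid
    because the open loop has no other closed-RHP poles) is cross-checked
    against the closed-loop characteristic roots unless disabled;
    disagreement raises :class:`StabilityDiagnosticError`.
    """
    n_origin = _classify_open_loop_poles(open_loop.den)
    omega = np.logspace(np.log10(freq_range[0]), np.log10(freq_range[1]), n_points)
    resp = open_loop(1j * omega)
    phase = np.unwrap(np.angle(1.0 + resp))
    delta = phase[-1] - phase[0]
    winding_ccw = (2.0 * delta - np.pi * n_origin) / (2.0 * np.pi)
    enc_cw = -int(np.round(winding_ccw))
    stable = enc_cw == 0

    if cross_check:
        char = np.polyadd(open_loop.den, open_loop.num)
        rts = np.roots(char)
        scale = max(1.0, float(np.max(np.abs(rts)))) if rts.size else 1.0
        pole_stable = bool(np.all(rts.real < -1e-9 * scale))
        if pole_stable != stable:
            raise StabilityDiagnosticError(
                f"Nyquist verdict ({stable}, {enc_cw} encirclements) contradicts "
                f"pole verdict ({pole_stable}); refine the frequency grid"
            )
    return NyquistResult(omega=omega, response=resp, encirclements=enc_cw, stable=stable)


def frozen_gains(controller: Union[PIDGains, FISConfig], e: float = 0.0, ce: float = 0.0) -> PIDGains:
    """Fixed gains, or the FIS schedule frozen at one (e, ce) operating point."""
    if isinstance(controller, PIDGains):
        return controller
    res = infer_and_defuzzify(controller, e * controller.e_gain, ce * controller.ce_gain)
    out = {}
    for name, y in zip(("kp", "ki", "kd"), (res.kp, res.ki, res.kd)):
        lo_u, hi_u = controller.out_vars[name].universe
        lo_g, hi_g = controller.gain_ranges[name]
        out[name] = lo_g + (y - lo_u) / (hi_u - lo_u) * (hi_g - lo_g)
    return PIDGains(**out)


def sensitivity_sweep(
    controller: Union[PIDGains, FISConfig],
    plant: StateSpaceModel,
    plant_tf: TransferFunction,
    blower_grid: Sequence[BlowerParams],
    scenario: ScenarioConfig,
    step_edge: float = 0.0,
    settling_band: float = 0.02,
) -> pd.DataFrame:
    """Closed-loop metrics and stability verdicts across blower parameters.

    One row per grid point: omega_n, zeta, the step metrics, the pole-check
    verdict of the frozen-gain loop, and a `diverged` flag (divergence is
    reported in the row, never raised).
    """
    rows = []
    gains = frozen_gains(controller)
    for bp in blower_grid:
        btf = blower_tf(bp)
        cl = closed_loop_tf(pid_tf(gains), btf, plant_tf)
        rts = poles(cl)
        scale = max(1.0, float(np.max(np.abs(rts))))
        stable = bool(np.all(rts.real < -1e-9 * scale))
        scn = ScenarioConfig(
            pattern=scenario.pattern, duration=scenario.duration, dt=scenario.dt,
            disturbance=scenario.disturbance, noise=scenario.noise,
            controller=controller, deriv_filter_n=scenario.deriv_filter_n,
            saturation=scenario.saturation,
        )
        row = {"omega_n": bp.omega_n, "zeta": bp.zeta, "stable": stable,
               "diverged": False, "mp": np.nan, "tp": np.nan, "ts": np.nan,
               "itae": np.nan}
        try:
            result = simulate_closed_loop(plant, btf, scn)
            m = compute_metrics(result, step_edge, settling_band)
            row.update(m.as_dict())
        except (SimulationDivergedError, MetricDomainError):
            row["diverged"] = True
        rows.append(row)
    return pd.DataFrame(rows)
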