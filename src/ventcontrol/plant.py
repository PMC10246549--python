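"""Linear models of the blower-driven patient-hose ventilation circuit.

The pneumatic path from blower outlet to patient lung is the classical RC
analogue of passive respiratory mechanics.  Air leaves the blower at pressure
``p_out``, crosses the hose resistance ``r_hose`` and reaches the airway node
at pressure ``p_airway``; from there part of the flow escapes through the
exhalation leak (``r_leak``) and the rest enters the lung through the airway
resistance ``r_lungs``, charging the lung compliance ``c_lungs`` whose
"voltage" is the lung pressure ``p_lungs``.  Conservation of flow at the
airway node gives a single-state linear system

    d(p_lungs)/dt = (p_airway - p_lungs) / (r_lungs * c_lungs)

with ``p_airway`` the resistive divider between ``p_lungs`` and ``p_out``.
Pressures are in mbar, flows in l/s, time in s; the compliance is stored in
ml/mbar as it is usually quoted clinically and converted to l/mbar
internally, so the lung filling time constant is
``r_lungs * c_lungs / 1000`` seconds (0.1 s at the default parameters).

The blower itself is a critically-damped second-order actuator from control
signal to outlet pressure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal


class ParameterDomainError(ValueError):
    """A physical parameter is outside its admissible domain."""


@dataclass(frozen=True)
class LungHoseParams:
    """Physical parameters of the hose-patient pneumatic circuit.

    Parameters
    ----------
    r_lungs : float
        Airway/lung resistance, mbar*s/l.
    c_lungs : float
        Lung compliance, ml/mbar (converted to l/mbar internally).
    r_hose : float
        Hose resistance between blower and airway node, mbar*s/l.
    r_leak : float
        Exhalation leak resistance at the airway node, mbar*s/l.
    """

    r_lungs: float = 5.0
    c_lungs: float = 20.0
    r_hose: float = 4.5
    r_leak: float = 60.0

    def __post_init__(self) -> None:
        for name in ("r_lungs", "c_lungs", "r_hose", "r_leak"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ParameterDomainError(
                    f"{name} must be strictly positive and finite, got {v!r}"
                )

    @property
    def c_lungs_l(self) -> float:
        """Lung compliance in l/mbar."""
        return self.c_lungs / 1000.0

    @property
    def tau_lungs(self) -> float:
        """Lung filling time constant r_lungs*c_lungs, seconds."""
        return self.r_lungs * self.c_lungs_l


@dataclass(frozen=True)
class BlowerParams:
    """Second-order blower actuator parameters.

    omega_n is the natural frequency in rad/s (default 2*pi*30, i.e. a 30 Hz
    actuator) and zeta the dimensionless damping ratio (default 1, critical
    damping: a double real pole at -omega_n).
    """

    omega_n: float = 2.0 * math.pi * 30.0
    zeta: float = 1.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.omega_n) and self.omega_n > 0):
            raise ParameterDomainError(f"omega_n must be > 0, got {self.omega_n!r}")
        if not (np.isfinite(self.zeta) and self.zeta > 0):
            raise ParameterDomainError(f"zeta must be > 0, got {self.zeta!r}")


@dataclass
class StateSpaceModel:
    """A real LTI system x' = Ax + Bu, y = Cx + Du with named signals."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray
    state_names: tuple[str, ...] = ()
    input_names: tuple[str, ...] = ()
    output_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.B = np.atleast_2d(np.asarray(self.B, dtype=float))
        self.C = np.atleast_2d(np.asarray(self.C, dtype=float))
        self.D = np.atleast_2d(np.asarray(self.D, dtype=float))
        n = self.A.shape[0]
        if self.A.shape != (n, n):
            raise ValueError(f"A must be square, got {self.A.shape}")
        m = self.B.shape[1]
        p = self.C.shape[0]
        if self.B.shape != (n, m):
            raise ValueError(f"B shape {self.B.shape} inconsistent with n={n}")
        if self.C.shape != (p, n):
            raise ValueError(f"C shape {self.C.shape} inconsistent with n={n}")
        if self.D.shape != (p, m):
            raise ValueError(f"D shape {self.D.shape} inconsistent with (p={p}, m={m})")
        if not self.state_names:
            self.state_names = tuple(f"x{i}" for i in range(n))
        if not self.input_names:
            self.input_names = tuple(f"u{i}" for i in range(m))
        if not self.output_names:
            self.output_names = tuple(f"y{i}" for i in range(p))

    @property
    def n_states(self) -> int:
        return self.A.shape[0]

    def output_index(self, name: str) -> int:
        try:
            return self.output_names.index(name)
        except ValueError:
            raise KeyError(
                f"unknown output {name!r}; available: {self.output_names}"
            ) from None

    def to_dict(self) -> dict:
        return {
            "A": self.A.tolist(),
            "B": self.B.tolist(),
            "C": self.C.tolist(),
            "D": self.D.tolist(),
            "state_names": list(self.state_names),
            "input_names": list(self.input_names),
            "output_names": list(self.output_names),
        }


@dataclass
class TransferFunction:
    """Rational transfer function with coefficients in descending powers of s.

    Coefficient arrays are kept exactly as computed: no pole-zero
    cancellation is ever performed, so e.g. a pure proportional "PID"
    deliberately keeps its s/s form.
    """

    num: np.ndarray
    den: np.ndarray

    def __post_init__(self) -> None:
        self.num = np.atleast_1d(np.asarray(self.num, dtype=float))
        self.den = np.atleast_1d(np.asarray(self.den, dtype=float))
        if self.den[0] == 0.0:
            raise ValueError("leading denominator coefficient must be nonzero")

    @property
    def proper(self) -> bool:
        """deg num <= deg den (the PID factor alone is deliberately improper)."""
        return len(self.num) <= len(self.den)

    def __call__(self, s):
        """Evaluate the transfer function at (complex, possibly array) s."""
        s = np.asarray(s)
        return np.polyval(self.num, s) / np.polyval(self.den, s)

    def monic(self) -> "TransferFunction":
        """Return an equivalent transfer function with monic denominator."""
        a0 = self.den[0]
        return TransferFunction(self.num / a0, self.den / a0)

    def dc_gain(self) -> float:
        return float(np.real(self(0.0)))

    def to_dict(self) -> dict:
        return {"num": self.num.tolist(), "den": self.den.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "TransferFunction":
        return cls(np.asarray(d["num"], float), np.asarray(d["den"], float))


def build_hose_patient_ss(params: LungHoseParams) -> StateSpaceModel:
    """Build the one-state hose-patient model.

    State: p_lungs (mbar).  Input: p_out (mbar, blower outlet pressure).
    Outputs, in order: p_airway (mbar) and q_patient (l/s).

    Parameters
    ----------
    params : LungHoseParams
        Circuit parameters; the compliance is converted from ml/mbar.

    Returns
    -------
    StateSpaceModel
    """
    gh = 1.0 / params.r_hose
    gl = 1.0 / params.r_lungs
    gk = 1.0 / params.r_leak
    s_tot = gh + gl + gk  # total airway-node conductance, l/(s*mbar)
    tau = params.tau_lungs

    a = -(gh + gk) / (tau * s_tot)
    b = gh / (tau * s_tot)
    c_airway = gl / s_tot
    d_airway = gh / s_tot
    c_qpat = -(gh + gk) / (params.r_lungs * s_tot)
    d_qpat = gh / (params.r_lungs * s_tot)

    return StateSpaceModel(
        A=[[a]],
        B=[[b]],
        C=[[c_airway], [c_qpat]],
        D=[[d_airway], [d_qpat]],
        state_names=("p_lungs",),
        input_names=("p_out",),
        output_names=("p_airway", "q_patient"),
    )


def ss_to_tf(model: StateSpaceModel, output_name: str) -> TransferFunction:
    """Convert one output of a single-input state-space model to a transfer
    function G(s) = C (sI - A)^-1 B + D with monic denominator."""
    if model.B.shape[1] != 1:
        raise ValueError("ss_to_tf requires a single-input model")
    idx = model.output_index(output_name)
    num, den = signal.ss2tf(
        model.A, model.B, model.C[idx : idx + 1, :], model.D[idx : idx + 1, :]
    )
    num = np.atleast_1d(num[0])
    # strip numerically-zero leading coefficients introduced by ss2tf padding
    scale = max(np.max(np.abs(num)), 1.0)
    k = 0
    while k < len(num) - 1 and abs(num[k]) < 1e-12 * scale:
        k += 1
    return TransferFunction(num[k:], den).monic()


def blower_tf(params: BlowerParams) -> TransferFunction:
    """Second-order blower model omega_n^2 / (s^2 + 2 zeta omega_n s + omega_n^2).

    Unit DC gain by construction: at rest the outlet pressure equals the
    commanded pressure.
    """
    wn = params.omega_n
    return TransferFunction([wn**2], [1.0, 2.0 * params.zeta * wn, wn**2])


def series_tf(a: TransferFunction, b: TransferFunction) -> TransferFunction:
    """Series (cascade) interconnection a*b by polynomial products.

    No pole-zero cancellation is performed; coefficient arrays are the raw
    convolutions of the operands'.
    """
    return TransferFunction(np.polymul(a.num, b.num), np.polymul(a.den, b.den))
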