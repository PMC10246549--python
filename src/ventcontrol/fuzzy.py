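"""Mamdani fuzzy inference for PID gain scheduling.

Two inputs — tracking error ``e`` and change in error ``ce``, both scaled
onto a normalized universe — drive three outputs, the normalized PID gains
``kp``, ``ki``, ``kd``.  Every variable carries seven membership functions
with the fixed linguistic ladder NL, NM, NS, ZE, PS, PM, PB (negative large
... positive big), so each output has a 7x7 rule grid (49 rules) and the
full controller is described by 147 integer consequents in {0..6}.

Inference is classical Mamdani: AND = min, implication = min (clipping the
consequent set at the rule firing strength), aggregation = max, rule weight
1.  Defuzzification is the area-barycenter (centroid) of the aggregated
output set, computed *exactly*: the aggregate of clipped piecewise-linear
membership functions is itself piecewise linear, so the trapezoid rule over
the complete set of kink abscissae (membership breakpoints, clip-level
crossings, and pairwise intersections of linear pieces) integrates it with
no discretization error.  This keeps the defuzzified output independent of
any grid-resolution choice and directly checkable against brute-force dense
integration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

#: Linguistic labels in canonical order; index in this tuple is the integer
#: encoding of the consequent (NL=0 ... PB=6).
LABELS: tuple[str, ...] = ("NL", "NM", "NS", "ZE", "PS", "PM", "PB")

N_LABELS = len(LABELS)
N_RULES = N_LABELS * N_LABELS  # 49 rules per output
N_OUTPUTS = 3
N_VARIABLES = N_RULES * N_OUTPUTS  # 147 integer consequents overall


class RuleDomainError(ValueError):
    """A rule value lies outside the encodable domain [0, 7)."""


@dataclass(frozen=True)
class MembershipFunction:
    """Piecewise-linear membership function given by interpolation knots.

    ``xp``/``fp`` are the knot abscissae (non-decreasing) and membership
    values; evaluation is linear interpolation, constant beyond the end
    knots (so shoulder MFs saturate).  Triangles have knots (a, b, c) with
    values (0, 1, 0); trapezoids (a, b, c, d) with (0, 1, 1, 0); shoulders
    are encoded with a saturated end knot.
    """

    label: str
    xp: tuple[float, ...]
    fp: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.xp) != len(self.fp) or len(self.xp) < 2:
            raise ValueError("xp and fp must be equal-length, length >= 2")
        if any(b < a for a, b in zip(self.xp, self.xp[1:])):
            raise ValueError(f"breakpoints must be non-decreasing: {self.xp}")
        if any(not (0.0 <= v <= 1.0) for v in self.fp):
            raise ValueError("membership values must lie in [0, 1]")
        if max(self.fp) != 1.0:
            raise ValueError("apex membership must equal 1")

    @property
    def shape(self) -> str:
        return "triangular" if len(self.xp) == 3 else "trapezoidal"

    def __call__(self, x):
        return np.interp(x, self.xp, self.fp)

    @classmethod
    def triangular(cls, label: str, a: float, b: float, c: float) -> "MembershipFunction":
        return cls(label, (a, b, c), (0.0, 1.0, 0.0))

    @classmethod
    def trapezoidal(
        cls, label: str, a: float, b: float, c: float, d: float
    ) -> "MembershipFunction":
        return cls(label, (a, b, c, d), (0.0, 1.0, 1.0, 0.0))

    @classmethod
    def left_shoulder(cls, label: str, top: float, foot: float) -> "MembershipFunction":
        """Saturated at 1 for x <= top, linear down to 0 at foot."""
        return cls(label, (top, foot), (1.0, 0.0))

    @classmethod
    def right_shoulder(cls, label: str, foot: float, top: float) -> "MembershipFunction":
        """0 at foot, linear up to 1 at top, saturated beyond."""
        return cls(label, (foot, top), (0.0, 1.0))


@dataclass
class FuzzyVariable:
    """A named variable with a closed universe and exactly 7 MFs in NL..PB order."""

    name: str
    universe: tuple[float, float]
    mfs: tuple[MembershipFunction, ...]

    def __post_init__(self) -> None:
        lo, hi = self.universe
        if not lo < hi:
            raise ValueError(f"universe must satisfy lo < hi, got {self.universe}")
        if len(self.mfs) != N_LABELS:
            raise ValueError(f"expected {N_LABELS} membership functions")
        got = tuple(mf.label for mf in self.mfs)
        if got != LABELS:
            raise ValueError(f"MF labels must be {LABELS} in order, got {got}")
        # Completeness is advisory: the default partition always covers the
        # universe, but user-supplied geometry may leave gaps, which the
        # inference engine handles with the midpoint fallback.
        grid = np.linspace(lo, hi, 101)
        cover = np.max([mf(grid) for mf in self.mfs], axis=0)
        if np.any(cover <= 0.0):
            warnings.warn(
                f"membership functions of {self.name!r} do not cover the "
                "universe; inputs in the gap will fall back to the midpoint",
                stacklevel=2,
            )

    @classmethod
    def uniform(cls, name: str, lo: float, hi: float) -> "FuzzyVariable":
        """Default partition: 7 triangles with uniformly spaced apexes,
        half-overlap (feet at the neighbouring apexes) and saturated
        shoulders at both ends.  This is a partition of unity."""
        v = np.linspace(lo, hi, N_LABELS)
        mfs = [MembershipFunction.left_shoulder(LABELS[0], v[0], v[1])]
        for i in range(1, N_LABELS - 1):
            mfs.append(
                MembershipFunction.triangular(LABELS[i], v[i - 1], v[i], v[i + 1])
            )
        mfs.append(MembershipFunction.right_shoulder(LABELS[-1], v[-2], v[-1]))
        return cls(name, (lo, hi), tuple(mfs))


@dataclass
class RuleGrid:
    """7x7 integer consequent grid, rows indexed by the e label, columns by ce."""

    consequent: np.ndarray

    def __post_init__(self) -> None:
        self.consequent = np.asarray(self.consequent, dtype=int)
        if self.consequent.shape != (N_LABELS, N_LABELS):
            raise ValueError(f"rule grid must be 7x7, got {self.consequent.shape}")
        if self.consequent.min() < 0 or self.consequent.max() > 6:
            raise ValueError("rule entries must lie in {0..6}")

    def flatten(self) -> np.ndarray:
        """Row-major flattened 49-vector (the X_k vector of the optimizer)."""
        return self.consequent.ravel().copy()

    @classmethod
    def from_flat(cls, flat) -> "RuleGrid":
        flat = np.asarray(flat, dtype=int)
        if flat.shape != (N_RULES,):
            raise ValueError(f"expected a {N_RULES}-vector")
        return cls(flat.reshape(N_LABELS, N_LABELS))

    def copy(self) -> "RuleGrid":
        return RuleGrid(self.consequent.copy())


@dataclass
class RuleTriplet:
    """The full 147-gene rule base: one RuleGrid per scheduled gain."""

    kp: RuleGrid
    ki: RuleGrid
    kd: RuleGrid

    def flatten(self) -> np.ndarray:
        return np.concatenate([self.kp.flatten(), self.ki.flatten(), self.kd.flatten()])

    @classmethod
    def from_flat(cls, flat) -> "RuleTriplet":
        flat = np.asarray(flat, dtype=int)
        if flat.shape != (N_VARIABLES,):
            raise ValueError(f"expected a {N_VARIABLES}-vector")
        return cls(
            RuleGrid.from_flat(flat[:N_RULES]),
            RuleGrid.from_flat(flat[N_RULES : 2 * N_RULES]),
            RuleGrid.from_flat(flat[2 * N_RULES :]),
        )

    def copy(self) -> "RuleTriplet":
        return RuleTriplet(self.kp.copy(), self.ki.copy(), self.kd.copy())

    @property
    def grids(self) -> dict[str, RuleGrid]:
        return {"kp": self.kp, "ki": self.ki, "kd": self.kd}


def encode_rule_value(x: float) -> int:
    """Truncate a real in [0, 7) to its consequent integer (floor)."""
    if not (0.0 <= x < 7.0):
        raise RuleDomainError(f"rule value must lie in [0, 7), got {x!r}")
    return int(np.floor(x))


def decode_rules(grid: RuleGrid) -> np.ndarray:
    """Map a rule grid to its 7x7 array of linguistic labels (0<->NL ... 6<->PB)."""
    return np.asarray(LABELS, dtype=object)[grid.consequent]


def encode_labels(labels) -> RuleGrid:
    """Inverse of :func:`decode_rules`."""
    lut = {lab: i for i, lab in enumerate(LABELS)}
    arr = np.asarray(labels, dtype=object)
    return RuleGrid(np.vectorize(lut.__getitem__)(arr).astype(int))


def default_rules() -> RuleTriplet:
    """A generic monotone seed table: the consequent grows with e + ce.

    This is a neutral, symmetric starting rule base (consequent index
    floor((i + j + 1) / 2) for antecedent indices i, j); it is the package's
    own default, intended as a plausible seed for optimization rather than a
    transcription of any published table.
    """
    i, j = np.meshgrid(np.arange(7), np.arange(7), indexing="ij")
    g = RuleGrid(((i + j + 1) // 2).astype(int))
    return RuleTriplet(g.copy(), g.copy(), g.copy())


@dataclass
class FISConfig:
    """Complete configuration of the gain-scheduling FIS.

    ``e_gain``/``ce_gain`` scale physical error (mbar) and error rate
    (mbar/s) onto the input universes before fuzzification; out-of-universe
    values are clamped.  ``gain_ranges`` affinely map each normalized output
    universe onto a physical gain interval.
    """

    e: FuzzyVariable = field(default_factory=lambda: FuzzyVariable.uniform("e", -1.0, 1.0))
    ce: FuzzyVariable = field(default_factory=lambda: FuzzyVariable.uniform("ce", -1.0, 1.0))
    out_kp: FuzzyVariable = field(default_factory=lambda: FuzzyVariable.uniform("kp", 0.0, 1.0))
    out_ki: FuzzyVariable = field(default_factory=lambda: FuzzyVariable.uniform("ki", 0.0, 1.0))
    out_kd: FuzzyVariable = field(default_factory=lambda: FuzzyVariable.uniform("kd", 0.0, 1.0))
    rules: RuleTriplet = field(default_factory=default_rules)
    e_gain: float = 1.0
    ce_gain: float = 0.01
    gain_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"kp": (0.0, 2.0), "ki": (0.0, 250.0), "kd": (0.0, 0.02)}
    )

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.gain_ranges.items():
            if not (0.0 <= lo < hi):
                raise ValueError(f"gain range for {name} must have 0 <= lo < hi")

    @property
    def out_vars(self) -> dict[str, FuzzyVariable]:
        return {"kp": self.out_kp, "ki": self.out_ki, "kd": self.out_kd}

    def with_rules(self, rules: RuleTriplet) -> "FISConfig":
        return FISConfig(
            e=self.e, ce=self.ce, out_kp=self.out_kp, out_ki=self.out_ki,
            out_kd=self.out_kd, rules=rules, e_gain=self.e_gain,
            ce_gain=self.ce_gain, gain_ranges=dict(self.gain_ranges),
        )


class InferenceResult(NamedTuple):
    kp: float
    ki: float
    kd: float
    fallback: tuple[bool, bool, bool]


def fuzzify(var: FuzzyVariable, x: float) -> np.ndarray:
    """Membership degrees of x (clamped to the universe) in the 7 MFs."""
    lo, hi = var.universe
    xc = min(max(float(x), lo), hi)
    return np.array([mf(xc) for mf in var.mfs])


def _firing_weights(mu_e: np.ndarray, mu_ce: np.ndarray, grid: RuleGrid) -> np.ndarray:
    """Per-consequent-label activation: max over the 49 rules (AND = min)."""
    w_rules = np.minimum.outer(mu_e, mu_ce)
    w = np.zeros(N_LABELS)
    np.maximum.at(w, grid.consequent.ravel(), w_rules.ravel())
    return w


def _clipped_segments(mf: MembershipFunction, w: float, lo: float, hi: float):
    """Linear segments (x0, x1, y0, y1) of min(w, mf(x)) on [lo, hi]."""
    xs = [lo] + [x for x in mf.xp if lo < x < hi] + [hi]
    ys = [float(mf(x)) for x in xs]
    segs = []
    for (x0, y0), (x1, y1) in zip(zip(xs, ys), zip(xs[1:], ys[1:])):
        if x1 <= x0:
            continue
        if y0 <= w and y1 <= w:
            segs.append((x0, x1, y0, y1))
        elif y0 >= w and y1 >= w:
            segs.append((x0, x1, w, w))
        else:
            xc = x0 + (w - y0) * (x1 - x0) / (y1 - y0)
            if y0 < w:
                segs.append((x0, xc, y0, w))
                segs.append((xc, x1, w, w))
            else:
                segs.append((x0, xc, w, w))
                segs.append((xc, x1, w, y1))
    return segs


def defuzzify_centroid(
    var: FuzzyVariable, weights: np.ndarray
) -> tuple[float, bool]:
    """Exact area-barycenter of max_k min(w_k, mf_k(x)) over the universe.

    Returns (centroid, fallback_flag).  When no rule fires (all weights
    zero, possible only with incomplete user partitions) the universe
    midpoint is returned and flagged.
    """
    lo, hi = var.universe
    active = [(mf, float(w)) for mf, w in zip(var.mfs, weights) if w > 0.0]
    if not active:
        return 0.5 * (lo + hi), True

    seg_list = []
    mf_id = []
    for k, (mf, w) in enumerate(active):
        s = _clipped_segments(mf, w, lo, hi)
        seg_list.extend(s)
        mf_id.extend([k] * len(s))
    seg = np.asarray(seg_list, dtype=float)  # (n, 4): x0, x1, y0, y1
    mf_id = np.asarray(mf_id)
    keep = seg[:, 1] > seg[:, 0]  # clip crossings can sit exactly on a knot
    seg, mf_id = seg[keep], mf_id[keep]
    x0, x1, y0, y1 = seg.T
    slope = (y1 - y0) / (x1 - x0)
    icept = y0 - slope * x0

    # pairwise intersections of linear pieces from different MFs
    with np.errstate(divide="ignore", invalid="ignore"):
        xc = (icept[None, :] - icept[:, None]) / (slope[:, None] - slope[None, :])
    left = np.maximum(x0[:, None], x0[None, :])
    right = np.minimum(x1[:, None], x1[None, :])
    valid = (
        np.isfinite(xc)
        & (mf_id[:, None] != mf_id[None, :])
        & (xc > left)
        & (xc < right)
    )
    crossings = xc[valid]

    knots = np.unique(
        np.clip(np.concatenate([x0, x1, crossings, [lo, hi]]), lo, hi)
    )
    vals = np.max(
        [np.minimum(w, mf(knots)) for mf, w in active], axis=0
    )
    # A(x) is linear on each knot interval, so the area is the trapezoid sum
    # and the first moment (piecewise quadratic integrand) has a closed form.
    xa, xb = knots[:-1], knots[1:]
    va, vb = vals[:-1], vals[1:]
    h = xb - xa
    area = float(np.sum(0.5 * (va + vb) * h))
    if area <= 1e-300:
        return 0.5 * (lo + hi), True
    with np.errstate(invalid="ignore"):
        s = np.where(h > 0, (vb - va) / np.where(h > 0, h, 1.0), 0.0)
    moment = float(np.sum(
        va * (xb**2 - xa**2) / 2.0
        + s * ((xb**3 - xa**3) / 3.0 - xa * (xb**2 - xa**2) / 2.0)
    ))
    c = moment / area
    return float(min(max(c, lo), hi)), False


def infer_and_defuzzify(fis: FISConfig, e: float, ce: float) -> InferenceResult:
    """Run all 49 rules per output on normalized inputs (e, ce).

    Inputs are on the input universes (already scaled); returns the three
    normalized outputs on their universes plus per-output fallback flags.
    """
    mu_e = fuzzify(fis.e, e)
    mu_ce = fuzzify(fis.ce, ce)
    outs = []
    flags = []
    for name, grid in fis.rules.grids.items():
        w = _firing_weights(mu_e, mu_ce, grid)
        c, fb = defuzzify_centroid(fis.out_vars[name], w)
        outs.append(c)
        flags.append(fb)
    return InferenceResult(outs[0], outs[1], outs[2], tuple(flags))


def gains_from_fis(fis: FISConfig, e: float, ce: float):
    """Scheduled PID gains for a physical error e (mbar) and error rate ce (mbar/s).

    Applies the input scaling gains, infers the normalized outputs and maps
    each affinely onto its configured physical gain range.
    """
    from .control import PIDGains  # deferred: control imports this module

    res = infer_and_defuzzify(fis, e * fis.e_gain, ce * fis.ce_gain)
    vals = {}
    for name, y in zip(("kp", "ki", "kd"), (res.kp, res.ki, res.kd)):
        lo_u, hi_u = fis.out_vars[name].universe
        lo_g, hi_g = fis.gain_ranges[name]
        frac = (y - lo_u) / (hi_u - lo_u)
        vals[name] = lo_g + frac * (hi_g - lo_g)
    return PIDGains(**vals)


def rules_to_json_dict(rules: RuleTriplet) -> dict:
    """Linguistic 7x7 tables per output with the integer sidecar form."""
    return {
        "labels": {
            name: decode_rules(grid).tolist() for name, grid in rules.grids.items()
        },
        "integer": {
            name: grid.consequent.tolist() for name, grid in rules.grids.items()
        },
    }


def rules_from_json_dict(d: dict) -> RuleTriplet:
    if "integer" in d:
        g = {k: RuleGrid(np.asarray(v)) for k, v in d["integer"].items()}
    else:
        g = {k: encode_labels(v) for k, v in d["labels"].items()}
    return RuleTriplet(g["kp"], g["ki"], g["kd"])
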