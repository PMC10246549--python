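"""Class-topper optimization and its reshaped variant for fuzzy rule bases.

The classical class-topper optimizer (CTO) is a sectioned-population
metaheuristic: the population ("class") is split into sections, the best
member of each section is its section topper (ST), the best topper overall
is the class topper (CT).  Section toppers learn from the class topper and
ordinary students from their section topper via momentum-style continuous
updates — that baseline is kept here for continuous search spaces.

For the 147 integer rule consequents of the gain-scheduling FIS a
continuous grade update is meaningless, so the reshaped variant (RCTO)
replaces it with two levels of block crossover: each non-topper member
first receives a contiguous block of rule positions from the class topper
(class-level crossover), then an independently placed block from its
section topper (section-level crossover), independently for each of the
three 49-rule output grids.  Selection is purely elitist: the class topper
survives unchanged, so the best-so-far fitness never increases.  Fitness is
the closed-loop ITAE of the candidate rule base on a deterministic
(noise-free) scenario; diverged simulations receive a large penalty.

An optional random-reset mutation (off by default, as the published
operator set defines none) can re-randomize individual consequents — note
that without it, crossover can only recombine values already present in
the initial population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .control import ScenarioConfig, SimulationDivergedError, compute_metrics, simulate_closed_loop
from .fuzzy import N_RULES, N_VARIABLES, FISConfig, RuleTriplet
from .plant import StateSpaceModel, TransferFunction

logger = logging.getLogger("ventcontrol.rcto")

#: Fitness assigned to candidates whose closed-loop simulation diverges;
#: dominates any feasible ITAE (mbar*s^2) by many orders of magnitude.
DIVERGENCE_PENALTY = 1e9


@dataclass(frozen=True)
class RCTOConfig:
    """Optimizer constants.

    n_pop members are dealt round-robin into n_sections equal sections
    (n_pop must divide evenly).  whf_t1/whf_t2 and ca1/ca2 are the inertia
    weights and acceleration factors of the continuous baseline update;
    segment_len is the contiguous crossover block length per 49-rule grid
    (the published choice is 10 rules per output variable).
    """

    n_pop: int = 20
    n_sections: int = 4
    max_iter: int = 50
    whf_t1: float = 0.7
    whf_t2: float = 0.7
    ca1: float = 2.0
    ca2: float = 2.0
    segment_len: int = 10
    mutation_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_pop >= self.n_sections >= 1:
            raise ValueError("need n_pop >= n_sections >= 1")
        if self.n_pop % self.n_sections != 0:
            raise ValueError("n_pop must be divisible by n_sections")
        if not 0 <= self.segment_len <= N_RULES:
            raise ValueError(f"segment_len must lie in [0, {N_RULES}]")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")


@dataclass
class Population:
    """Sectioned population of rule triplets with (possibly unevaluated) fitness."""

    members: list[RuleTriplet]
    sections: np.ndarray
    fitness: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.members)
        self.sections = np.asarray(self.sections, dtype=int)
        self.fitness = np.asarray(self.fitness, dtype=float)
        if self.sections.shape != (n,) or self.fitness.shape != (n,):
            raise ValueError("sections/fitness must have one entry per member")

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def evaluated(self) -> bool:
        return bool(np.all(np.isfinite(self.fitness)))


@dataclass
class CTOState:
    """Topper identities, plus grade/performance arrays for the continuous baseline."""

    st: np.ndarray  # member index of each section topper
    ct: int  # member index of the class topper
    ex: Optional[np.ndarray] = None
    prf: Optional[np.ndarray] = None


def init_population(config: RCTOConfig) -> Population:
    """Uniform random rule triplets: 147 reals on [0, 7) floored to {0..6},
    dealt round-robin into sections; reproducible from config.seed."""
    rng = np.random.default_rng(config.seed)
    flat = np.floor(rng.uniform(0.0, 7.0, size=(config.n_pop, N_VARIABLES))).astype(int)
    members = [RuleTriplet.from_flat(row) for row in flat]
    sections = np.arange(config.n_pop) % config.n_sections
    return Population(members, sections, np.full(config.n_pop, np.nan))


def evaluate_fitness(
    triplet: RuleTriplet,
    fis_template: FISConfig,
    scenario: ScenarioConfig,
    plant: StateSpaceModel,
    blower: TransferFunction,
    penalty: float = DIVERGENCE_PENALTY,
) -> float:
    """Closed-loop ITAE of a candidate rule base (penalty on divergence)."""
    fis = fis_template.with_rules(triplet)
    scn = ScenarioConfig(
        pattern=scenario.pattern, duration=scenario.duration, dt=scenario.dt,
        disturbance=scenario.disturbance, noise=scenario.noise, controller=fis,
        deriv_filter_n=scenario.deriv_filter_n, saturation=scenario.saturation,
    )
    try:
        result = simulate_closed_loop(plant, blower, scn)
    except SimulationDivergedError:
        return penalty
    return compute_metrics(result, step_edge=_first_rise(scenario)).itae


def _first_rise(scenario: ScenarioConfig) -> float:
    """Time of the first rising reference edge (pulse: half period; PEEP/PIP: 0)."""
    pat = scenario.pattern
    return pat.period / 2.0 if pat.kind == "pulse" else 0.0


def select_toppers(pop: Population) -> CTOState:
    """Section-wise and global fitness argmins; ties break to the lowest index."""
    if not pop.evaluated:
        raise RuntimeError("all members must be evaluated before selecting toppers")
    n_sec = int(pop.sections.max()) + 1
    st = np.empty(n_sec, dtype=int)
    for s in range(n_sec):
        idx = np.nonzero(pop.sections == s)[0]
        st[s] = idx[int(np.argmin(pop.fitness[idx]))]
    ct = int(st[int(np.argmin(pop.fitness[st]))])
    return CTOState(st=st, ct=ct)


# ---------------------------------------------------------------------------
# continuous baseline (grade/performance updates on real-valued positions)
# ---------------------------------------------------------------------------

def cto_update_continuous(
    state: CTOState,
    config: RCTOConfig,
    sections: np.ndarray,
    rng: np.random.Generator,
    rd1: Optional[np.ndarray] = None,
    rd2: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One grade/performance update of the classical continuous CTO.

    Section toppers accelerate toward the class topper,
    Ex <- whf_t1*Ex + ca1*rd1*(CT - ST); other students toward their section
    topper, Ex <- whf_t2*Ex + ca2*rd2*(ST - student); every member then adds
    its new grade to its performance (position), Prf <- Prf + Ex.  rd1/rd2
    are fresh U(0,1) draws per member unless supplied explicitly.
    """
    ex, prf = state.ex, state.prf
    if ex is None or prf is None:
        raise ValueError("continuous update requires state.ex and state.prf")
    n = prf.shape[0]
    if rd1 is None:
        rd1 = rng.random(n)
    if rd2 is None:
        rd2 = rng.random(n)
    st_pos = prf[state.st[sections]]  # each member's section-topper position
    ct_pos = prf[state.ct]
    new_ex = np.empty_like(ex)
    is_st = np.zeros(n, dtype=bool)
    is_st[state.st] = True
    for i in range(n):
        if is_st[i]:
            new_ex[i] = config.whf_t1 * ex[i] + config.ca1 * rd1[i] * (ct_pos - prf[i])
        else:
            new_ex[i] = config.whf_t2 * ex[i] + config.ca2 * rd2[i] * (st_pos[i] - prf[i])
    return new_ex, prf + new_ex


def cto_minimize(
    f: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    config: RCTOConfig,
) -> tuple[np.ndarray, float, list[float]]:
    """Minimize a continuous function with the classical CTO baseline.

    Returns (best position, best fitness, best-so-far history).  Positions
    are clipped to the box bounds after every update.
    """
    rng = np.random.default_rng(config.seed)
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    d = len(bounds)
    prf = rng.uniform(lo, hi, size=(config.n_pop, d))
    ex = np.zeros_like(prf)
    sections = np.arange(config.n_pop) % config.n_sections

    best_x = None
    best_f = np.inf
    history: list[float] = []
    for _ in range(config.max_iter):
        fit = np.array([f(x) for x in prf])
        i = int(np.argmin(fit))
        if fit[i] < best_f:
            best_f = float(fit[i])
            best_x = prf[i].copy()
        history.append(best_f)
        pop = Population([None] * config.n_pop, sections, fit)  # type: ignore[list-item]
        state = select_toppers(pop)
        state.ex, state.prf = ex, prf
        ex, prf = cto_update_continuous(state, config, sections, rng)
        prf = np.clip(prf, lo, hi)
    fit = np.array([f(x) for x in prf])
    i = int(np.argmin(fit))
    if fit[i] < best_f:
        best_f = float(fit[i])
        best_x = prf[i].copy()
    return best_x, best_f, history


# ---------------------------------------------------------------------------
# reshaped (integer rule-base) operators
# ---------------------------------------------------------------------------

def _block_crossover(
    member: RuleTriplet, donor: RuleTriplet, segment_len: int, rng
) -> RuleTriplet:
    """Overwrite one contiguous block per 49-rule grid with the donor's values."""
    if segment_len == 0:
        return member.copy()
    child = member.flatten()
    donor_flat = donor.flatten()
    for g in range(3):
        start = int(rng.integers(0, N_RULES - segment_len + 1))
        a = g * N_RULES + start
        child[a : a + segment_len] = donor_flat[a : a + segment_len]
    return RuleTriplet.from_flat(child)


def class_level_crossover(
    member: RuleTriplet, ct: RuleTriplet, config: RCTOConfig, rng
) -> RuleTriplet:
    """Class-level crossover: donor is the class topper."""
    return _block_crossover(member, ct, config.segment_len, rng)


def section_level_crossover(
    member: RuleTriplet, st: RuleTriplet, config: RCTOConfig, rng
) -> RuleTriplet:
    """Section-level crossover: donor is the member's section topper, with an
    independently drawn block position."""
    return _block_crossover(member, st, config.segment_len, rng)


def optimize_rules(
    config: RCTOConfig,
    fis_template: Optional[FISConfig] = None,
    scenario: Optional[ScenarioConfig] = None,
    plant: Optional[StateSpaceModel] = None,
    blower: Optional[TransferFunction] = None,
    fitness_fn: Optional[Callable[[RuleTriplet], float]] = None,
    seed_members: Optional[Sequence[RuleTriplet]] = None,
) -> tuple[RuleTriplet, list[float]]:
    """Run the reshaped CTO over integer rule triplets.

    Per iteration: select toppers, then give every non-topper member a
    class-level crossover block from the class topper followed by a
    section-level block from its section topper (plus optional random-reset
    mutation), and re-evaluate.  The class topper survives unchanged
    (elitism), so the returned best-so-far history is non-increasing.

    ``fitness_fn`` overrides the closed-loop ITAE evaluation (used for
    surrogate objectives); otherwise ``fis_template``, ``scenario``,
    ``plant`` and ``blower`` are required.  ``seed_members`` replaces the
    first initial members with known triplets.
    """
    if fitness_fn is None:
        if None in (fis_template, scenario, plant, blower):
            raise ValueError(
                "either fitness_fn or (fis_template, scenario, plant, blower) required"
            )
        if scenario.noise is not None:
            raise ValueError("optimization scenario must be deterministic (no noise)")

        def fitness_fn(tr: RuleTriplet) -> float:
            return evaluate_fitness(tr, fis_template, scenario, plant, blower)

    rng = np.random.default_rng(config.seed + 1)  # decoupled from init draws
    pop = init_population(config)
    if seed_members:
        for i, m in enumerate(seed_members):
            pop.members[i] = m.copy()
    pop.fitness = np.array([fitness_fn(m) for m in pop.members])

    best_idx = int(np.argmin(pop.fitness))
    best = pop.members[best_idx].copy()
    best_f = float(pop.fitness[best_idx])
    history = [best_f]

    for it in range(config.max_iter):
        state = select_toppers(pop)
        ct_rules = pop.members[state.ct].copy()
        st_rules = {s: pop.members[i].copy() for s, i in enumerate(state.st)}
        for i in range(pop.n):
            if i == state.ct:
                continue  # elitism: the class topper survives unchanged
            child = class_level_crossover(pop.members[i], ct_rules, config, rng)
            child = section_level_crossover(
                child, st_rules[int(pop.sections[i])], config, rng
            )
            if config.mutation_rate > 0.0:
                flat = child.flatten()
                mask = rng.random(N_VARIABLES) < config.mutation_rate
                flat[mask] = rng.integers(0, 7, int(mask.sum()))
                child = RuleTriplet.from_flat(flat)
            pop.members[i] = child
            pop.fitness[i] = fitness_fn(child)
        i_min = int(np.argmin(pop.fitness))
        if pop.fitness[i_min] < best_f:
            best_f = float(pop.fitness[i_min])
            best = pop.members[i_min].copy()
        history.append(best_f)
        logger.info(
            "iteration %d: best fitness %.6g (CT in section %d)",
            it + 1, best_f, int(pop.sections[i_min]),
        )
    return best, history
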