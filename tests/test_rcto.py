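"""Class-topper optimization: continuous baseline and reshaped rule-base variant."""

import numpy as np
import pytest

import ventcontrol as vc
from ventcontrol.fuzzy import N_VARIABLES, RuleTriplet
from ventcontrol.rcto import (
    DIVERGENCE_PENALTY,
    CTOState,
    Population,
    _block_crossover,
    cto_update_continuous,
    evaluate_fitness,
    init_population,
    select_toppers,
)


class _StubRng:
    """Deterministic stand-in for a Generator, yielding scripted integers."""

    def __init__(self, values):
        self.values = list(values)

    def integers(self, lo, hi):
        return self.values.pop(0)


def _hamming_fitness(seed):
    target = np.random.default_rng(seed).integers(0, 7, N_VARIABLES)
    return target, lambda tr: float(np.sum(tr.flatten() != target))


class TestInitPopulation:
    def test_sizes_and_sections(self):
        pop = init_population(vc.RCTOConfig(n_pop=8, n_sections=4, seed=0))
        assert pop.n == 8
        assert all(np.sum(pop.sections == s) == 2 for s in range(4))

    def test_entries_in_valid_range(self):
        pop = init_population(vc.RCTOConfig(n_pop=20, n_sections=4, seed=1))
        allv = np.concatenate([m.flatten() for m in pop.members])
        assert allv.min() >= 0 and allv.max() <= 6
        assert allv.size == 20 * N_VARIABLES

    def test_seed_determinism(self):
        p1 = init_population(vc.RCTOConfig(seed=9))
        p2 = init_population(vc.RCTOConfig(seed=9))
        assert all(
            np.array_equal(a.flatten(), b.flatten())
            for a, b in zip(p1.members, p2.members)
        )

    def test_config_validation(self):
        with pytest.raises(ValueError):
            vc.RCTOConfig(n_pop=10, n_sections=4)  # not divisible
        with pytest.raises(ValueError):
            vc.RCTOConfig(n_pop=2, n_sections=4)
        with pytest.raises(ValueError):
            vc.RCTOConfig(segment_len=50)


class TestSelectToppers:
    def test_argmin_per_section_and_global(self):
        pop = init_population(vc.RCTOConfig(n_pop=6, n_sections=2, seed=0))
        # round-robin sections: members (0,2,4) in section 0, (1,3,5) in 1
        pop.fitness = np.array([3.0, 5.0, 1.0, 0.0, 2.0, 4.0])
        state = select_toppers(pop)
        assert list(state.st) == [2, 3]
        assert state.ct == 3

    def test_single_section_topper_is_class_topper(self):
        pop = init_population(vc.RCTOConfig(n_pop=4, n_sections=1, seed=0))
        pop.fitness = np.array([4.0, 1.0, 2.0, 3.0])
        state = select_toppers(pop)
        assert list(state.st) == [1]
        assert state.ct == 1

    def test_unevaluated_population_raises(self):
        pop = init_population(vc.RCTOConfig(n_pop=4, n_sections=2, seed=0))
        with pytest.raises(RuntimeError):
            select_toppers(pop)


class TestContinuousUpdate:
    def test_hand_arithmetic_of_topper_update(self):
        # two sections of one member each; member 1 is a section topper but
        # not the class topper, so it moves toward the class topper:
        # Ex_new = 0.5*2 + 2*0.25*(6-2) = 3, Prf_new = 2 + 3 = 5
        cfg = vc.RCTOConfig(n_pop=2, n_sections=2, whf_t1=0.5, ca1=2.0, seed=0)
        sections = np.array([0, 1])
        state = CTOState(
            st=np.array([0, 1]), ct=0,
            ex=np.array([[0.0], [2.0]]), prf=np.array([[6.0], [2.0]]),
        )
        ex, prf = cto_update_continuous(
            state, cfg, sections, np.random.default_rng(0),
            rd1=np.array([0.25, 0.25]), rd2=np.array([0.0, 0.0]),
        )
        assert ex[1, 0] == pytest.approx(3.0)
        assert prf[1, 0] == pytest.approx(5.0)

    def test_degenerate_constants_give_pure_inertia(self):
        cfg = vc.RCTOConfig(n_pop=2, n_sections=2, whf_t1=1.0, whf_t2=1.0,
                            ca1=0.0, ca2=0.0, seed=0)
        sections = np.array([0, 1])
        ex0 = np.array([[1.5], [-2.0]])
        prf0 = np.array([[3.0], [4.0]])
        state = CTOState(st=np.array([0, 1]), ct=0, ex=ex0.copy(), prf=prf0.copy())
        ex, prf = cto_update_continuous(state, cfg, sections, np.random.default_rng(0))
        assert np.allclose(ex, ex0)
        assert np.allclose(prf, prf0 + ex0)

    def test_class_topper_update_is_inertia_only(self):
        # for the class topper itself CT - ST = 0, so only the weight factor acts
        cfg = vc.RCTOConfig(n_pop=2, n_sections=2, whf_t1=0.7, ca1=2.0, seed=0)
        sections = np.array([0, 1])
        state = CTOState(
            st=np.array([0, 1]), ct=0,
            ex=np.array([[2.0], [0.0]]), prf=np.array([[1.0], [5.0]]),
        )
        ex, _ = cto_update_continuous(
            state, cfg, sections, np.random.default_rng(0),
            rd1=np.array([0.9, 0.9]), rd2=np.array([0.9, 0.9]),
        )
        assert ex[0, 0] == pytest.approx(0.7 * 2.0)

    def test_sphere_function_baseline(self):
        """The continuous CTO localizes the 2-D sphere optimum to 1e-2 in at
        least 8 of 10 seeded runs (N=20, 4 sections, 100 iterations)."""
        hits = 0
        for seed in range(10):
            cfg = vc.RCTOConfig(n_pop=20, n_sections=4, max_iter=100, seed=seed)
            x, _, _ = vc.cto_minimize(
                lambda v: float(v @ v), [(-5.0, 5.0)] * 2, cfg
            )
            hits += np.linalg.norm(x) < 1e-2
        assert hits >= 8


class TestCrossover:
    def _two_triplets(self):
        parent = RuleTriplet.from_flat(np.full(N_VARIABLES, 1))
        donor = RuleTriplet.from_flat(np.full(N_VARIABLES, 2))
        return parent, donor

    def test_zero_segment_returns_parent(self):
        parent, donor = self._two_triplets()
        cfg = vc.RCTOConfig(segment_len=0)
        out = vc.class_level_crossover(parent, donor, cfg, np.random.default_rng(0))
        assert np.array_equal(out.flatten(), parent.flatten())

    def test_full_segment_copies_donor(self):
        parent, donor = self._two_triplets()
        cfg = vc.RCTOConfig(segment_len=49)
        out = vc.class_level_crossover(parent, donor, cfg, np.random.default_rng(0))
        assert np.array_equal(out.flatten(), donor.flatten())

    def test_block_at_start_copies_first_ten_rules(self):
        parent, donor = self._two_triplets()
        out = _block_crossover(parent, donor, 10, _StubRng([0, 0, 0]))
        flat = out.flatten()
        for g in range(3):
            blk = flat[g * 49 : (g + 1) * 49]
            assert np.all(blk[:10] == 2)
            assert np.all(blk[10:] == 1)

    def test_random_block_is_contiguous_per_grid(self):
        parent, donor = self._two_triplets()
        cfg = vc.RCTOConfig(segment_len=10)
        out = vc.class_level_crossover(parent, donor, cfg, np.random.default_rng(3))
        flat = out.flatten()
        for g in range(3):
            diff = np.nonzero(flat[g * 49 : (g + 1) * 49] == 2)[0]
            assert len(diff) == 10
            assert diff[-1] - diff[0] == 9  # contiguous

    def test_member_equal_to_donor_is_unchanged(self):
        parent, _ = self._two_triplets()
        cfg = vc.RCTOConfig(segment_len=10)
        out = vc.section_level_crossover(parent, parent, cfg, np.random.default_rng(1))
        assert np.array_equal(out.flatten(), parent.flatten())

    def test_disjoint_blocks_from_both_donors_coexist(self):
        parent = RuleTriplet.from_flat(np.full(N_VARIABLES, 0))
        ct = RuleTriplet.from_flat(np.full(N_VARIABLES, 5))
        st = RuleTriplet.from_flat(np.full(N_VARIABLES, 6))
        cfg = vc.RCTOConfig(segment_len=10)
        out = vc.class_level_crossover(parent, ct, cfg, _StubRng([0, 0, 0]))
        out = vc.section_level_crossover(out, st, cfg, _StubRng([20, 20, 20]))
        flat = out.flatten()
        for g in range(3):
            blk = flat[g * 49 : (g + 1) * 49]
            assert np.all(blk[0:10] == 5)
            assert np.all(blk[20:30] == 6)
            assert np.all(blk[10:20] == 0)

    def test_closure_of_rule_domain(self):
        rng = np.random.default_rng(7)
        cfg = vc.RCTOConfig(segment_len=17)
        a = RuleTriplet.from_flat(rng.integers(0, 7, N_VARIABLES))
        b = RuleTriplet.from_flat(rng.integers(0, 7, N_VARIABLES))
        out = vc.class_level_crossover(a, b, cfg, rng)
        assert out.flatten().min() >= 0 and out.flatten().max() <= 6


class TestOptimizeRules:
    def test_history_monotone_and_deterministic(self):
        _, fit = _hamming_fitness(100)
        cfg = vc.RCTOConfig(n_pop=8, n_sections=2, max_iter=30, seed=7)
        best1, h1 = vc.optimize_rules(cfg, fitness_fn=fit)
        best2, h2 = vc.optimize_rules(cfg, fitness_fn=fit)
        assert h1 == h2
        assert np.array_equal(best1.flatten(), best2.flatten())
        assert all(b <= a for a, b in zip(h1, h1[1:]))

    def test_seeded_member_bounds_final_fitness(self):
        target, fit = _hamming_fitness(101)
        known = RuleTriplet.from_flat((target + 1) % 7)  # a deliberately bad seed
        good = RuleTriplet.from_flat(target.copy())
        cfg = vc.RCTOConfig(n_pop=8, n_sections=2, max_iter=5, seed=3)
        _, hist = vc.optimize_rules(cfg, fitness_fn=fit, seed_members=[good, known])
        assert hist[-1] <= fit(good)

    def test_requires_models_without_surrogate(self):
        with pytest.raises(ValueError):
            vc.optimize_rules(vc.RCTOConfig())


class TestFitnessEvaluation:
    @pytest.fixture
    def tiny_scenario(self, step_scenario_factory, default_fis):
        return step_scenario_factory(duration=0.1, dt=5e-4, controller=default_fis)

    def test_identical_triplets_identical_fitness(
        self, plant_ss, blower, default_fis, tiny_scenario
    ):
        tri = RuleTriplet.from_flat(np.random.default_rng(0).integers(0, 7, N_VARIABLES))
        f1 = evaluate_fitness(tri, default_fis, tiny_scenario, plant_ss, blower)
        f2 = evaluate_fitness(tri.copy(), default_fis, tiny_scenario, plant_ss, blower)
        assert f1 == f2

    def test_all_ze_rule_base_is_finite(
        self, plant_ss, blower, default_fis, tiny_scenario
    ):
        tri = RuleTriplet.from_flat(np.full(N_VARIABLES, 3))
        f = evaluate_fitness(tri, default_fis, tiny_scenario, plant_ss, blower)
        assert np.isfinite(f)
        assert f < DIVERGENCE_PENALTY

    def test_noisy_scenario_rejected_for_optimization(
        self, plant_ss, blower, default_fis, step_scenario_factory
    ):
        scn = step_scenario_factory(
            duration=0.1, dt=5e-4, controller=default_fis,
            noise=vc.Noise(std=0.01, seed=1),
        )
        with pytest.raises(ValueError):
            vc.optimize_rules(
                vc.RCTOConfig(n_pop=4, n_sections=2, max_iter=1),
                fis_template=default_fis, scenario=scn,
                plant=plant_ss, blower=blower,
            )
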