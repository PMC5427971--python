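"""Viability-evolution optimizer: units, boundaries, scheduler, contracts."""

import numpy as np
import pytest

from viasm import mvie
from viasm.mvie import (
    Candidate,
    Constraint,
    MvieSettings,
    Problem,
    SearchUnit,
    ViabilityBoundaries,
    compare,
    initialize,
    local_step,
    recombine,
    run,
)


def sphere_problem(dim=2, half=5.0):
    return Problem(
        -half * np.ones(dim),
        half * np.ones(dim),
        lambda x: (float(x @ x), []),
        [],
        sense="min",
    )


def constrained_1d():
    """min x² s.t. x ≥ 1 on [−5, 5]; optimum at x = 1, objective 1."""
    return Problem(
        np.array([-5.0]),
        np.array([5.0]),
        lambda x: (float(x[0] ** 2), [float(x[0])]),
        [Constraint(1.0, np.inf, "x>=1")],
        sense="min",
    )


def make_candidate(params_norm, violations, objective, idx=0):
    v = np.asarray(violations, dtype=float)
    return Candidate(
        np.asarray(params_norm, dtype=float),
        np.asarray(params_norm, dtype=float),
        v.copy(),
        v,
        objective,
        idx,
    )


class TestInitialize:
    def test_determinism(self):
        p = sphere_problem()
        u1, _ = initialize(p, 6, seed=42)
        u2, _ = initialize(p, 6, seed=42)
        for a, b in zip(u1, u2):
            np.testing.assert_array_equal(a.mean, b.mean)

    def test_too_few_units(self):
        with pytest.raises(ValueError):
            initialize(sphere_problem(), 3, seed=0)

    def test_feasible_population_gives_zero_boundaries(self):
        # constraint value always inside its interval -> all violations 0
        p = Problem(
            np.zeros(2),
            np.ones(2),
            lambda x: (float(x.sum()), [0.5]),
            [Constraint(0.0, 1.0)],
            sense="min",
        )
        ev = mvie._Evaluator(p, 100)
        _, boundaries = initialize(p, 5, seed=0, evaluator=ev)
        np.testing.assert_array_equal(boundaries.current, [0.0])

    def test_initial_population_viable_under_initial_boundaries(self):
        p = constrained_1d()
        ev = mvie._Evaluator(p, 100)
        units, boundaries = initialize(p, 8, seed=3, evaluator=ev)
        for u in units:
            bv = boundaries.boundary_violations(u.best)
            np.testing.assert_allclose(bv, 0.0, atol=1e-12)


class TestCompare:
    def setup_method(self):
        self.problem = sphere_problem()
        self.bounds = ViabilityBoundaries(np.zeros(1), np.zeros(1))

    def test_viable_beats_nonviable(self):
        good = make_candidate([0.5], [0.0], objective=100.0)
        bad = make_candidate([0.1], [2.0], objective=0.0)
        assert compare(self.problem, bad, good, self.bounds) is good

    def test_smaller_violation_wins(self):
        c1 = make_candidate([0.5], [2.0], None)
        c2 = make_candidate([0.1], [1.0], None)
        assert compare(self.problem, c1, c2, self.bounds) is c2

    def test_objective_breaks_viable_tie(self):
        pmax = Problem(
            np.zeros(1), np.ones(1), lambda x: (0.0, []), [], sense="max"
        )
        lo = make_candidate([0.5], [0.0], objective=1.0)
        hi = make_candidate([0.1], [0.0], objective=2.0)
        assert compare(pmax, lo, hi, self.bounds) is hi

    def test_incumbent_bias(self):
        c1 = make_candidate([0.5], [0.0], objective=1.0)
        c2 = make_candidate([0.1], [0.0], objective=1.0)
        assert compare(self.problem, c1, c2, self.bounds) is c1


class TestLocalStep:
    def test_sphere_convergence_single_unit(self):
        """(1+1)-CMA-ES alone solves the 2-D sphere to below 1e-6."""
        p = sphere_problem()
        for seed in range(3):
            ev = mvie._Evaluator(p, 2001)
            unit = SearchUnit(
                np.random.default_rng(seed).uniform(size=2),
                np.random.default_rng([seed, 0]),
            )
            bnd = ViabilityBoundaries(np.zeros(0), np.zeros(0))
            unit.best = ev(unit.mean, [unit.mean])
            for _ in range(2000):
                local_step(unit, p, bnd, ev, [unit.mean])
            assert unit.best.objective < 1e-6

    def test_rejection_keeps_mean_and_shrinks_sigma(self):
        # objective already optimal at the mean: every step is rejected
        p = Problem(
            np.zeros(2), np.ones(2),
            lambda x: (float(np.sum((x - 0.5) ** 2)), []), [], sense="min",
        )
        ev = mvie._Evaluator(p, 1000)
        unit = SearchUnit(np.array([0.5, 0.5]), np.random.default_rng(0))
        bnd = ViabilityBoundaries(np.zeros(0), np.zeros(0))
        unit.best = ev(unit.mean, [unit.mean])
        sigmas = [unit.sigma]
        for _ in range(50):
            local_step(unit, p, bnd, ev, [unit.mean])
            sigmas.append(unit.sigma)
        np.testing.assert_array_equal(unit.mean, [0.5, 0.5])
        assert sigmas[-1] < sigmas[0]

    def test_each_step_costs_one_evaluation(self):
        p = sphere_problem()
        ev = mvie._Evaluator(p, 100)
        unit = SearchUnit(np.array([0.3, 0.3]), np.random.default_rng(1))
        bnd = ViabilityBoundaries(np.zeros(0), np.zeros(0))
        unit.best = ev(unit.mean, [unit.mean])
        before = ev.count
        local_step(unit, p, bnd, ev, [unit.mean])
        assert ev.count == before + 1


class TestRecombine:
    def test_de_algebra_f0_cr1(self):
        """F=0, CR=1: trial equals the base member's mean exactly."""
        p = sphere_problem()
        ev = mvie._Evaluator(p, 100)
        units, bnd = initialize(p, 5, seed=0, evaluator=ev)
        means_before = np.array([u.mean for u in units])
        recombine(units, p, bnd, ev, np.random.default_rng(0), f=0.0, cr=1.0)
        # every trial must coincide with one of the previous means
        for u in units:
            assert any(
                np.allclose(u.mean, m) for m in means_before
            ) or any(np.allclose(u.best.params_norm, m) for m in means_before)

    def test_identical_units_no_change(self):
        p = sphere_problem()
        ev = mvie._Evaluator(p, 100)
        units, bnd = initialize(p, 5, seed=0, evaluator=ev)
        shared = np.array([0.4, 0.6])
        for u in units:
            u.mean = shared.copy()
            u.best = ev(u.mean, [shared])
        recombine(units, p, bnd, ev, np.random.default_rng(1))
        for u in units:
            np.testing.assert_allclose(u.mean, shared, atol=1e-12)

    def test_too_few_units(self):
        p = sphere_problem()
        ev = mvie._Evaluator(p, 10)
        units, bnd = initialize(p, 4, seed=0, evaluator=ev)
        with pytest.raises(ValueError):
            recombine(units[:3], p, bnd, ev, np.random.default_rng(0))

    def test_recombination_escapes_poor_basin(self):
        """Two-basin toy: DE moves a trapped unit to the better basin more
        often than local steps alone (seeded A/B comparison)."""

        def two_basin(x):
            # global minimum at 0.8, poor local minimum at 0.2
            v = float(
                -1.0 * np.exp(-((x[0] - 0.8) ** 2) / 0.002)
                - 0.5 * np.exp(-((x[0] - 0.2) ** 2) / 0.002)
            )
            return v, []

        p = Problem(np.zeros(1), np.ones(1), two_basin, [], sense="min")
        escapes_with_de, escapes_local = 0, 0
        for seed in range(10):
            for use_de, counter in ((True, "de"), (False, "local")):
                ev = mvie._Evaluator(p, 10_000)
                units, bnd = initialize(p, 6, seed=seed, evaluator=ev)
                # trap unit 0 in the poor basin
                units[0].mean = np.array([0.2])
                units[0].best = ev(units[0].mean, [u.mean for u in units])
                # park the others in the good basin
                for u in units[1:]:
                    u.mean = np.array([0.8]) + 0.01 * u.mean
                    u.best = ev(u.mean, [w.mean for w in units])
                rng = np.random.default_rng(seed + 100)
                for _ in range(5):
                    if use_de:
                        recombine(units, p, bnd, ev, rng)
                    else:
                        for _ in range(len(units)):
                            local_step(units[0], p, bnd, ev, [u.mean for u in units])
                if abs(units[0].mean[0] - 0.8) < 0.1:
                    if use_de:
                        escapes_with_de += 1
                    else:
                        escapes_local += 1
        assert escapes_with_de > escapes_local


class TestBoundaries:
    def test_schedule_reaches_zero_and_monotone(self):
        p = constrained_1d()
        res = run(p, budget=2000, seed=5)
        prev = None
        for rec in res.trace:
            b = rec["boundaries"]
            if prev is not None:
                assert np.all(b <= prev + 1e-12)
            prev = b
        # after the tightening point all boundaries are zero
        tighten_at = 0.5 * 2000
        for rec in res.trace:
            if rec["evals"] >= tighten_at:
                np.testing.assert_allclose(rec["boundaries"], 0.0, atol=1e-12)


class TestRun:
    def test_constrained_optimum(self):
        res = run(constrained_1d(), budget=5000, seed=2)
        assert res.feasible
        assert res.best.params[0] == pytest.approx(1.0, abs=1e-3)
        assert res.best.objective == pytest.approx(1.0, abs=2e-3)

    def test_archive_only_contains_feasible(self):
        res = run(constrained_1d(), budget=3000, seed=1)
        for cand in res.archive:
            assert np.all(cand.violations <= mvie.FEAS_TOL)

    def test_budget_respected_exactly(self):
        res = run(constrained_1d(), budget=777, seed=0)
        assert res.n_evaluations == 777

    def test_determinism_same_seed(self):
        r1 = run(constrained_1d(), budget=2000, seed=7)
        r2 = run(constrained_1d(), budget=2000, seed=7)
        np.testing.assert_array_equal(r1.best.params, r2.best.params)
        assert len(r1.archive) == len(r2.archive)
        assert [t["evals"] for t in r1.trace] == [t["evals"] for t in r2.trace]

    def test_impossible_constraints_flagged(self):
        p = Problem(
            np.zeros(1), np.ones(1),
            lambda x: (0.0, [float(x[0])]),
            [Constraint(5.0, 6.0)],  # unreachable inside [0, 1]
            sense="min",
        )
        res = run(p, budget=500, seed=0)
        assert not res.feasible
        assert res.best is res.least_violating
        assert res.best.total_violation > 0

    def test_diversity_objective_archives_quickly(self):
        p = Problem(
            np.zeros(2), np.ones(2),
            lambda x: (None, [0.5]),
            [Constraint(0.0, 1.0)],
            sense="max",
            diversity_objective=True,
        )
        res = run(p, budget=200, seed=0)
        assert res.feasible
        assert len(res.archive) > 0
        assert all(c.objective is not None for c in res.archive)

    def test_unconstrained_matches_plain_cmaes_scale(self):
        """With no constraints the full scheduler still solves the sphere
        within an order of magnitude of a bare (1+1)-CMA-ES's budget."""
        p = sphere_problem()
        res = run(p, budget=20_000, seed=3, settings=MvieSettings(n_units=4))
        assert res.best.objective < 1e-6

    def test_grid_oracle_2d(self):
        """Dense brute force finds no feasible point beating mViE's best by
        more than 1% of the objective range (5 seeds)."""
        lo, hi = np.array([-2.0, -2.0]), np.array([2.0, 2.0])

        def objective(x):
            return float((x[0] - 0.5) ** 2 + (x[1] + 0.3) ** 2)

        def cons_val(x):
            return float(x[0] + x[1])

        p = Problem(
            lo, hi,
            lambda x: (objective(x), [cons_val(x)]),
            [Constraint(1.0, np.inf)],
            sense="min",
        )
        # 10^6-point grid oracle
        g = np.linspace(-2, 2, 1000)
        xx, yy = np.meshgrid(g, g, indexing="ij")
        feas = xx + yy >= 1.0
        vals = (xx - 0.5) ** 2 + (yy + 0.3) ** 2
        grid_best = vals[feas].min()
        obj_range = vals[feas].max() - grid_best
        for seed in range(5):
            res = run(p, budget=4000, seed=seed)
            assert res.feasible
            assert res.best.objective <= grid_best + 0.01 * obj_range
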