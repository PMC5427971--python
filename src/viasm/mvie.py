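"""Memetic Viability Evolution (mViE): constrained evolutionary optimization.

The optimizer never aggregates objective and constraints into one weighted
fitness.  Instead, each constraint carries a *viability boundary* — an
allowance on its violation — that starts wide enough to admit the whole
initial population and tightens over the run until only candidates
satisfying the true constraints survive.  Search is memetic: a population
of (1+1)-CMA-ES local search units performs exploitation, periodically
recombined by Differential Evolution (DE/rand/1/bin) for global search,
under a fixed-cycle scheduler.

All search happens in the normalized unit box; decoding to physical
parameters is the caller's job via :class:`Problem`'s callables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scoring import diversity

__all__ = [
    "Constraint",
    "Problem",
    "SearchUnit",
    "ViabilityBoundaries",
    "Candidate",
    "RunResult",
    "MvieSettings",
    "initialize",
    "compare",
    "local_step",
    "recombine",
    "update_boundaries",
    "run",
]

#: Feasibility tolerance on final-bound violations (normalized units).
FEAS_TOL = 1e-9


@dataclass
class Constraint:
    """An inequality/interval constraint ``lower <= value <= upper``.

    Use ``lower=-inf`` for pure upper bounds (the steric-energy constraint
    E_phys < 0 is expressed as ``upper = -1e-6`` so that zero contact does
    not count as viable).
    """

    lower: float
    upper: float
    name: str = ""

    def violation(self, value: float) -> float:
        return max(0.0, self.lower - value, value - self.upper)


@dataclass
class Problem:
    """Optimization problem in a finite box.

    ``eval_fn(x_physical) -> (objective_value, constraint_values)`` — one
    call per candidate; ``objective_value`` may be None when
    ``diversity_objective`` is set (the built-in Eq.-style population
    diversity in normalized coordinates is used instead).
    ``sense`` is "max" or "min".
    """

    lower: np.ndarray
    upper: np.ndarray
    eval_fn: object
    constraints: list = field(default_factory=list)
    sense: str = "min"
    diversity_objective: bool = False

    def __post_init__(self):
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if self.lower.shape != self.upper.shape or np.any(self.upper <= self.lower):
            raise ValueError("invalid box bounds")
        if self.sense not in ("min", "max"):
            raise ValueError("sense must be 'min' or 'max'")
        if self.eval_fn is None and not self.diversity_objective:
            raise ValueError("problem needs an objective or constraints")

    @property
    def dim(self) -> int:
        return self.lower.size

    def decode(self, u: np.ndarray) -> np.ndarray:
        return self.lower + u * (self.upper - self.lower)


@dataclass
class Candidate:
    """An evaluated parameter vector."""

    params_norm: np.ndarray
    params: np.ndarray
    constraint_values: np.ndarray
    violations: np.ndarray  # against the FINAL bounds
    objective: float | None
    eval_index: int

    @property
    def feasible(self) -> bool:
        return bool(np.all(self.violations <= FEAS_TOL))

    @property
    def total_violation(self) -> float:
        return float(self.violations.sum())


@dataclass
class ViabilityBoundaries:
    """Per-constraint violation allowances b_j(t), nonincreasing in t."""

    initial: np.ndarray
    current: np.ndarray

    def boundary_violations(self, cand: Candidate) -> np.ndarray:
        return np.maximum(0.0, cand.violations - self.current)

    def copy(self) -> "ViabilityBoundaries":
        return ViabilityBoundaries(self.initial.copy(), self.current.copy())


class SearchUnit:
    """(1+1)-CMA-ES local search state (Cholesky-factor variant)."""

    # strategy constants (frozen defaults, see MvieSettings)
    P_TARGET = 2.0 / 11.0
    C_P = 1.0 / 12.0

    def __init__(self, mean: np.ndarray, rng: np.random.Generator, sigma0: float = 0.25):
        self.dim = mean.size
        self.mean = np.asarray(mean, dtype=float)
        self.A = np.eye(self.dim)
        self.sigma = float(sigma0)
        self.sigma0 = float(sigma0)
        self.p_succ = self.P_TARGET
        self.best: Candidate | None = None
        self.rng = rng
        self.damping = 1.0 + self.dim / 2.0
        self.c_cov = 2.0 / (self.dim**2 + 6.0)

    def sample(self) -> tuple:
        """Propose a point in the unit box (resample up to 10×, then clip)."""
        for _ in range(10):
            z = self.rng.standard_normal(self.dim)
            y = self.mean + self.sigma * (self.A @ z)
            if np.all((y >= 0.0) & (y <= 1.0)):
                return y, z
        return np.clip(y, 0.0, 1.0), z

    def adapt(self, success: bool, z: np.ndarray) -> None:
        """1/5th-success-rule step-size control and rank-one factor update."""
        self.p_succ = (1.0 - self.C_P) * self.p_succ + self.C_P * float(success)
        self.sigma *= np.exp(
            (self.p_succ - self.P_TARGET) / ((1.0 - self.P_TARGET) * self.damping)
        )
        self.sigma = float(np.clip(self.sigma, 1e-12, 1.0))
        if success:
            na2 = float(z @ z)
            if na2 > 0:
                a = np.sqrt(1.0 - self.c_cov)
                factor = (a / na2) * (
                    np.sqrt(1.0 + self.c_cov * na2 / (1.0 - self.c_cov)) - 1.0
                )
                Az = self.A @ z
                self.A = a * self.A + factor * np.outer(Az, z)

    def reset_adaptation(self) -> None:
        self.A = np.eye(self.dim)
        self.sigma = self.sigma0
        self.p_succ = self.P_TARGET


@dataclass
class MvieSettings:
    """Frozen optimizer defaults (all configurable)."""

    n_units: int = 20
    g_local: int = 10  # local generations per recombination sweep
    de_f: float = 0.7
    de_cr: float = 0.9
    t_tighten_frac: float = 0.5  # boundaries reach 0 at this budget fraction
    sigma0: float = 0.25


@dataclass
class RunResult:
    archive: list
    best: Candidate | None
    n_evaluations: int
    trace: list
    feasible: bool
    least_violating: Candidate | None = None
    unit_bests: list = field(default_factory=list)  # final incumbent per unit


class _Evaluator:
    """Counts evaluations and archives final-bound-feasible candidates."""

    def __init__(self, problem: Problem, budget: int):
        self.problem = problem
        self.budget = budget
        self.count = 0
        self.archive: list = []
        self.least_violating: Candidate | None = None

    @property
    def exhausted(self) -> bool:
        return self.count >= self.budget

    def __call__(self, u: np.ndarray, unit_means: list) -> Candidate:
        if self.exhausted:
            raise RuntimeError("evaluation budget exhausted")
        x = self.problem.decode(u)
        obj, cons = self.problem.eval_fn(x)
        cons = np.asarray(cons, dtype=float) if len(self.problem.constraints) else np.empty(0)
        viol = np.array(
            [c.violation(v) for c, v in zip(self.problem.constraints, cons)]
        )
        if self.problem.diversity_objective:
            obj = diversity(u, np.array(unit_means))
        cand = Candidate(u.copy(), x, cons, viol, obj, self.count)
        self.count += 1
        if cand.feasible:
            self.archive.append(cand)
        if (
            self.least_violating is None
            or cand.total_violation < self.least_violating.total_violation
        ):
            self.least_violating = cand
        return cand


def _objective_better(problem: Problem, a: float, b: float) -> bool:
    """True if objective a beats objective b."""
    return a > b if problem.sense == "max" else a < b


def compare(
    problem: Problem,
    c1: Candidate,
    c2: Candidate,
    boundaries: ViabilityBoundaries,
) -> Candidate:
    """Select the better of two candidates under current viability boundaries.

    Lexicographic: fewer boundary-violated constraints, then smaller total
    boundary violation, then (both viable) better objective; ties keep c1
    (incumbent bias).
    """
    bv1 = boundaries.boundary_violations(c1)
    bv2 = boundaries.boundary_violations(c2)
    n1, n2 = int(np.sum(bv1 > 0)), int(np.sum(bv2 > 0))
    if n1 != n2:
        return c1 if n1 < n2 else c2
    s1, s2 = bv1.sum(), bv2.sum()
    if abs(s1 - s2) > 0:
        return c1 if s1 < s2 else c2
    if c1.objective is not None and c2.objective is not None:
        if _objective_better(problem, c2.objective, c1.objective):
            return c2
    return c1


def initialize(
    problem: Problem,
    n_units: int,
    seed: int,
    sigma0: float = 0.25,
    evaluator: "_Evaluator | None" = None,
) -> tuple:
    """Seeded uniform population; boundaries admit every initial unit.

    Initial boundaries are the per-constraint maxima of the initial
    population's violations against the final bounds, so every starting
    unit is viable with respect to the starting boundaries.
    """
    if n_units < 4:
        raise ValueError("DE recombination needs at least 4 units")
    init_rng = np.random.default_rng([seed, 1_000_003])
    units = [
        SearchUnit(
            init_rng.uniform(size=problem.dim),
            np.random.default_rng([seed, i]),
            sigma0,
        )
        for i in range(n_units)
    ]
    n_cons = len(problem.constraints)
    boundaries = ViabilityBoundaries(np.zeros(n_cons), np.zeros(n_cons))
    if evaluator is not None:
        for u in units:
            if evaluator.exhausted:
                break
            u.best = evaluator(u.mean, [w.mean for w in units])
        if n_cons:
            viols = np.array([u.best.violations for u in units if u.best is not None])
            boundaries.initial = viols.max(axis=0)
            boundaries.current = boundaries.initial.copy()
    return units, boundaries


def local_step(
    unit: SearchUnit,
    problem: Problem,
    boundaries: ViabilityBoundaries,
    evaluator: _Evaluator,
    unit_means: list,
) -> Candidate:
    """One (1+1)-CMA-ES iteration: sample, evaluate, select, adapt."""
    y, z = unit.sample()
    cand = evaluator(y, unit_means)
    winner = compare(problem, unit.best, cand, boundaries) if unit.best else cand
    success = winner is cand
    if success:
        unit.best = cand
        unit.mean = cand.params_norm.copy()
    unit.adapt(success, z)
    return cand


def recombine(
    units: list,
    problem: Problem,
    boundaries: ViabilityBoundaries,
    evaluator: _Evaluator,
    rng: np.random.Generator,
    f: float = 0.7,
    cr: float = 0.9,
) -> None:
    """DE/rand/1/bin sweep over all units; successful trials replace the
    unit's mean and personal best and reset its CMA adaptation."""
    n = len(units)
    if n < 4:
        raise ValueError("DE recombination needs at least 4 units")
    means = [u.mean.copy() for u in units]
    for i in range(n):
        if evaluator.exhausted:
            return
        choices = [j for j in range(n) if j != i]
        r1, r2, r3 = rng.choice(choices, size=3, replace=False)
        jrand = rng.integers(problem.dim)
        mutant = means[r1] + f * (means[r2] - means[r3])
        crossover = rng.uniform(size=problem.dim) < cr
        crossover[jrand] = True
        trial = np.where(crossover, mutant, means[i])
        trial = np.clip(trial, 0.0, 1.0)
        cand = evaluator(trial, [u.mean for u in units])
        if units[i].best is None or compare(problem, units[i].best, cand, boundaries) is cand:
            units[i].best = cand
            units[i].mean = cand.params_norm.copy()
            units[i].reset_adaptation()


def update_boundaries(
    boundaries: ViabilityBoundaries,
    units: list,
    evals: int,
    budget: int,
    t_tighten_frac: float = 0.5,
) -> None:
    """Tighten viability boundaries (in place): never above the linear
    schedule ``b_j(0)·(1 − t/T_tighten)``, never above the worst current
    unit, never increasing; zero from ``T_tighten`` on."""
    if boundaries.current.size == 0:
        return
    t_tighten = max(1.0, t_tighten_frac * budget)
    sched = boundaries.initial * max(0.0, 1.0 - evals / t_tighten)
    pop_max = np.max(
        [b.violations for b in (u.best for u in units) if b is not None], axis=0
    )
    boundaries.current = np.minimum(boundaries.current, np.minimum(sched, pop_max))
    boundaries.current = np.maximum(boundaries.current, 0.0)


def run(
    problem: Problem,
    budget: int,
    seed: int = 0,
    settings: MvieSettings | None = None,
) -> RunResult:
    """Full mViE run: scheduler alternating local search and recombination.

    Every evaluated parameter vector counts once against ``budget``.  All
    candidates satisfying the final constraint bounds are archived;
    ``best`` is the archive's best by objective (or the least-violating
    candidate, flagged infeasible, if the archive stays empty).
    """
    st = settings or MvieSettings()
    if budget < st.n_units:
        raise ValueError("budget must cover at least one evaluation per unit")
    evaluator = _Evaluator(problem, budget)
    units, boundaries = initialize(problem, st.n_units, seed, st.sigma0, evaluator)
    de_rng = np.random.default_rng([seed, 2_000_003])

    trace = []
    while not evaluator.exhausted:
        for _ in range(st.g_local):
            for u in units:
                if evaluator.exhausted:
                    break
                local_step(u, problem, boundaries, evaluator, [w.mean for w in units])
            if evaluator.exhausted:
                break
        if not evaluator.exhausted:
            recombine(units, problem, boundaries, evaluator, de_rng, st.de_f, st.de_cr)
        update_boundaries(boundaries, units, evaluator.count, budget, st.t_tighten_frac)
        n_feas = sum(1 for u in units if u.best is not None and u.best.feasible)
        trace.append(
            {
                "evals": evaluator.count,
                "boundaries": boundaries.current.copy(),
                "feasible_fraction": n_feas / len(units),
                "archive_size": len(evaluator.archive),
            }
        )

    best = None
    if evaluator.archive:
        best = evaluator.archive[0]
        for cand in evaluator.archive[1:]:
            if (
                cand.objective is not None
                and best.objective is not None
                and _objective_better(problem, cand.objective, best.objective)
            ):
                best = cand
    return RunResult(
        archive=evaluator.archive,
        best=best if best is not None else evaluator.least_violating,
        n_evaluations=evaluator.count,
        trace=trace,
        feasible=bool(evaluator.archive),
        least_violating=evaluator.least_violating,
        unit_bests=[u.best for u in units if u.best is not None],
    )
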