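"""Experiment protocols: wiring scores, optimizer and post-processing.

Five assembly modes, each a constrained-optimization formulation solved by
the viability optimizer:

- ``diversity``      — restraints + E_phys < 0 as viability constraints,
                       population diversity as objective, ccc ranking after
                       clustering.
- ``energy``         — minimize E_phys subject to the restraints.
- ``ccc_objective``  — restraints + energy as constraints, map
                       cross-correlation as objective (frame re-fitted every
                       1000 evaluations).
- ``blind_dock``     — 10-parameter search (4 assembly + 6 global pose),
                       E_phys < 0 the sole constraint, ccc the objective.
- ``crosslink``      — homodimer mode maximizing the correlation between
                       inter-subunit Cβ distances and fractional
                       crosslinking, anchored on the top-crosslinked residue.

plus the wrong-restraint ``audit`` and the legacy weighted-sum reference
mode.  All protocols are deterministic per (inputs, seed) and respect
their evaluation budgets exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from . import density, mvie, postprocess
from .assembly import (
    AssemblyParams,
    SymmetrySpec,
    build_symmetric,
    default_bounds,
)
from .scoring import (
    LJParams,
    aggregated_fitness,
    constraint_violations,
    pearson,
)
from .structio import Structure

__all__ = [
    "ProtocolConfig",
    "ProtocolResult",
    "protocol_diversity",
    "protocol_energy_objective",
    "protocol_ccc_objective",
    "protocol_blind_dock",
    "protocol_crosslink",
    "protocol_audit",
    "protocol_aggregated_reference",
]

#: Strict-negativity bound used for the E_phys < 0 viability constraint.
E_PHYS_UPPER = -1e-6
TWO_PI = 2.0 * np.pi


@dataclass
class ProtocolConfig:
    """Declarative run configuration (the CLI marshals files into this)."""

    mode: str = "diversity"
    subunit: str | None = None
    symmetry_n: int = 2
    constraints: str | None = None
    map: str | None = None
    resolution: float = 15.0
    voxel: float | None = None
    profile: str | None = None
    anchor_target: float | None = None
    anchor_tolerance: float = 2.0
    budget: int = 20_000
    trials: int = 1
    seed: int = 0
    n_units: int = 20
    cluster_threshold: float = 1.0
    top_k: int = 5

    MODES = (
        "diversity",
        "energy_objective",
        "ccc_objective",
        "blind_dock",
        "crosslink",
        "audit",
        "aggregated_reference",
    )

    def __post_init__(self):
        if self.mode not in self.MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "blind_dock" and self.map is None:
            raise ValueError("blind_dock requires a density map")
        if self.mode == "crosslink" and self.profile is None:
            raise ValueError("crosslink mode requires a crosslink profile")


@dataclass
class ProtocolResult:
    """Outcome of one protocol run."""

    mode: str
    success: bool
    message: str = ""
    run: mvie.RunResult | None = None
    ranked: postprocess.RankedModels | None = None
    clusters: postprocess.ClusterReport | None = None
    best_structure: Structure | None = None
    best_params: np.ndarray | None = None
    extras: dict = field(default_factory=dict)


# ----------------------------------------------------------------------
# Fast assembly evaluation (no Structure objects inside the hot loop)
# ----------------------------------------------------------------------

class _AssemblyEngine:
    """Vectorized Cn-assembly evaluation for the optimizer's inner loop.

    Produces numerically identical results to building a
    :class:`~viasm.structio.Structure` via :func:`build_symmetric` and
    scoring it (asserted in the test suite), but avoids per-candidate
    object construction.
    """

    def __init__(self, subunit: Structure, n: int, constraints=(), lj=LJParams()):
        self.subunit = subunit
        self.n = n
        self.lj = lj
        self.center = subunit.centroid()
        self.coords0 = subunit.coords - self.center
        self.ca_idx = np.array(
            [i for i, nm in enumerate(subunit.atom_names) if nm == "CA"]
        )
        self.rz = []
        for k in range(n):
            ang = TWO_PI * k / n
            c, s = np.cos(ang), np.sin(ang)
            self.rz.append(np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]]))
        self.cons = list(constraints)
        self.cons_idx = []
        for c in self.cons:
            ia = self._atom_index(c.residue_a, c.atom_type)
            ib = self._atom_index(c.residue_b, c.atom_type)
            self.cons_idx.append((ia, ib))

    def _atom_index(self, res_id: int, atom_type: str) -> int:
        for i, (r, nm) in enumerate(zip(self.subunit.res_ids, self.subunit.atom_names)):
            if int(r) == int(res_id) and nm == atom_type:
                return i
        from .structio import SelectionError

        raise SelectionError(f"residue {res_id} has no {atom_type} atom")

    def copies(self, alpha, beta, gamma, x) -> np.ndarray:
        """(n, n_atoms, 3) stack of subunit-copy coordinates."""
        rot = Rotation.from_euler("ZYZ", [alpha, beta, gamma]).as_matrix()
        base = self.coords0 @ rot.T + np.array([x, 0.0, 0.0])
        return np.stack([base @ rz.T for rz in self.rz])

    def e_phys(self, stacked: np.ndarray) -> float:
        cas = stacked[:, self.ca_idx, :]
        total = 0.0
        for i in range(self.n):
            for j in range(i + 1, self.n):
                d = cdist(cas[i], cas[j])
                close = d[(d > 0) & (d < self.lj.cutoff)]
                if close.size:
                    s = self.lj.sigma / close
                    total += float(
                        np.sum(4.0 * self.lj.epsilon * (s**9 - s**6))
                    )
        return total

    def constraint_dists(self, stacked: np.ndarray) -> np.ndarray:
        out = np.empty(len(self.cons_idx))
        for k, (ia, ib) in enumerate(self.cons_idx):
            out[k] = np.linalg.norm(stacked[0, ia] - stacked[1, ib])
        return out

    def structure(self, params_vec) -> Structure:
        params = AssemblyParams(*params_vec[:3], x=params_vec[3])
        return build_symmetric(self.subunit, params, SymmetrySpec(self.n))


def _mvie_constraints(constraints, with_energy=True):
    cons = [
        mvie.Constraint(c.lower, c.upper, f"d{k}") for k, c in enumerate(constraints)
    ]
    if with_energy:
        cons.append(mvie.Constraint(-np.inf, E_PHYS_UPPER, "e_phys"))
    return cons


def _select_for_clustering(problem, archive, cap=400):
    """Cap the archived candidates before clustering: best by objective,
    deduplicated on rounded parameters (desk-scale choice)."""
    sense = problem.sense
    cands = [c for c in archive if c.objective is not None]
    cands.sort(key=lambda c: (-c.objective if sense == "max" else c.objective,
                              c.eval_index))
    seen, out = set(), []
    for c in cands:
        key = tuple(np.round(c.params, 3))
        if key in seen:
            continue
        seen.add(key)
        out.append(c)
        if len(out) >= cap:
            break
    return out


def _cluster_and_rank(
    problem,
    engine: _AssemblyEngine,
    result: mvie.RunResult,
    reference_map,
    cluster_threshold,
    top_k,
    rank_fit="fast",
    max_cluster=400,
):
    selected = _select_for_clustering(problem, result.archive, max_cluster)
    coord_sets = np.stack(
        [engine.copies(*c.params[:4]) [:, engine.ca_idx, :].reshape(-1, 3)
         for c in selected]
    )
    report = postprocess.cluster_solutions(coord_sets, cluster_threshold)
    centroid_structs = [engine.structure(selected[i].params) for i in report.centroids]
    if reference_map is not None:
        ranked = postprocess.rank_by_ccc(centroid_structs, reference_map, fit=rank_fit)
        best_struct = ranked.best[1]
        best_params = selected[report.centroids[ranked.best[0]]].params
    else:
        order = np.argsort([-len(c) for c in report.clusters])
        ranked = postprocess.RankedModels(
            [(int(i), centroid_structs[int(i)], None, float("nan")) for i in order]
        )
        best_struct = ranked.best[1]
        best_params = selected[report.centroids[ranked.best[0]]].params
    return report, ranked, best_struct, best_params


def _failure(mode, result):
    return ProtocolResult(
        mode=mode,
        success=False,
        message="no viable solutions within budget",
        run=result,
        best_params=(
            result.least_violating.params if result.least_violating else None
        ),
    )


# ----------------------------------------------------------------------
# Protocols
# ----------------------------------------------------------------------

def protocol_diversity(
    subunit: Structure,
    symmetry_n: int,
    constraints,
    reference_map: density.DensityMap | None = None,
    budget: int = 20_000,
    seed: int = 0,
    settings: mvie.MvieSettings | None = None,
    cluster_threshold: float = 1.0,
    lj: LJParams = LJParams(),
    bounds=None,
    top_k: int = 5,
    rank_fit: str = "fast",
) -> ProtocolResult:
    """Restraints and steric energy as viability constraints, population
    diversity as objective; archive clustered at 1 Å and centroids ranked
    by map cross-correlation."""
    engine = _AssemblyEngine(subunit, symmetry_n, constraints, lj)
    if bounds is None:
        bounds = default_bounds(subunit, SymmetrySpec(symmetry_n))

    def eval_fn(x):
        stacked = engine.copies(*x[:4])
        return None, np.append(engine.constraint_dists(stacked), engine.e_phys(stacked))

    problem = mvie.Problem(
        bounds.lower,
        bounds.upper,
        eval_fn,
        _mvie_constraints(constraints),
        sense="max",
        diversity_objective=True,
    )
    result = mvie.run(problem, budget, seed, settings)
    if not result.feasible:
        return _failure("diversity", result)
    report, ranked, best_struct, best_params = _cluster_and_rank(
        problem, engine, result, reference_map, cluster_threshold, top_k, rank_fit
    )
    return ProtocolResult(
        "diversity", True, "", result, ranked, report, best_struct, best_params
    )


def protocol_energy_objective(
    subunit: Structure,
    symmetry_n: int,
    constraints,
    reference_map: density.DensityMap | None = None,
    budget: int = 20_000,
    seed: int = 0,
    settings: mvie.MvieSettings | None = None,
    cluster_threshold: float = 1.0,
    lj: LJParams = LJParams(),
    bounds=None,
    top_k: int = 5,
) -> ProtocolResult:
    """Minimize E_phys subject to the distance restraints only."""
    engine = _AssemblyEngine(subunit, symmetry_n, constraints, lj)
    if bounds is None:
        bounds = default_bounds(subunit, SymmetrySpec(symmetry_n))

    def eval_fn(x):
        stacked = engine.copies(*x[:4])
        return engine.e_phys(stacked), engine.constraint_dists(stacked)

    problem = mvie.Problem(
        bounds.lower,
        bounds.upper,
        eval_fn,
        _mvie_constraints(constraints, with_energy=False),
        sense="min",
    )
    result = mvie.run(problem, budget, seed, settings)
    if not result.feasible:
        return _failure("energy_objective", result)
    report, ranked, best_struct, best_params = _cluster_and_rank(
        problem, engine, result, reference_map, cluster_threshold, top_k
    )
    # for the energy objective the best model is the archive's minimum
    best_struct = engine.structure(result.best.params)
    return ProtocolResult(
        "energy_objective", True, "", result, ranked, report, best_struct,
        result.best.params,
        extras={"best_e_phys": result.best.objective},
    )


def protocol_ccc_objective(
    subunit: Structure,
    symmetry_n: int,
    constraints,
    reference_map: density.DensityMap,
    budget: int = 20_000,
    seed: int = 0,
    settings: mvie.MvieSettings | None = None,
    cluster_threshold: float = 1.0,
    lj: LJParams = LJParams(),
    bounds=None,
    top_k: int = 5,
    refit_every: int = 1000,
) -> ProtocolResult:
    """Restraints + energy as constraints, map cross-correlation as the
    objective.  Every ``refit_every`` evaluations the alignment frame is
    refreshed by re-fitting the best model seen so far into the map;
    between refreshes candidates are scored in the current frame."""
    engine = _AssemblyEngine(subunit, symmetry_n, constraints, lj)
    if bounds is None:
        bounds = default_bounds(subunit, SymmetrySpec(symmetry_n))
    sigma = reference_map.resolution
    state = {
        "count": 0,
        "frame": np.concatenate(
            [np.zeros(3), reference_map.center_of_mass() - np.zeros(3)]
        ),
        "best_ccc": -np.inf,
        "best_params": None,
        "n_refits": 0,
    }

    def score(stacked):
        ca = stacked[:, engine.ca_idx, :].reshape(-1, 3)
        center = ca.mean(axis=0)
        pose = state["frame"].copy()
        # frame translation stored as absolute target position of the centroid
        pose[3:] = pose[3:] - center
        return density.score_in_map(
            density._posed(ca, center, pose), reference_map, "plain"
        )

    def eval_fn(x):
        if (
            state["count"] > 0
            and refit_every > 0
            and state["count"] % refit_every == 0
            and state["best_params"] is not None
        ):
            st = engine.structure(state["best_params"])
            pose, _ = postprocess.fast_fit_ccc(st, reference_map)
            centroid = st.ca_coords().mean(axis=0)
            rot = pose[:3]
            # store absolute centroid destination so any candidate reuses it
            state["frame"] = np.concatenate([rot, centroid + pose[3:]])
            state["n_refits"] += 1
        stacked = engine.copies(*x[:4])
        obj = score(stacked)
        cons = np.append(engine.constraint_dists(stacked), engine.e_phys(stacked))
        state["count"] += 1
        if np.all(constraint_violations(cons[:-1], constraints) == 0) and cons[-1] < 0:
            if obj > state["best_ccc"]:
                state["best_ccc"] = obj
                state["best_params"] = x.copy()
        return obj, cons

    problem = mvie.Problem(
        bounds.lower,
        bounds.upper,
        eval_fn,
        _mvie_constraints(constraints),
        sense="max",
    )
    result = mvie.run(problem, budget, seed, settings)
    if not result.feasible:
        return _failure("ccc_objective", result)
    report, ranked, best_struct, best_params = _cluster_and_rank(
        problem, engine, result, reference_map, cluster_threshold, top_k
    )
    return ProtocolResult(
        "ccc_objective", True, "", result, ranked, report, best_struct, best_params,
        extras={"n_refits": state["n_refits"], "best_ccc": result.best.objective},
    )


def protocol_blind_dock(
    subunit: Structure,
    symmetry_n: int,
    reference_map: density.DensityMap,
    budget: int = 100_000,
    seed: int = 0,
    settings: mvie.MvieSettings | None = None,
    cluster_threshold: float = 1.0,
    lj: LJParams = LJParams(),
    bounds=None,
    top_k: int = 5,
    t_max: float | None = None,
) -> ProtocolResult:
    """Blind docking into a density map: no distance restraints.

    Ten parameters: the four assembly parameters plus a 6-dof global pose
    applied after translating the assembled ring to the map's center.
    E_phys < 0 is the sole viability constraint; ccc is the objective.
    """
    engine = _AssemblyEngine(subunit, symmetry_n, (), lj)
    if bounds is None:
        bounds = default_bounds(subunit, SymmetrySpec(symmetry_n))
    if t_max is None:
        extent = (np.array(reference_map.shape) - 1) * reference_map.voxel
        t_max = float(extent.max()) / 4.0
    map_center = reference_map.center()
    lower = np.concatenate([bounds.lower, np.zeros(3), -t_max * np.ones(3)])
    upper = np.concatenate([bounds.upper, TWO_PI * np.ones(3), t_max * np.ones(3)])

    def posed_ca(x):
        stacked = engine.copies(*x[:4])
        ca = stacked[:, engine.ca_idx, :].reshape(-1, 3)
        center = ca.mean(axis=0)
        rot = Rotation.from_euler("ZYZ", x[4:7]).as_matrix()
        return (ca - center) @ rot.T + map_center + x[7:10], stacked

    # a single copy has no inter-subunit energy: the constraint only exists
    # for true multimers
    use_energy = symmetry_n > 1

    def eval_fn(x):
        ca, stacked = posed_ca(x)
        obj = density.score_in_map(ca, reference_map, "plain")
        cons = np.array([engine.e_phys(stacked)]) if use_energy else np.empty(0)
        return obj, cons

    problem = mvie.Problem(
        lower,
        upper,
        eval_fn,
        [mvie.Constraint(-np.inf, E_PHYS_UPPER, "e_phys")] if use_energy else [],
        sense="max",
    )
    result = mvie.run(problem, budget, seed, settings)
    if not result.feasible:
        return _failure("blind_dock", result)
    best = result.best
    params = AssemblyParams(*best.params[:3], x=best.params[3])
    asm = build_symmetric(subunit, params, SymmetrySpec(symmetry_n))
    ca = asm.ca_coords()
    center = ca.mean(axis=0)
    rot = Rotation.from_euler("ZYZ", best.params[4:7]).as_matrix()
    posed = Structure(
        list(asm.atom_names),
        asm.res_ids.copy(),
        list(asm.chain_ids),
        (asm.coords - center) @ rot.T + map_center + best.params[7:10],
        list(asm.elements),
    )
    ranked = postprocess.RankedModels([(0, posed, best.params[4:10], best.objective)])
    return ProtocolResult(
        "blind_dock", True, "", result, ranked, None, posed, best.params,
        extras={"assembly_frame_structure": asm, "best_ccc": best.objective},
    )


def protocol_crosslink(
    subunit: Structure,
    profile,
    anchor_target: float,
    anchor_tolerance: float = 2.0,
    budget: int = 3000,
    seed: int = 0,
    settings: mvie.MvieSettings | None = None,
    lj: LJParams = LJParams(),
    bounds=None,
) -> ProtocolResult:
    """Homodimer assembly from fractional crosslinking data.

    Constraints: the Cβ–Cβ distance of the most crosslinked residue inside
    ``anchor_target ± anchor_tolerance``, and E_phys < 0.  Objective: the
    magnitude |R| of the Pearson correlation between per-residue
    inter-subunit Cβ distances and crosslink fractions (the signed value is
    reported alongside; the physical expectation is negative).
    """
    residues = profile.residues
    if len(residues) < 3:
        raise ValueError("need at least 3 profiled residues")
    if anchor_target is None:
        raise ValueError("anchor_target (Cβ–Cβ distance, Å) must be given")
    anchor_res = profile.top_residue()
    engine = _AssemblyEngine(subunit, 2, (), lj)
    cb_idx = np.array([engine._atom_index(r, "CB") for r in residues])
    anchor_idx = engine._atom_index(anchor_res, "CB")
    fractions = profile.values()
    if bounds is None:
        bounds = default_bounds(subunit, SymmetrySpec(2))

    def eval_fn(x):
        stacked = engine.copies(*x[:4])
        d = np.linalg.norm(stacked[0, cb_idx] - stacked[1, cb_idx], axis=1)
        anchor_d = float(np.linalg.norm(stacked[0, anchor_idx] - stacked[1, anchor_idx]))
        if np.ptp(d) == 0:
            r_abs = 0.0
        else:
            r_abs = abs(pearson(fractions, d))
        return r_abs, np.array([anchor_d, engine.e_phys(stacked)])

    problem = mvie.Problem(
        bounds.lower,
        bounds.upper,
        eval_fn,
        [
            mvie.Constraint(anchor_target - anchor_tolerance,
                            anchor_target + anchor_tolerance, "anchor"),
            mvie.Constraint(-np.inf, E_PHYS_UPPER, "e_phys"),
        ],
        sense="max",
    )
    result = mvie.run(problem, budget, seed, settings)
    if not result.feasible:
        return _failure("crosslink", result)
    best = result.best
    best_struct = engine.structure(best.params)
    stacked = engine.copies(*best.params[:4])
    d = np.linalg.norm(stacked[0, cb_idx] - stacked[1, cb_idx], axis=1)
    signed_r = pearson(fractions, d) if np.ptp(d) > 0 else 0.0
    table = pd.DataFrame(
        {"residue": residues, "fraction": fractions, "cb_distance": d}
    )
    low_r = abs(signed_r) < 0.5
    return ProtocolResult(
        "crosslink",
        True,
        "low correlation: profile may be uninformative" if low_r else "",
        result,
        None,
        None,
        best_struct,
        best.params,
        extras={
            "abs_r": abs(signed_r),
            "signed_r": signed_r,
            "table": table,
            "low_correlation": low_r,
        },
    )


def protocol_audit(
    subunit: Structure,
    symmetry_n: int,
    true_pool,
    false_pool,
    mixtures=((5, 1), (5, 2), (5, 3), (5, 4)),
    trials: int = 5,
    budget: int = 5000,
    seed: int = 0,
    settings: mvie.MvieSettings | None = None,
    lj: LJParams = LJParams(),
    bounds=None,
    relaxation_ladder=(0.0, 1.0, 2.0, 4.0),
) -> pd.DataFrame:
    """Wrong-constraint audit: PPV of restraint satisfaction per mixture.

    For each mixture (t true, f false restraints) and trial, a seeded
    sample of restraints is optimized with the diversity protocol, treating
    every sampled restraint as a viability constraint.  Contradictory
    restraints usually make full viability unsatisfiable; once the
    boundaries reach zero, the lexicographic survivor selection makes each
    search unit converge to a model violating as few restraints as
    possible, so the returned models (the archive plus the final unit
    incumbents) naturally maximize the number of restraints satisfied.
    Models satisfying the most restraints at the restraints' own intervals
    are selected and their precision PPV = TP/(TP+FP) averaged.  If that
    pool satisfies nothing, the intervals are widened along the relaxation
    ladder until some model satisfies at least one restraint.
    """
    for t, f in mixtures:
        if t > len(true_pool) or f > len(false_pool):
            raise ValueError(f"pool too small for mixture {t}T-{f}F")
    rows = []
    for t, f in mixtures:
        trial_ppvs = []
        for trial in range(trials):
            rng = np.random.default_rng([seed, trial, t, f])
            chosen_t = [true_pool[i] for i in rng.choice(len(true_pool), t, replace=False)]
            chosen_f = [false_pool[i] for i in rng.choice(len(false_pool), f, replace=False)]
            cons = chosen_t + chosen_f
            trial_ppv = np.nan
            for delta in relaxation_ladder:
                widened = [c.widened(delta) for c in cons]
                engine = _AssemblyEngine(subunit, symmetry_n, widened, lj)
                b = bounds or default_bounds(subunit, SymmetrySpec(symmetry_n))

                def eval_fn(x, _engine=engine):
                    stacked = _engine.copies(*x[:4])
                    return None, np.append(
                        _engine.constraint_dists(stacked), _engine.e_phys(stacked)
                    )

                problem = mvie.Problem(
                    b.lower, b.upper, eval_fn, _mvie_constraints(widened),
                    sense="max", diversity_objective=True,
                )
                result = mvie.run(problem, budget, seed + 1000 * trial, settings)
                pool = result.archive + result.unit_bests
                # satisfaction is always judged at the restraints' own
                # intervals, regardless of the widening used for the search
                best_count, best_ppvs = 0, []
                for cand in pool:
                    dists = cand.constraint_values[:-1]
                    sat = constraint_violations(dists, cons) == 0
                    count = int(sat.sum())
                    if count == 0:
                        continue
                    tp = sum(1 for c, s in zip(cons, sat) if s and c.is_true)
                    fp = sum(1 for c, s in zip(cons, sat) if s and not c.is_true)
                    if count > best_count:
                        best_count, best_ppvs = count, []
                    if count == best_count:
                        best_ppvs.append(tp / (tp + fp))
                if best_ppvs:
                    trial_ppv = float(np.mean(best_ppvs))
                    break
            trial_ppvs.append(trial_ppv)
        rows.append(
            {
                "n_true": t,
                "n_false": f,
                "label": f"{t}T-{f}F",
                "mean_ppv": float(np.nanmean(trial_ppvs)) if trial_ppvs else np.nan,
                "ppvs": trial_ppvs,
            }
        )
    return pd.DataFrame(rows)


def protocol_aggregated_reference(
    subunit: Structure,
    symmetry_n: int,
    constraints,
    reference_map: density.DensityMap | None = None,
    w: float = 0.2,
    budget: int = 20_000,
    seed: int = 0,
    settings: mvie.MvieSettings | None = None,
    cluster_threshold: float = 1.0,
    lj: LJParams = LJParams(),
    bounds=None,
    top_k: int = 5,
) -> ProtocolResult:
    """Legacy weighted-sum baseline: unconstrained minimization of
    ``w·E_phys + (1−w)·E_data`` by the same optimizer in single-objective
    mode, with identical clustering/ranking downstream.  Kept only for
    comparison against the viability protocols."""
    engine = _AssemblyEngine(subunit, symmetry_n, constraints, lj)
    if bounds is None:
        bounds = default_bounds(subunit, SymmetrySpec(symmetry_n))
    targets = np.array([c.target for c in constraints])

    def eval_fn(x):
        stacked = engine.copies(*x[:4])
        ep = engine.e_phys(stacked)
        if len(constraints):
            dists = engine.constraint_dists(stacked)
            ed = float(np.sqrt(np.sum((dists - targets) ** 2)))
        else:
            ed = 0.0
        return aggregated_fitness(ep, ed, w), np.empty(0)

    problem = mvie.Problem(bounds.lower, bounds.upper, eval_fn, [], sense="min")
    result = mvie.run(problem, budget, seed, settings)
    report, ranked, best_struct, best_params = _cluster_and_rank(
        problem, engine, result, reference_map, cluster_threshold, top_k
    )
    best_struct = engine.structure(result.best.params)
    return ProtocolResult(
        "aggregated_reference", True, "", result, ranked, report, best_struct,
        result.best.params,
        extras={"best_fitness": result.best.objective, "w": w},
    )
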