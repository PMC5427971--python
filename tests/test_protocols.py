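"""Protocol layer: formulations, guarantees and small-scale behavior.

Full-scale recovery experiments live in the acceptance suite; these tests
exercise the protocol contracts at small budgets.
"""

import numpy as np
import pytest

from viasm import density, postprocess, protocols, scoring, synthetic
from viasm.mvie import MvieSettings
from viasm.protocols import (
    ProtocolConfig,
    _AssemblyEngine,
    protocol_aggregated_reference,
    protocol_blind_dock,
    protocol_ccc_objective,
    protocol_crosslink,
    protocol_diversity,
    protocol_energy_objective,
)
from viasm.scoring import DistanceConstraint

FAST = MvieSettings(n_units=8)


class TestEngineConsistency:
    """The vectorized inner-loop evaluator must agree exactly with the
    reference path (build_symmetric + scoring functions)."""

    def test_matches_structure_path(self, helix_subunit, helix_constraints, rng):
        engine = _AssemblyEngine(helix_subunit, 5, helix_constraints)
        for _ in range(5):
            vec = np.array(
                [rng.uniform(0, 2 * np.pi), rng.uniform(0, 2 * np.pi),
                 rng.uniform(0, 2 * np.pi), rng.uniform(3, 25)]
            )
            stacked = engine.copies(*vec)
            st = engine.structure(vec)
            assert engine.e_phys(stacked) == pytest.approx(
                scoring.e_phys(st), rel=1e-12, abs=1e-12
            )
            np.testing.assert_allclose(
                engine.constraint_dists(stacked),
                scoring.constraint_distances(st, helix_constraints),
                rtol=1e-12,
            )


class TestDiversityProtocol:
    def test_returned_models_satisfy_constraints(
        self, helix_subunit, helix_c5, helix_constraints, helix_map
    ):
        assembly, _ = helix_c5
        res = protocol_diversity(
            helix_subunit, 5, helix_constraints, helix_map,
            budget=4000, seed=0, settings=FAST,
        )
        assert res.success
        # the viability guarantee: every ranked model satisfies everything
        for _, st, _, _ in res.ranked.entries:
            obs = scoring.constraint_distances(st, helix_constraints)
            np.testing.assert_array_equal(
                scoring.constraint_violations(obs, helix_constraints), 0.0
            )
            assert scoring.e_phys(st) < 0

    def test_unsatisfiable_constraints_fail_explicitly(self, helix_subunit):
        impossible = [
            DistanceConstraint(1, 1, "CA", 4.0, 0.1),
            DistanceConstraint(1, 1, "CA", 40.0, 0.1),  # same pair, disjoint
        ]
        res = protocol_diversity(
            helix_subunit, 5, impossible, None, budget=1500, seed=0, settings=FAST
        )
        assert not res.success
        assert "no viable" in res.message

    def test_deterministic(self, helix_subunit, helix_constraints, helix_map):
        r1 = protocol_diversity(helix_subunit, 5, helix_constraints, helix_map,
                                budget=2000, seed=3, settings=FAST)
        r2 = protocol_diversity(helix_subunit, 5, helix_constraints, helix_map,
                                budget=2000, seed=3, settings=FAST)
        assert r1.success == r2.success
        if r1.success:
            np.testing.assert_array_equal(r1.best_params, r2.best_params)


class TestEnergyProtocol:
    def test_beats_feasible_grid(self, helix_subunit):
        """Returned E_phys is at least as low as any feasible coarse grid
        point (4-D brute force oracle on a dimer)."""
        dimer, _ = synthetic.make_reference_assembly(helix_subunit, 2, seed=3)
        cons = synthetic.derive_constraints(dimer, 1, 2.0, seed=3)
        res = protocol_energy_objective(
            helix_subunit, 2, cons, budget=6000, seed=0, settings=FAST
        )
        assert res.success
        engine = _AssemblyEngine(helix_subunit, 2, cons)
        angles = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        radii = np.linspace(2.0, 40.0, 20)
        grid_best = np.inf
        for a in angles:
            for b in angles:
                for g in angles:
                    for x in radii:
                        stacked = engine.copies(a, b, g, x)
                        d = engine.constraint_dists(stacked)
                        if np.all((d >= cons[0].lower) & (d <= cons[0].upper)):
                            grid_best = min(grid_best, engine.e_phys(stacked))
        assert res.extras["best_e_phys"] <= grid_best + 1e-9

    def test_no_constraints_finds_contact(self, helix_subunit):
        res = protocol_energy_objective(
            helix_subunit, 2, [], budget=3000, seed=1, settings=FAST
        )
        assert res.success
        assert res.extras["best_e_phys"] < 0  # subunits found each other


class TestCccObjectiveProtocol:
    def test_recovers_truth_with_one_constraint(
        self, globular_subunit, globular_c5, globular_map
    ):
        assembly, _ = globular_c5
        cons = synthetic.derive_constraints(assembly, 1, 2.0, seed=1)
        res = protocol_ccc_objective(
            globular_subunit, 5, cons, globular_map,
            budget=4000, seed=0, settings=FAST,
        )
        assert res.success
        assert res.extras["best_ccc"] >= 0.95
        rmsd = postprocess.compare_to_reference(res.ranked.best[1], assembly, 5)
        assert rmsd <= 2.0

    def test_small_budget_means_no_refits(
        self, globular_subunit, globular_c5, globular_map
    ):
        assembly, _ = globular_c5
        cons = synthetic.derive_constraints(assembly, 1, 2.0, seed=1)
        res = protocol_ccc_objective(
            globular_subunit, 5, cons, globular_map,
            budget=900, seed=0, settings=FAST, refit_every=1000,
        )
        assert res.extras.get("n_refits", 0) == 0


class TestBlindDock:
    def test_single_subunit_pose_recovery(self, globular_subunit):
        m = density.simulate_map(globular_subunit, 15.0)
        res = protocol_blind_dock(
            globular_subunit, 1, m, budget=3000, seed=0, settings=FAST
        )
        assert res.success
        from viasm.structio import rmsd_superposed

        rmsd = rmsd_superposed(
            res.best_structure.ca_coords(), globular_subunit.ca_coords()
        )
        assert rmsd <= m.voxel  # within one voxel-equivalent

    def test_energy_constraint_enforced(self, globular_subunit, globular_map):
        res = protocol_blind_dock(
            globular_subunit, 5, globular_map, budget=4000, seed=0, settings=FAST
        )
        if res.success:
            assert scoring.e_phys(res.extras["assembly_frame_structure"]) < 0


class TestCrosslinkProtocol:
    def test_informative_profile_recovers_interface(
        self, helix_subunit, helix_dimer, dimer_profile
    ):
        assembly, _ = helix_dimer
        chains = assembly.chains
        anchor = dimer_profile.top_residue()
        anchor_d = float(np.linalg.norm(
            assembly.atom_xyz(chains[0], anchor, "CB")
            - assembly.atom_xyz(chains[1], anchor, "CB")
        ))
        res = protocol_crosslink(
            helix_subunit, dimer_profile, anchor_d, 2.0,
            budget=3000, seed=0, settings=FAST,
        )
        assert res.success
        assert res.extras["abs_r"] >= 0.9
        rmsd = postprocess.compare_to_reference(res.best_structure, assembly, 2)
        assert rmsd <= 2.0
        # per-residue table is returned for plotting/inspection
        assert set(res.extras["table"].columns) == {
            "residue", "fraction", "cb_distance"
        }

    def test_uninformative_profile_scores_lower(
        self, helix_subunit, helix_dimer, dimer_profile
    ):
        """Shuffled fractions (geometry-independent) cannot reach the
        informative profile's correlation."""
        assembly, _ = helix_dimer
        chains = assembly.chains
        rng = np.random.default_rng(1)
        shuffled = scoring.CrosslinkProfile(
            dict(zip(dimer_profile.residues,
                     rng.permutation(dimer_profile.values())))
        )
        anchor = shuffled.top_residue()
        anchor_d = float(np.linalg.norm(
            assembly.atom_xyz(chains[0], anchor, "CB")
            - assembly.atom_xyz(chains[1], anchor, "CB")
        ))
        res = protocol_crosslink(
            helix_subunit, shuffled, anchor_d, 2.0,
            budget=3000, seed=0, settings=FAST,
        )
        informative = protocol_crosslink(
            helix_subunit, dimer_profile, anchor_d, 2.0,
            budget=3000, seed=0, settings=FAST,
        )
        if res.success and informative.success:
            assert res.extras["abs_r"] < informative.extras["abs_r"]

    def test_tiny_profile_rejected(self, helix_subunit):
        prof = scoring.CrosslinkProfile({1: 0.9, 2: 0.5})
        with pytest.raises(ValueError):
            protocol_crosslink(helix_subunit, prof, 8.0, 2.0, budget=500)


class TestAggregatedReference:
    def test_weight_limits(self, helix_subunit, helix_constraints):
        """w=1 reduces to pure E_phys minimization; w=0 to pure E_data."""
        res_phys = protocol_aggregated_reference(
            helix_subunit, 5, helix_constraints, w=1.0,
            budget=2000, seed=0, settings=FAST,
        )
        st = res_phys.best_structure
        assert res_phys.extras["best_fitness"] == pytest.approx(
            scoring.e_phys(st), rel=1e-9
        )
        res_data = protocol_aggregated_reference(
            helix_subunit, 5, helix_constraints, w=0.0,
            budget=2000, seed=0, settings=FAST,
        )
        st = res_data.best_structure
        obs = scoring.constraint_distances(st, helix_constraints)
        targets = [c.target for c in helix_constraints]
        assert res_data.extras["best_fitness"] == pytest.approx(
            scoring.e_data(obs, targets), rel=1e-9, abs=1e-9
        )


class TestConfig:
    def test_mode_validation(self):
        with pytest.raises(ValueError, match="unknown mode"):
            ProtocolConfig(mode="nonsense")

    def test_mode_requirements(self):
        with pytest.raises(ValueError, match="map"):
            ProtocolConfig(mode="blind_dock")
        with pytest.raises(ValueError, match="profile"):
            ProtocolConfig(mode="crosslink")
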