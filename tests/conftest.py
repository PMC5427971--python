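"""Shared fixtures: all test inputs are generated programmatically."""

import numpy as np
import pytest

from viasm import density, synthetic


@pytest.fixture(scope="session")
def helix_subunit():
    return synthetic.make_toy_subunit(synthetic.ToySpec(20, "helix", 0))


@pytest.fixture(scope="session")
def globular_subunit():
    return synthetic.make_toy_subunit(synthetic.ToySpec(24, "compact-random", 0))


@pytest.fixture(scope="session")
def helix_c5(helix_subunit):
    """Ground-truth C5 ring of the helix toy: (assembly, params)."""
    return synthetic.make_reference_assembly(helix_subunit, 5, seed=1)


@pytest.fixture(scope="session")
def globular_c5(globular_subunit):
    return synthetic.make_reference_assembly(globular_subunit, 5, seed=1)


@pytest.fixture(scope="session")
def helix_constraints(helix_c5):
    assembly, _ = helix_c5
    return synthetic.derive_constraints(assembly, 3, 2.0, seed=1)


@pytest.fixture(scope="session")
def helix_map(helix_c5):
    assembly, _ = helix_c5
    return density.simulate_map(assembly, 15.0)


@pytest.fixture(scope="session")
def globular_map(globular_c5):
    assembly, _ = globular_c5
    return density.simulate_map(assembly, 15.0)


@pytest.fixture(scope="session")
def helix_dimer(helix_subunit):
    return synthetic.make_reference_assembly(helix_subunit, 2, seed=3)


@pytest.fixture(scope="session")
def dimer_profile(helix_dimer, helix_subunit):
    assembly, _ = helix_dimer
    residues = sorted({int(r) for r in helix_subunit.res_ids})[:16]
    return synthetic.synth_crosslink_profile(assembly, residues, noise_sd=0.05, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
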