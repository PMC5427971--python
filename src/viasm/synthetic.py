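"""Synthetic fixtures: toy subunits, ground-truth rings, restraints, profiles.

Everything needed to exercise the full assembly protocol is generated
programmatically — toy Cα/Cβ subunits, ground-truth Cn assemblies with
known parameters, true and deliberately wrong distance restraints, and
noisy fractional-crosslinking profiles.  Every generator is a pure
function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .assembly import AssemblyParams, SymmetrySpec, build_symmetric
from .scoring import CrosslinkProfile, DistanceConstraint, LJParams, e_phys
from .structio import Structure

__all__ = [
    "ToySpec",
    "make_toy_subunit",
    "make_reference_assembly",
    "derive_constraints",
    "derive_wrong_constraints",
    "synth_crosslink_profile",
]

#: Minimum Cα–Cα separation (Å), the physical lower bound for protein traces.
MIN_SEPARATION = 3.8
#: Pseudo-Cβ offset from Cα (Å), along a fixed per-residue local direction.
CB_OFFSET = 1.5

# ideal α-helix trace parameters
HELIX_RISE = 1.5
HELIX_TWIST = np.deg2rad(100.0)
HELIX_RADIUS = 2.3


@dataclass
class ToySpec:
    """Specification of a toy subunit."""

    n_residues: int = 20
    geometry: str = "helix"  # "helix" | "compact-random"
    seed: int = 0

    def __post_init__(self):
        if self.n_residues < 5:
            raise ValueError("need at least 5 residues")
        if self.geometry not in ("helix", "compact-random"):
            raise ValueError(f"unknown geometry {self.geometry!r}")


def _with_cb(ca: np.ndarray, cb_dirs: np.ndarray, chain: str = "A") -> Structure:
    """Interleave CA/CB atoms into a Structure (Cβ = Cα + 1.5 Å × direction)."""
    n = len(ca)
    cb = ca + CB_OFFSET * cb_dirs
    names, rids, coords = [], [], []
    for i in range(n):
        names += ["CA", "CB"]
        rids += [i + 1, i + 1]
        coords += [ca[i], cb[i]]
    return Structure(names, np.array(rids), [chain] * (2 * n), np.array(coords),
                     ["C"] * (2 * n))


def make_toy_subunit(spec: ToySpec) -> Structure:
    """Generate a deterministic toy subunit (Cα trace + pseudo-Cβ).

    ``helix``: ideal α-helix trace (rise 1.5 Å, 100°/residue, radius
    2.3 Å), Cβ pointing radially outward.  ``compact-random``: a
    self-avoiding chain of 3.8 Å steps biased toward its running centroid,
    rejection-sampled to keep all pairs ≥ 3.8 Å apart.
    """
    n = spec.n_residues
    if spec.geometry == "helix":
        t = np.arange(n)
        ca = np.column_stack(
            [
                HELIX_RADIUS * np.cos(HELIX_TWIST * t),
                HELIX_RADIUS * np.sin(HELIX_TWIST * t),
                HELIX_RISE * t,
            ]
        )
        dirs = np.column_stack(
            [np.cos(HELIX_TWIST * t), np.sin(HELIX_TWIST * t), np.zeros(n)]
        )
        return _with_cb(ca - ca.mean(axis=0), dirs)

    rng = np.random.default_rng([spec.seed, 77])
    for _restart in range(50):
        ca = [np.zeros(3)]
        ok = True
        for _i in range(1, n):
            placed = False
            centroid = np.mean(ca, axis=0)
            for _try in range(200):
                d = rng.standard_normal(3)
                pull = centroid - ca[-1]
                pn = np.linalg.norm(pull)
                if pn > 1e-9:
                    d = d / np.linalg.norm(d) + 0.4 * pull / pn
                d /= np.linalg.norm(d)
                cand = ca[-1] + MIN_SEPARATION * d
                if len(ca) < 2 or np.min(
                    np.linalg.norm(np.array(ca[:-1]) - cand, axis=1)
                ) >= MIN_SEPARATION - 1e-9:
                    ca.append(cand)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            ca = np.array(ca)
            centroid = ca.mean(axis=0)
            dirs = ca - centroid
            norms = np.linalg.norm(dirs, axis=1, keepdims=True)
            dirs = np.where(norms > 1e-9, dirs / np.maximum(norms, 1e-9),
                            np.array([0.0, 0.0, 1.0]))
            return _with_cb(ca - centroid, dirs)
    raise RuntimeError("could not generate a self-avoiding toy subunit")


def make_reference_assembly(
    subunit: Structure,
    n: int,
    seed: int = 0,
    lj: LJParams = LJParams(),
) -> tuple:
    """Ground-truth Cn assembly with a random orientation and a contact radius.

    The radius is the smallest x (0.25 Å line search) giving an assembly
    with negative steric energy and no inter-subunit Cα pair closer than
    3.0 Å — subunits in contact but not clashing.  Returns
    ``(assembly, params)``; rebuilding from ``params`` reproduces the
    assembly exactly.
    """
    if n < 2:
        raise ValueError("need n >= 2 for a reference assembly")
    rng = np.random.default_rng([seed, 11])
    angles = rng.uniform(0.0, 2.0 * np.pi, size=3)
    sym = SymmetrySpec(n)
    sub_r = np.max(np.linalg.norm(subunit.coords - subunit.centroid(), axis=1))
    for x in np.arange(0.5, 6.0 * sub_r * n, 0.25):
        params = AssemblyParams(*angles, x=float(x))
        asm = build_symmetric(subunit, params, sym)
        chains = asm.chains
        d01 = cdist(asm.ca_coords(chains[0]), asm.ca_coords(chains[1]))
        if d01.min() < 3.0:
            continue
        # non-adjacent copies must not clash either
        min_all = min(
            cdist(asm.ca_coords(chains[i]), asm.ca_coords(chains[j])).min()
            for i in range(n)
            for j in range(i + 1, n)
        )
        if min_all < 3.0:
            continue
        if d01.min() <= lj.cutoff and e_phys(asm, lj) < 0:
            return asm, params
    raise RuntimeError("no contact radius found for this subunit")


def _interface_pairs(assembly: Structure, max_dist: float = 8.0):
    """Cross-interface Cα residue pairs (copy 0 vs copy 1) within max_dist."""
    chains = assembly.chains
    a, b = chains[0], chains[1]
    ca_a, ca_b = assembly.chain(a), assembly.chain(b)
    ra = [int(r) for r, nm in zip(ca_a.res_ids, ca_a.atom_names) if nm == "CA"]
    rb = [int(r) for r, nm in zip(ca_b.res_ids, ca_b.atom_names) if nm == "CA"]
    d = cdist(ca_a.ca_coords(), ca_b.ca_coords())
    pairs = []
    for i, ri in enumerate(ra):
        for j, rj in enumerate(rb):
            if d[i, j] < max_dist:
                pairs.append((ri, rj, float(d[i, j])))
    return pairs, d, ra, rb


def derive_constraints(
    assembly: Structure, k: int, tolerance: float = 2.0, seed: int = 0
) -> list:
    """Sample k true restraints from interfacial Cα pairs closer than 8 Å.

    Targets equal the true distances, so the ground-truth assembly
    satisfies every derived restraint with zero violation.
    """
    pairs, _, _, _ = _interface_pairs(assembly, 8.0)
    if len(pairs) < k:
        raise ValueError(f"interface too sparse: {len(pairs)} pairs < k={k}")
    rng = np.random.default_rng([seed, 23])
    idx = rng.choice(len(pairs), size=k, replace=False)
    return [
        DistanceConstraint(pairs[i][0], pairs[i][1], "CA", pairs[i][2], tolerance, True)
        for i in sorted(int(i) for i in idx)
    ]


def derive_wrong_constraints(
    assembly: Structure, k: int, tolerance: float = 2.0, seed: int = 0
) -> list:
    """Sample k wrong restraints: plausible contact targets (6 Å ± tolerance)
    assigned to pairs whose true distance exceeds the interval's upper bound
    by at least 5 Å, so native geometry violates every one of them."""
    target = 6.0
    margin = 5.0
    chains = assembly.chains
    ca_a = assembly.chain(chains[0])
    ca_b = assembly.chain(chains[1])
    ra = [int(r) for r, nm in zip(ca_a.res_ids, ca_a.atom_names) if nm == "CA"]
    rb = [int(r) for r, nm in zip(ca_b.res_ids, ca_b.atom_names) if nm == "CA"]
    d = cdist(ca_a.ca_coords(), ca_b.ca_coords())
    far = [
        (ra[i], rb[j])
        for i in range(len(ra))
        for j in range(len(rb))
        if d[i, j] >= target + tolerance + margin
    ]
    if len(far) < k:
        raise ValueError("cannot find sufficiently wrong residue pairs")
    rng = np.random.default_rng([seed, 29])
    idx = rng.choice(len(far), size=k, replace=False)
    return [
        DistanceConstraint(far[i][0], far[i][1], "CA", target, tolerance, False)
        for i in sorted(int(i) for i in idx)
    ]


def synth_crosslink_profile(
    assembly: Structure,
    residues,
    noise_sd: float = 0.05,
    seed: int = 0,
    d0: float = 12.0,
    scale: float = 3.0,
) -> CrosslinkProfile:
    """Noisy fractional-crosslinking profile of a homodimer interface.

    ``fraction_i = clamp(logistic((d0 − d_i)/scale) + N(0, noise_sd), 0, 1)``
    with ``d_i`` the inter-subunit Cβ–Cβ distance of residue i — shorter
    distances crosslink more, mimicking disulfide scanning data.
    """
    chains = assembly.chains
    if len(chains) != 2:
        raise ValueError("crosslink profiles require a dimer")
    rng = np.random.default_rng([seed, 37])
    fractions = {}
    for r in residues:
        pa = assembly.atom_xyz(chains[0], int(r), "CB")
        pb = assembly.atom_xyz(chains[1], int(r), "CB")
        d = float(np.linalg.norm(pa - pb))
        f = 1.0 / (1.0 + np.exp(-(d0 - d) / scale))
        if noise_sd > 0:
            f += rng.normal(0.0, noise_sd)
        fractions[int(r)] = float(np.clip(f, 0.0, 1.0))
    return CrosslinkProfile(fractions)
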