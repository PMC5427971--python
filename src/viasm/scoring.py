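"""Scalar scores and constraints for assembly prediction.

Implements the coarse 9-6 Lennard-Jones inter-subunit potential (E_phys),
the restraint-deviation norm (E_data), the weighted aggregate of the two
(the legacy single-objective fitness), population diversity, precision
(PPV) of restraint satisfaction, Pearson correlation, and the crosslink
correlation objective used for homodimer interface reconstruction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr

from .structio import SelectionError, Structure

__all__ = [
    "DistanceConstraint",
    "LJParams",
    "CrosslinkProfile",
    "lj_96",
    "e_phys",
    "constraint_distances",
    "constraint_violations",
    "e_data",
    "aggregated_fitness",
    "diversity",
    "ppv",
    "pearson",
    "crosslink_objective",
    "read_constraints",
    "write_constraints",
    "read_crosslink_profile",
    "write_crosslink_profile",
]


@dataclass
class DistanceConstraint:
    """An inter-subunit residue–residue distance restraint.

    The distance is measured between ``atom_type`` atoms of residue
    ``residue_a`` on subunit copy 0 and ``residue_b`` on the adjacent copy 1
    (cyclic symmetry makes all adjacent interfaces equivalent).  The
    restraint is satisfied when the observed distance lies in
    ``[target - tolerance, target + tolerance]``.

    ``is_true`` is an optional ground-truth label used only by the
    wrong-constraint audit.
    """

    residue_a: int
    residue_b: int
    atom_type: str = "CA"
    target: float = 0.0
    tolerance: float = 2.0
    is_true: bool | None = None

    def __post_init__(self):
        if self.target <= 0:
            raise ValueError(f"target distance must be positive, got {self.target}")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        if self.atom_type not in ("CA", "CB"):
            raise ValueError(f"atom_type must be CA or CB, got {self.atom_type}")

    @property
    def lower(self) -> float:
        return self.target - self.tolerance

    @property
    def upper(self) -> float:
        return self.target + self.tolerance

    def widened(self, delta: float) -> "DistanceConstraint":
        """Copy with the tolerance widened by ``delta`` Å (audit relaxation)."""
        return DistanceConstraint(
            self.residue_a,
            self.residue_b,
            self.atom_type,
            self.target,
            self.tolerance + delta,
            self.is_true,
        )


@dataclass
class LJParams:
    """9-6 Lennard-Jones parameters: σ = 4.7 Å, ε = 1 kcal/mol, 12 Å cutoff."""

    sigma: float = 4.7
    epsilon: float = 1.0
    cutoff: float = 12.0

    def __post_init__(self):
        if min(self.sigma, self.epsilon, self.cutoff) <= 0:
            raise ValueError("LJ parameters must be positive")


@dataclass
class CrosslinkProfile:
    """Residue index -> fraction crosslinked (disulfide scanning data)."""

    fractions: dict = field(default_factory=dict)

    def __post_init__(self):
        for r, f in self.fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction for residue {r} outside [0,1]: {f}")

    @property
    def residues(self) -> list:
        return sorted(self.fractions)

    def values(self) -> np.ndarray:
        return np.array([self.fractions[r] for r in self.residues])

    def top_residue(self) -> int:
        """Residue with the highest crosslinking degree (anchor candidate)."""
        return max(self.fractions, key=lambda r: (self.fractions[r], -r))


# ----------------------------------------------------------------------
# Energies
# ----------------------------------------------------------------------

def lj_96(r, params: LJParams = LJParams()):
    """9-6 Lennard-Jones: ``4ε[(σ/r)^9 − (σ/r)^6]``, truncated at the cutoff.

    Zero at r = σ, minimum −16ε/27 at r = σ(3/2)^(1/3), 0 beyond the cutoff
    (plain truncation, not shifted; the ≈ −0.0136 kcal/mol discontinuity at
    12 Å is accepted as in typical coarse scoring).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distances must be positive")
    s = params.sigma / r
    e = 4.0 * params.epsilon * (s**9 - s**6)
    return np.where(r >= params.cutoff, 0.0, e) if e.ndim else (
        0.0 if r >= params.cutoff else float(e)
    )


def e_phys(assembly: Structure, params: LJParams = LJParams()) -> float:
    """Summed 9-6 LJ over all unique inter-subunit Cα pairs within the cutoff.

    All copy pairs count, not just adjacent ones: in closed rings a subunit
    can clash with any other copy.  Intra-subunit pairs are excluded.
    """
    chains = assembly.chains
    if len(chains) < 2:
        warnings.warn("single-subunit assembly: E_phys = 0")
        return 0.0
    cas = [assembly.ca_coords(c) for c in chains]
    total = 0.0
    for i in range(len(chains)):
        for j in range(i + 1, len(chains)):
            d = cdist(cas[i], cas[j])
            close = d[(d > 0) & (d < params.cutoff)]
            if close.size:
                s = params.sigma / close
                total += float(np.sum(4.0 * params.epsilon * (s**9 - s**6)))
    return total


# ----------------------------------------------------------------------
# Restraints
# ----------------------------------------------------------------------

def constraint_distances(assembly: Structure, constraints) -> np.ndarray:
    """Observed distance o_i of every restraint in the assembly model.

    Measured between copy 0 (first chain) and copy 1 (second chain).
    """
    chains = assembly.chains
    if len(chains) < 2:
        raise ValueError("assembly needs at least 2 subunit copies")
    out = np.empty(len(constraints))
    for k, c in enumerate(constraints):
        try:
            pa = assembly.atom_xyz(chains[0], c.residue_a, c.atom_type)
            pb = assembly.atom_xyz(chains[1], c.residue_b, c.atom_type)
        except SelectionError as exc:
            raise SelectionError(
                f"constraint {k} ({c.residue_a}-{c.residue_b} {c.atom_type}): {exc}"
            ) from exc
        out[k] = np.linalg.norm(pa - pb)
    return out


def constraint_violations(observed, constraints) -> np.ndarray:
    """Interval violation ``max(0, l−o, o−u)`` per restraint."""
    observed = np.asarray(observed, dtype=float)
    lo = np.array([c.lower for c in constraints])
    up = np.array([c.upper for c in constraints])
    return np.maximum(0.0, np.maximum(lo - observed, observed - up))


def e_data(observed, targets) -> float:
    """Root of the summed squared restraint deviations: ``sqrt(Σ(o_i−t_i)²)``."""
    observed = np.asarray(observed, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if observed.shape != targets.shape or observed.size < 1:
        raise ValueError("observed and target lists must have equal length >= 1")
    return float(np.sqrt(np.sum((observed - targets) ** 2)))


def aggregated_fitness(e_phys_value: float, e_data_value: float, w: float = 0.2) -> float:
    """Legacy single-objective fitness ``w·E_phys + (1−w)·E_data`` (w = 0.2).

    Kept only as a comparison baseline; the viability protocol never
    aggregates the two terms.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"weight must be in [0,1], got {w}")
    return w * e_phys_value + (1.0 - w) * e_data_value


# ----------------------------------------------------------------------
# Diversity, audits, correlations
# ----------------------------------------------------------------------

def diversity(x_t, population) -> float:
    """Population diversity of a candidate: ``sqrt(Σ_i ||x_t − X_i||²) / n``.

    Vectors must be expressed in the normalized unit box so that angle and
    radius coordinates are commensurate.
    """
    pop = np.atleast_2d(np.asarray(population, dtype=float))
    if pop.size == 0:
        raise ValueError("empty population")
    x_t = np.asarray(x_t, dtype=float)
    if x_t.shape != pop.shape[1:]:
        raise ValueError("dimension mismatch between candidate and population")
    sq = np.sum((pop - x_t) ** 2)
    return float(np.sqrt(sq) / len(pop))


def ppv(tp: int, fp: int) -> float:
    """Precision of restraint satisfaction: TP / (TP + FP)."""
    if tp < 0 or fp < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp == 0:
        raise ValueError("PPV undefined: no satisfied constraints")
    return tp / (tp + fp)


def pearson(x, y) -> float:
    """Product-moment correlation; raises on zero variance or n < 3."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length samples of at least 3 values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(pearsonr(x, y).statistic)


def crosslink_objective(assembly: Structure, profile: CrosslinkProfile):
    """Correlation between inter-subunit Cβ distances and crosslink fractions.

    For every profiled residue the Cβ–Cβ distance between the two copies of
    that residue is measured; the unsigned magnitude |R| of the Pearson
    correlation against the crosslinking fractions is the objective to be
    maximized (the physically expected sign is negative — more crosslinked
    residues sit closer — and the signed value is returned alongside).

    Returns ``(abs_r, signed_r, distances)``.
    """
    residues = profile.residues
    if len(residues) < 3:
        raise ValueError("need at least 3 profiled residues")
    chains = assembly.chains
    if len(chains) < 2:
        raise ValueError("crosslink objective needs a dimer")
    d = np.empty(len(residues))
    for i, r in enumerate(residues):
        pa = assembly.atom_xyz(chains[0], r, "CB")
        pb = assembly.atom_xyz(chains[1], r, "CB")
        d[i] = np.linalg.norm(pa - pb)
    r_val = pearson(profile.values(), d)
    return abs(r_val), r_val, d


# ----------------------------------------------------------------------
# Text-table I/O
# ----------------------------------------------------------------------

_CONSTRAINT_HEADER = "# viasm constraints v1: residue_a residue_b atom_type target tolerance [truth]"
_PROFILE_HEADER = "# viasm crosslink profile v1: residue fraction"


def write_constraints(constraints, path) -> None:
    with open(path, "w") as fh:
        fh.write(_CONSTRAINT_HEADER + "\n")
        for c in constraints:
            line = f"{c.residue_a} {c.residue_b} {c.atom_type} {c.target:.4f} {c.tolerance:.4f}"
            if c.is_true is not None:
                line += " " + ("true" if c.is_true else "false")
            fh.write(line + "\n")


def read_constraints(path) -> list:
    out = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (5, 6):
                raise ValueError(f"{path}:{ln}: expected 5 or 6 fields, got {len(parts)}")
            label = None
            if len(parts) == 6:
                label = parts[5].lower() in ("true", "1", "t")
            out.append(
                DistanceConstraint(
                    int(parts[0]), int(parts[1]), parts[2],
                    float(parts[3]), float(parts[4]), label,
                )
            )
    return out


def write_crosslink_profile(profile: CrosslinkProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write(_PROFILE_HEADER + "\n")
        for r in profile.residues:
            fh.write(f"{r} {profile.fractions[r]:.4f}\n")


def read_crosslink_profile(path) -> CrosslinkProfile:
    fractions = {}
    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 'residue fraction'")
            fractions[int(parts[0])] = float(parts[1])
    return CrosslinkProfile(fractions)
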