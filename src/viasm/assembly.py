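"""Cn-symmetric assembly construction from single-subunit parameters.

A whole cyclic complex is generated from four numbers: three Euler angles
``(alpha, beta, gamma)`` orienting one subunit and the ring radius ``x``.
The subunit is centered on its Cα centroid, rotated, translated to
``(x, 0, 0)`` and replicated by rotations of ``2*pi*k/n`` about the z axis.
Blind-dock mode adds a 6-dof global pose of the finished ring.

Conventions (frozen for reproducibility): intrinsic ZYZ right-handed Euler
angles applied about the subunit centroid; symmetry axis is z through the
origin; first copy sits on +x.  Angles are radians internally (the CLI
accepts degrees).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .structio import CHAIN_ALPHABET, Structure, concatenate

__all__ = [
    "AssemblyParams",
    "SymmetrySpec",
    "ParameterBounds",
    "build_symmetric",
    "apply_global_pose",
    "default_bounds",
]

TWO_PI = 2.0 * np.pi


@dataclass
class AssemblyParams:
    """Search parameters of one subunit placement.

    alpha, beta, gamma : radians, reduced to [0, 2π)
    x : ring radius in Å (≥ 0)
    global_pose : optional (rx, ry, rz, tx, ty, tz) — rotation angles
        (radians, intrinsic ZYZ) and translation (Å) applied to the whole
        assembly in blind-dock mode.
    """

    alpha: float
    beta: float
    gamma: float
    x: float
    global_pose: tuple | None = None

    def __post_init__(self):
        if not np.isfinite([self.alpha, self.beta, self.gamma, self.x]).all():
            raise ValueError("non-finite assembly parameters")
        if self.x < 0:
            raise ValueError(f"radius must be >= 0, got {self.x}")
        self.alpha = float(self.alpha) % TWO_PI
        self.beta = float(self.beta) % TWO_PI
        self.gamma = float(self.gamma) % TWO_PI
        self.x = float(self.x)

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma, self.x])


@dataclass
class SymmetrySpec:
    """Cyclic symmetry about the z axis through the origin."""

    n_subunits: int

    def __post_init__(self):
        if int(self.n_subunits) < 1:
            raise ValueError("n_subunits must be >= 1")
        self.n_subunits = int(self.n_subunits)


@dataclass
class ParameterBounds:
    """Box constraints for the four assembly parameters (normalized search)."""

    lower: np.ndarray = field(default_factory=lambda: np.zeros(4))
    upper: np.ndarray = field(default_factory=lambda: np.array([TWO_PI] * 3 + [100.0]))

    def __post_init__(self):
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if np.any(self.upper <= self.lower):
            raise ValueError("upper bounds must exceed lower bounds")


def _euler_zyz(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Rotation matrix for intrinsic ZYZ angles."""
    return Rotation.from_euler("ZYZ", [alpha, beta, gamma]).as_matrix()


def build_symmetric(
    subunit: Structure, params: AssemblyParams, sym: SymmetrySpec
) -> Structure:
    """Build the Cn assembly implied by ``params``.

    Returns a structure with ``n * subunit.n_atoms`` atoms, one chain ID per
    copy (A, B, C, ... from :data:`CHAIN_ALPHABET`).
    """
    if subunit.n_atoms == 0:
        raise ValueError("empty subunit")
    n = sym.n_subunits
    if n > len(CHAIN_ALPHABET):
        raise ValueError(f"n={n} exceeds available chain IDs")
    rot = _euler_zyz(params.alpha, params.beta, params.gamma)
    center = subunit.centroid()
    base = (subunit.coords - center) @ rot.T + np.array([params.x, 0.0, 0.0])
    copies = []
    for k in range(n):
        ang = TWO_PI * k / n
        c, s = np.cos(ang), np.sin(ang)
        rz = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        copies.append(
            Structure(
                list(subunit.atom_names),
                subunit.res_ids.copy(),
                [CHAIN_ALPHABET[k]] * subunit.n_atoms,
                base @ rz.T,
                list(subunit.elements),
            )
        )
    asm = concatenate(copies)
    if params.global_pose is not None:
        asm = apply_global_pose(asm, params.global_pose)
    return asm


def apply_global_pose(assembly: Structure, pose) -> Structure:
    """Rigid 6-dof transform of a whole assembly (blind-dock mode).

    ``pose`` is (rx, ry, rz, tx, ty, tz): intrinsic ZYZ rotation about the
    assembly's Cα centroid followed by a translation.  Inter-atomic
    distances are preserved exactly.
    """
    pose = np.asarray(pose, dtype=float)
    if pose.shape != (6,) or not np.all(np.isfinite(pose)):
        raise ValueError("pose must be 6 finite numbers")
    rot = _euler_zyz(*pose[:3])
    center = assembly.centroid()
    return Structure(
        list(assembly.atom_names),
        assembly.res_ids.copy(),
        list(assembly.chain_ids),
        (assembly.coords - center) @ rot.T + center + pose[3:],
        list(assembly.elements),
    )


def bounding_radius(subunit: Structure) -> float:
    """Radius of the bounding sphere about the Cα centroid."""
    d = subunit.coords - subunit.centroid()
    return float(np.sqrt(np.max(np.sum(d * d, axis=1))))


def default_bounds(
    subunit: Structure, sym: SymmetrySpec, x_max: float | None = None
) -> ParameterBounds:
    """Default search box: full angle ranges, radius up to
    ``2 * bounding-sphere radius * n`` (override with ``x_max``)."""
    if subunit.n_atoms == 0:
        raise ValueError("empty subunit")
    if x_max is None:
        x_max = 2.0 * bounding_radius(subunit) * sym.n_subunits
    return ParameterBounds(
        lower=np.zeros(4),
        upper=np.array([TWO_PI, TWO_PI, TWO_PI, float(x_max)]),
    )
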