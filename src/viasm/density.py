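"""Density-map simulation, cross-correlation scoring and rigid-body fitting.

Maps are simulated from Cα positions as sums of unit-weight isotropic
Gaussians whose FWHM equals the nominal resolution (kernel truncated at
3σ).  Model/map agreement is the Pearson cross-correlation coefficient
(ccc) over occupied voxels, optionally after a discrete Laplacian filter
that sharpens shape boundaries for low-resolution maps.  Fitting is a
deterministic multistart local search over the 6 rigid degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np
from scipy import ndimage
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .structio import Structure

__all__ = [
    "DensityMap",
    "simulate_map",
    "render_on_grid",
    "ccc",
    "laplace_filter",
    "fit_to_map",
    "read_map",
    "write_map",
]

#: FWHM = 2 sqrt(2 ln 2) σ
FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))
#: ccc floor: voxels where either map exceeds 1e-6 × its maximum participate
CCC_FLOOR = 1e-6


@dataclass
class DensityMap:
    """Regular 3-D scalar grid.

    ``grid[i, j, k]`` sits at ``origin + voxel * (i, j, k)`` (Å); spacing is
    isotropic.  ``resolution`` is the nominal resolution label in Å (None
    for maps read from files that do not store one).
    """

    origin: np.ndarray
    voxel: float
    grid: np.ndarray
    resolution: float | None = None

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.grid = np.asarray(self.grid, dtype=float)
        if self.voxel <= 0:
            raise ValueError("voxel spacing must be positive")
        if self.grid.ndim != 3 or self.grid.size == 0:
            raise ValueError("grid must be a non-empty 3-D array")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("grid contains non-finite values")

    @property
    def shape(self) -> tuple:
        return self.grid.shape

    def center(self) -> np.ndarray:
        """Geometric center of the grid box (Å)."""
        return self.origin + self.voxel * (np.array(self.shape) - 1) / 2.0

    def center_of_mass(self) -> np.ndarray:
        """Intensity-weighted center (falls back to box center if empty)."""
        total = self.grid.sum()
        if total <= 0:
            return self.center()
        idx = np.array(ndimage.center_of_mass(self.grid))
        return self.origin + self.voxel * idx

    def same_geometry(self, other: "DensityMap") -> bool:
        return (
            self.shape == other.shape
            and abs(self.voxel - other.voxel) < 1e-9
            and np.allclose(self.origin, other.origin, atol=1e-6)
        )


def _kernel_sigma(resolution: float) -> float:
    return resolution / FWHM_FACTOR


def render_on_grid(
    coords: np.ndarray,
    origin: np.ndarray,
    voxel: float,
    shape: tuple,
    sigma: float,
) -> np.ndarray:
    """Sum of unit Gaussians (truncated at 3σ) rasterized on a given grid."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    grid = np.zeros(shape)
    rcut = 3.0 * sigma
    rvox = int(np.ceil(rcut / voxel))
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    nx, ny, nz = shape
    for p in coords:
        fidx = (p - origin) / voxel
        lo = np.maximum(np.ceil(fidx - rvox).astype(int), 0)
        hi = np.minimum(np.floor(fidx + rvox).astype(int), [nx - 1, ny - 1, nz - 1])
        if np.any(lo > hi):
            continue
        ax = (np.arange(lo[0], hi[0] + 1) - fidx[0]) * voxel
        ay = (np.arange(lo[1], hi[1] + 1) - fidx[1]) * voxel
        az = (np.arange(lo[2], hi[2] + 1) - fidx[2]) * voxel
        d2 = (
            ax[:, None, None] ** 2
            + ay[None, :, None] ** 2
            + az[None, None, :] ** 2
        )
        block = np.exp(-d2 * inv2s2)
        block[d2 > rcut * rcut] = 0.0
        grid[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] += block
    return grid


def simulate_map(
    structure: Structure, resolution: float, voxel: float | None = None
) -> DensityMap:
    """Simulate a density map from the Cα trace at a nominal resolution.

    The kernel is an isotropic Gaussian with FWHM equal to ``resolution``,
    truncated at 3σ; the grid pads the structure's bounding box by 3σ.
    Default voxel spacing is ``resolution / 3`` (15 Å → 5 Å voxels).
    """
    if structure.n_atoms == 0:
        raise ValueError("empty structure")
    if voxel is None:
        voxel = resolution / 3.0
    if resolution < 2.0 * voxel:
        raise ValueError(
            f"resolution {resolution} Å below Nyquist limit 2×voxel = {2 * voxel} Å"
        )
    ca = structure.ca_coords()
    sigma = _kernel_sigma(resolution)
    pad = 3.0 * sigma
    lo = ca.min(axis=0) - pad
    hi = ca.max(axis=0) + pad
    shape = tuple(np.ceil((hi - lo) / voxel).astype(int) + 1)
    grid = render_on_grid(ca, lo, voxel, shape, sigma)
    return DensityMap(origin=lo, voxel=float(voxel), grid=grid, resolution=float(resolution))


def ccc(map_a: DensityMap, map_b: DensityMap) -> float:
    """Cross-correlation coefficient between two maps on the same grid.

    Pearson correlation over the union of voxels where either map exceeds
    ``1e-6`` of its own maximum (so empty space does not dominate);
    invariant under positive affine intensity transforms.
    """
    if not map_a.same_geometry(map_b):
        raise ValueError("maps must share grid geometry; resample first")
    a, b = map_a.grid, map_b.grid
    mask = (a > CCC_FLOOR * a.max()) | (b > CCC_FLOOR * b.max())
    av, bv = a[mask], b[mask]
    if av.size < 2 or np.ptp(av) == 0 or np.ptp(bv) == 0:
        raise ValueError("zero-variance map within support")
    return _pearson_flat(av, bv)


def _pearson_flat(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        raise ValueError("zero-variance map within support")
    return float(np.clip((a @ b) / denom, -1.0, 1.0))


def laplace_filter(dmap: DensityMap) -> DensityMap:
    """6-neighbor discrete Laplacian (zero-gradient borders), same shape."""
    if min(dmap.shape) < 3:
        raise ValueError("grid must have at least 3 voxels per axis")
    lap = ndimage.laplace(dmap.grid, mode="nearest")
    return DensityMap(dmap.origin.copy(), dmap.voxel, lap, dmap.resolution)


# ----------------------------------------------------------------------
# Rigid-body fitting
# ----------------------------------------------------------------------

def _start_rotations(n_starts: int) -> list:
    """Deterministic orientation starts: identity first, then octahedral
    group elements in a fixed quaternion order."""
    group = Rotation.create_group("O")
    quats = group.as_quat()
    order = np.lexsort(quats.T[::-1])
    rots = [Rotation.identity()] + [group[int(i)] for i in order]
    # drop duplicates of identity
    out, seen = [], set()
    for r in rots:
        key = tuple(np.round(np.abs(r.as_quat()), 6))
        if key in seen:
            continue
        seen.add(key)
        out.append(r)
    return out[: max(1, n_starts)]


def score_in_map(
    coords: np.ndarray, dmap: DensityMap, mode: str = "plain",
    sigma: float | None = None, target_grid: np.ndarray | None = None,
) -> float:
    """ccc of a Cα coordinate set rendered on ``dmap``'s grid.

    ``target_grid`` lets callers pre-filter the target once (laplace mode).
    """
    if sigma is None:
        if dmap.resolution is None:
            raise ValueError("map has no resolution label; pass sigma")
        sigma = _kernel_sigma(dmap.resolution)
    model = render_on_grid(coords, dmap.origin, dmap.voxel, dmap.shape, sigma)
    target = dmap.grid if target_grid is None else target_grid
    if mode == "laplace":
        model = ndimage.laplace(model, mode="nearest")
    mask = np.abs(target) > CCC_FLOOR * np.abs(target).max()
    mmax = np.abs(model).max()
    if mmax > 0:
        mask |= np.abs(model) > CCC_FLOOR * mmax
    mv, tv = model[mask], target[mask]
    if mv.size < 2 or np.ptp(mv) == 0 or np.ptp(tv) == 0:
        return -1.0
    return _pearson_flat(mv, tv)


def _posed(coords: np.ndarray, center: np.ndarray, pose: np.ndarray) -> np.ndarray:
    rot = Rotation.from_rotvec(pose[:3]).as_matrix()
    return (coords - center) @ rot.T + center + pose[3:]


def fit_to_map(
    structure: Structure,
    dmap: DensityMap,
    mode: str = "plain",
    n_starts: int = 8,
    maxfev: int = 200,
    sigma: float | None = None,
) -> tuple:
    """Rigid 6-dof fit of a structure into a map, maximizing ccc.

    Multistart local search: ``n_starts`` orientations from a fixed rotation
    set, translation initialized by aligning the Cα centroid to the map's
    center of mass, each polished by Powell iterations.  Deterministic.

    Returns ``(pose, ccc)`` where ``pose`` is ``[rotvec (3), translation
    (3)]`` applied about the structure's Cα centroid.
    """
    if mode not in ("plain", "laplace"):
        raise ValueError(f"unknown mode {mode!r}")
    if structure.n_atoms == 0:
        raise ValueError("empty structure")
    ca = structure.ca_coords()
    center = ca.mean(axis=0)
    t0 = dmap.center_of_mass() - center
    target = (
        ndimage.laplace(dmap.grid, mode="nearest") if mode == "laplace" else None
    )

    def neg_ccc(pose):
        return -score_in_map(
            _posed(ca, center, np.asarray(pose)), dmap, mode, sigma, target
        )

    best_pose, best_val = None, np.inf
    for rot in _start_rotations(n_starts):
        pose0 = np.concatenate([rot.as_rotvec(), t0])
        res = minimize(
            neg_ccc,
            pose0,
            method="Powell",
            options={"maxfev": maxfev, "xtol": 1e-3, "ftol": 1e-6},
        )
        if res.fun < best_val:
            best_val, best_pose = res.fun, res.x
        if -best_val >= 0.9999:
            break
    if best_val >= 0:  # no overlap found from any start
        import warnings

        warnings.warn("fit_to_map: no overlapping support; best-effort pose")
    return np.asarray(best_pose), float(-best_val)


def apply_fit_pose(structure: Structure, pose: np.ndarray) -> Structure:
    """Apply a pose returned by :func:`fit_to_map` to a structure."""
    ca = structure.ca_coords()
    center = ca.mean(axis=0)
    rot = Rotation.from_rotvec(np.asarray(pose)[:3]).as_matrix()
    return Structure(
        list(structure.atom_names),
        structure.res_ids.copy(),
        list(structure.chain_ids),
        (structure.coords - center) @ rot.T + center + np.asarray(pose)[3:],
        list(structure.elements),
    )


# ----------------------------------------------------------------------
# File I/O: MRC/CCP4 (gemmi) and SITUS ASCII
# ----------------------------------------------------------------------

def write_map(dmap: DensityMap, path) -> None:
    """Write MRC/CCP4 mode-2 (.mrc/.ccp4/.map) or SITUS ASCII (.situs/.sit)."""
    path = str(path)
    if path.endswith((".situs", ".sit")):
        _write_situs(dmap, path)
        return
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(dmap.grid, dtype=np.float32))
    nx, ny, nz = dmap.shape
    m.grid.unit_cell = gemmi.UnitCell(
        nx * dmap.voxel, ny * dmap.voxel, nz * dmap.voxel, 90, 90, 90
    )
    m.grid.spacegroup = gemmi.find_spacegroup_by_name("P1")
    m.update_ccp4_header()
    # MRC ORIGIN fields (header words 50-52)
    m.set_header_float(50, float(dmap.origin[0]))
    m.set_header_float(51, float(dmap.origin[1]))
    m.set_header_float(52, float(dmap.origin[2]))
    m.write_ccp4_map(path)


def read_map(path) -> DensityMap:
    path = str(path)
    if path.endswith((".situs", ".sit")):
        return _read_situs(path)
    try:
        m = gemmi.read_ccp4_map(path)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot read map {path}: {exc}") from exc
    grid = np.array(m.grid, copy=True).astype(float)
    cell = m.grid.unit_cell
    voxel = cell.a / m.grid.nu
    origin = np.array(
        [m.header_float(50), m.header_float(51), m.header_float(52)], dtype=float
    )
    return DensityMap(origin=origin, voxel=float(voxel), grid=grid)


def _write_situs(dmap: DensityMap, path) -> None:
    # SITUS ASCII: "voxel origin_x origin_y origin_z nx ny nz" then values,
    # x fastest, 10 per line.
    nx, ny, nz = dmap.shape
    vals = np.transpose(dmap.grid, (2, 1, 0)).ravel()  # x fastest
    with open(path, "w") as fh:
        fh.write(
            f"{dmap.voxel:.6f} {dmap.origin[0]:.6f} {dmap.origin[1]:.6f} "
            f"{dmap.origin[2]:.6f} {nx} {ny} {nz}\n\n"
        )
        for i in range(0, len(vals), 10):
            fh.write(" ".join(f"{v:.6e}" for v in vals[i : i + 10]) + "\n")


def _read_situs(path) -> DensityMap:
    with open(path) as fh:
        tokens = fh.read().split()
    if len(tokens) < 7:
        raise ValueError(f"{path}: truncated SITUS header")
    voxel = float(tokens[0])
    origin = np.array([float(t) for t in tokens[1:4]])
    nx, ny, nz = (int(t) for t in tokens[4:7])
    vals = np.array([float(t) for t in tokens[7:]])
    if vals.size != nx * ny * nz:
        raise ValueError(
            f"{path}: expected {nx * ny * nz} voxels, found {vals.size} (truncated?)"
        )
    grid = np.transpose(vals.reshape(nz, ny, nx), (2, 1, 0))
    return DensityMap(origin=origin, voxel=voxel, grid=grid)
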