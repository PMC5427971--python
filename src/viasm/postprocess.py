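"""Post-processing of viable solutions: clustering, ranking, audits.

Viable candidates are hierarchically clustered (complete linkage on
fixed-frame Cα-RMSD, 1 Å cut), cluster centroids are fitted into a
reference density map and ranked by cross-correlation, restraint
satisfaction is audited against truth labels (PPV), and final models are
compared to reference structures with cyclic-relabeling superposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from . import density
from .scoring import constraint_distances, constraint_violations, ppv
from .structio import Structure, rmsd_superposed

__all__ = [
    "ClusterReport",
    "RankedModels",
    "cluster_solutions",
    "rank_by_ccc",
    "audit_constraints",
    "compare_to_reference",
]


@dataclass
class ClusterReport:
    """Clusters of candidate indices with per-cluster centroid."""

    clusters: list  # list of sorted member-index lists
    centroids: list  # one member index per cluster
    max_rmsd: list  # within-cluster max pairwise RMSD

    def __len__(self):
        return len(self.clusters)


@dataclass
class RankedModels:
    """Centroid models ordered by descending ccc."""

    entries: list = field(default_factory=list)  # (candidate_index, structure, pose, ccc)

    def top(self, k: int = 5) -> list:
        return self.entries[:k]

    @property
    def best(self):
        return self.entries[0] if self.entries else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(i, c) for i, _, _, c in self.entries], columns=["candidate", "ccc"]
        )


def pairwise_fixed_rmsd(coord_sets: np.ndarray) -> np.ndarray:
    """Condensed fixed-frame RMSD matrix over (m, n_atoms, 3) coordinates."""
    m = len(coord_sets)
    flat = coord_sets.reshape(m, -1)
    n_atoms = coord_sets.shape[1]
    out = np.empty(m * (m - 1) // 2)
    k = 0
    for i in range(m - 1):
        diff = flat[i + 1 :] - flat[i]
        out[k : k + m - i - 1] = np.sqrt(
            np.sum(diff * diff, axis=1) / n_atoms
        )
        k += m - i - 1
    return out


def cluster_solutions(coord_sets, threshold: float = 1.0) -> ClusterReport:
    """Agglomerative complete-linkage clustering on fixed-frame Cα-RMSD.

    Complete linkage is the only standard linkage that guarantees every
    cluster's maximum pairwise RMSD stays below the cut (1 Å by default).
    The centroid of a cluster is the member minimizing its summed RMSD to
    the other members (ties: lowest index).  Candidates are expected in one
    common assembly frame; no superposition is applied.
    """
    coord_sets = np.asarray(coord_sets, dtype=float)
    if coord_sets.ndim != 3 or len(coord_sets) == 0:
        raise ValueError("need a non-empty (m, n_atoms, 3) coordinate stack")
    m = len(coord_sets)
    if m == 1:
        return ClusterReport([[0]], [0], [0.0])
    condensed = pairwise_fixed_rmsd(coord_sets)
    labels = fcluster(
        linkage(condensed, method="complete"),
        t=threshold * (1.0 - 1e-12),
        criterion="distance",
    )
    square = squareform(condensed)
    clusters, centroids, maxes = [], [], []
    for lab in np.unique(labels):
        members = sorted(np.flatnonzero(labels == lab).tolist())
        sub = square[np.ix_(members, members)]
        centroids.append(members[int(np.argmin(sub.sum(axis=1)))])
        clusters.append(members)
        maxes.append(float(sub.max()) if len(members) > 1 else 0.0)
    order = np.argsort([c[0] for c in clusters])
    return ClusterReport(
        [clusters[i] for i in order],
        [centroids[i] for i in order],
        [maxes[i] for i in order],
    )


def fast_fit_ccc(
    structure: Structure,
    dmap: density.DensityMap,
    mode: str = "plain",
    n_angles: int = 72,
    polish: bool = True,
) -> tuple:
    """ccc of an assembly against a map sharing the canonical symmetry frame.

    Candidates and simulated maps both place the symmetry axis on z, so
    only the ring phase (rotation about z), an up/down flip and a small
    translation need fitting: the phase is scanned on a grid, the best
    variant optionally polished by a short local search.  Much cheaper than
    the full 6-dof multistart fit and adequate for ranking many centroids.

    Returns ``(pose, ccc)`` in :func:`density.fit_to_map` pose convention.
    """
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    ca = structure.ca_coords()
    center = ca.mean(axis=0)
    t0 = dmap.center_of_mass() - center
    target = ndimage.laplace(dmap.grid, mode="nearest") if mode == "laplace" else None

    def score(pose):
        return density.score_in_map(
            density._posed(ca, center, pose), dmap, mode, None, target
        )

    best_pose, best = None, -np.inf
    for flip in (False, True):
        for ang in np.linspace(0.0, 2.0 * np.pi, n_angles, endpoint=False):
            rot = Rotation.from_euler("z", ang)
            if flip:
                rot = rot * Rotation.from_euler("x", np.pi)
            pose = np.concatenate([rot.as_rotvec(), t0])
            s = score(pose)
            if s > best:
                best, best_pose = s, pose
    if polish and best_pose is not None:
        res = minimize(
            lambda p: -score(p),
            best_pose,
            method="Powell",
            options={"maxfev": 150, "xtol": 1e-3, "ftol": 1e-6},
        )
        if -res.fun > best:
            best, best_pose = -res.fun, res.x
    return best_pose, float(best)


def rank_by_ccc(
    centroid_structures,
    reference_map: density.DensityMap,
    mode: str = "plain",
    fit: str = "fast",
) -> RankedModels:
    """Fit each centroid into the reference map and rank by descending ccc.

    ``fit="fast"`` uses the shared-frame phase scan (:func:`fast_fit_ccc`);
    ``fit="full"`` runs the 6-dof multistart :func:`density.fit_to_map`.
    Ties are broken by input index, so the ranking is permutation-invariant.
    """
    structures = list(centroid_structures)
    if not structures:
        raise ValueError("no centroids to rank")
    rows = []
    for i, st in enumerate(structures):
        if fit == "full":
            pose, c = density.fit_to_map(st, reference_map, mode=mode)
        else:
            pose, c = fast_fit_ccc(st, reference_map, mode=mode)
        rows.append((i, st, pose, c))
    rows.sort(key=lambda r: (-r[3], r[0]))
    return RankedModels(rows)


def audit_constraints(model: Structure, constraints, tolerance_extra: float = 0.0):
    """Count satisfied true/false restraints in a model and compute PPV.

    A restraint is satisfied iff its observed distance lies inside its own
    ``[l, u]`` interval (optionally widened by ``tolerance_extra``).
    Requires truth labels on every constraint.  Returns ``(tp, fp, ppv)``;
    ppv is None when the model satisfies no restraint at all.
    """
    if any(c.is_true is None for c in constraints):
        raise ValueError("audit requires truth labels on all constraints")
    obs = constraint_distances(model, constraints)
    widened = [c.widened(tolerance_extra) for c in constraints]
    viol = constraint_violations(obs, widened)
    tp = sum(1 for c, v in zip(constraints, viol) if v == 0 and c.is_true)
    fp = sum(1 for c, v in zip(constraints, viol) if v == 0 and not c.is_true)
    return tp, fp, (ppv(tp, fp) if tp + fp > 0 else None)


def compare_to_reference(
    model: Structure,
    reference: Structure,
    symmetry_n: int,
    allow_reflection: bool = False,
) -> float:
    """Cα-RMSD to a reference assembly after optimal superposition,
    minimized over the n cyclic chain relabelings (subunit copies are
    interchangeable).  Optional reflection is off by default."""
    mc = [model.ca_coords(c) for c in model.chains]
    rc = [reference.ca_coords(c) for c in reference.chains]
    if len(mc) != symmetry_n or len(rc) != symmetry_n:
        raise ValueError("chain count does not match symmetry_n")
    if any(len(a) != len(rc[0]) for a in mc + rc):
        raise ValueError("subunit atom counts differ between model and reference")
    ref = np.vstack(rc)
    variants = [model]
    if allow_reflection:
        refl = model.copy()
        refl.coords = refl.coords * np.array([1.0, 1.0, -1.0])
        variants.append(refl)
    best = np.inf
    for var in variants:
        vc = [var.ca_coords(c) for c in var.chains]
        for shift in range(symmetry_n):
            mod = np.vstack([vc[(i + shift) % symmetry_n] for i in range(symmetry_n)])
            best = min(best, rmsd_superposed(mod, ref))
    return float(best)
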