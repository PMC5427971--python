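"""Coarse macromolecular structure I/O and coordinate comparisons.

The assembly protocol works at the Cα/Cβ level: a :class:`Structure` is a
flat list of atom records grouped by chain and 1-based residue index.  PDB
reading/writing is backed by gemmi; only ATOM records of standard amino
acids are kept (the coarse scoring model needs no ligands or hydrogens).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Structure",
    "ParseError",
    "SelectionError",
    "read_pdb",
    "write_pdb",
    "rmsd_fixed_frame",
    "rmsd_superposed",
    "CHAIN_ALPHABET",
]

#: One-character chain identifiers available for assembly copies (wwPDB v3.3
#: single-column chain field): 62 symbols.
CHAIN_ALPHABET = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)


class ParseError(ValueError):
    """A PDB file could not be interpreted."""


class SelectionError(KeyError):
    """A requested chain/residue/atom does not exist in the structure."""


@dataclass
class Structure:
    """Atom records of one subunit or one assembled complex.

    Parameters
    ----------
    atom_names : list of str
        PDB atom names (``CA``, ``CB``, ...).
    res_ids : ndarray of int
        1-based residue indices, unique within each chain.
    chain_ids : list of str
        One-character chain identifier per atom.
    coords : (n_atoms, 3) ndarray
        Cartesian coordinates in Å.
    elements : list of str
        Element symbols (defaults to the first letter of the atom name).
    """

    atom_names: list = field(default_factory=list)
    res_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    chain_ids: list = field(default_factory=list)
    coords: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    elements: list = field(default_factory=list)

    def __post_init__(self):
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.size and not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if not self.elements:
            self.elements = [n[:1] for n in self.atom_names]
        if len({len(self.atom_names), len(self.res_ids), len(self.chain_ids),
                len(self.coords), len(self.elements)}) > 1:
            raise ValueError("field lengths disagree")
        # residue indices must be unique within a chain (same residue may
        # contribute several atoms, but an (chain, res, atom-name) triple is
        # unique)
        seen = set()
        for cid, rid, name in zip(self.chain_ids, self.res_ids, self.atom_names):
            key = (cid, int(rid), name)
            if key in seen:
                raise ValueError(f"duplicate atom {name} in {cid}:{rid}")
            seen.add(key)
        self._index = seen

    # ------------------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def chains(self) -> list:
        """Chain identifiers in order of first appearance."""
        out, seen = [], set()
        for c in self.chain_ids:
            if c not in seen:
                out.append(c)
                seen.add(c)
        return out

    def chain(self, chain_id: str) -> "Structure":
        """Sub-structure of a single chain (copy)."""
        mask = [c == chain_id for c in self.chain_ids]
        if not any(mask):
            raise SelectionError(f"no chain {chain_id!r}")
        idx = np.flatnonzero(mask)
        return Structure(
            [self.atom_names[i] for i in idx],
            self.res_ids[idx],
            [self.chain_ids[i] for i in idx],
            self.coords[idx],
            [self.elements[i] for i in idx],
        )

    def atom_xyz(self, chain_id: str, res_id: int, atom_name: str) -> np.ndarray:
        """Coordinates of one named atom; raises SelectionError if absent."""
        for i, (c, r, n) in enumerate(
            zip(self.chain_ids, self.res_ids, self.atom_names)
        ):
            if c == chain_id and r == res_id and n == atom_name:
                return self.coords[i]
        raise SelectionError(
            f"atom {atom_name} of residue {res_id} in chain {chain_id} not found"
        )

    def ca_coords(self, chain_id: str | None = None) -> np.ndarray:
        """Cα coordinates, optionally restricted to one chain (file order)."""
        mask = [
            n == "CA" and (chain_id is None or c == chain_id)
            for n, c in zip(self.atom_names, self.chain_ids)
        ]
        return self.coords[np.flatnonzero(mask)]

    def residue_xyz(self, res_id: int, atom_type: str, chain_id: str | None = None):
        """Cα or Cβ of a residue; first chain if unspecified."""
        cid = chain_id if chain_id is not None else self.chains[0]
        return self.atom_xyz(cid, res_id, atom_type)

    def centroid(self) -> np.ndarray:
        """Centroid of the Cα trace (the reference point for assembly moves)."""
        ca = self.ca_coords()
        if ca.size == 0:
            raise ValueError("structure has no Cα atoms")
        return ca.mean(axis=0)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """New structure with ``x -> R x + t`` applied to every atom."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        return Structure(
            list(self.atom_names),
            self.res_ids.copy(),
            list(self.chain_ids),
            self.coords @ rotation.T + translation,
            list(self.elements),
        )

    def with_chain(self, chain_id: str) -> "Structure":
        return Structure(
            list(self.atom_names),
            self.res_ids.copy(),
            [chain_id] * self.n_atoms,
            self.coords.copy(),
            list(self.elements),
        )

    def copy(self) -> "Structure":
        return self.with_chain_ids(list(self.chain_ids))

    def with_chain_ids(self, chain_ids: list) -> "Structure":
        return Structure(
            list(self.atom_names),
            self.res_ids.copy(),
            list(chain_ids),
            self.coords.copy(),
            list(self.elements),
        )


def concatenate(parts: list) -> Structure:
    """Concatenate structures (used to stack assembly copies)."""
    return Structure(
        sum((list(p.atom_names) for p in parts), []),
        np.concatenate([p.res_ids for p in parts]) if parts else np.empty(0, int),
        sum((list(p.chain_ids) for p in parts), []),
        np.vstack([p.coords for p in parts]) if parts else np.empty((0, 3)),
        sum((list(p.elements) for p in parts), []),
    )


# ----------------------------------------------------------------------
# PDB I/O (gemmi-backed)
# ----------------------------------------------------------------------

def read_pdb(path) -> Structure:
    """Read ATOM records of standard amino acids from a PDB file.

    Alternate locations keep the highest-occupancy conformer (ties: the one
    appearing first).  HETATM records and insertion codes are ignored;
    residue numbering from the file is preserved (1-based).
    """
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except FileNotFoundError:
        raise
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse PDB file {path}: {exc}") from exc

    names, rids, cids, xyz, elems = [], [], [], [], []
    if len(st) == 0:
        raise ParseError(f"{path}: no models")
    model = st[0]
    for chain in model:
        for res in chain:
            if res.het_flag != "A":  # ATOM records only
                continue
            best = {}
            for atom in res:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for atom in res:  # preserve file order of names
                if best.get(atom.name) is not atom:
                    continue
                names.append(atom.name)
                rids.append(res.seqid.num)
                cids.append(chain.name[:1] or "A")
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
                elems.append(atom.element.name)
    if not names:
        raise ParseError(f"{path}: no ATOM records of standard residues")
    return Structure(names, np.array(rids), cids, np.array(xyz), elems)


def write_pdb(structure: Structure, path) -> None:
    """Write a structure (or assembly) as PDB text, one chain per subunit copy."""
    if structure.n_atoms == 0:
        raise ValueError("refusing to write an empty structure")
    if len(structure.chains) > len(CHAIN_ALPHABET):
        raise ValueError(
            f"{len(structure.chains)} chains exceed the {len(CHAIN_ALPHABET)}-symbol "
            "chain-ID alphabet"
        )
    st = gemmi.Structure()
    st.name = "viasm"
    model = gemmi.Model("1")
    chain_map = {}
    for name, rid, cid, co, el in zip(
        structure.atom_names,
        structure.res_ids,
        structure.chain_ids,
        structure.coords,
        structure.elements,
    ):
        if cid not in chain_map:
            chain_map[cid] = gemmi.Chain(cid)
        chain = chain_map[cid]
        if len(chain) == 0 or chain[-1].seqid.num != int(rid):
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(int(rid), " ")
            res.het_flag = "A"
            chain.add_residue(res)
        atom = gemmi.Atom()
        atom.name = name
        atom.pos = gemmi.Position(*co)
        atom.element = gemmi.Element(el or name[:1])
        atom.occ = 1.0
        chain[-1].add_atom(atom)
    for chain in chain_map.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    doc = st.make_pdb_string()
    with open(path, "w") as fh:
        fh.write(doc)


# ----------------------------------------------------------------------
# RMSD
# ----------------------------------------------------------------------

def _as_paired(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3 or len(a) < 1:
        raise ValueError(f"coordinate shapes disagree: {a.shape} vs {b.shape}")
    return a, b


def rmsd_fixed_frame(a, b) -> float:
    """Root-mean-square deviation between paired coordinates, no superposition.

    Candidate assemblies all live in the common symmetry frame (axis on z,
    first copy on +x), so clustering compares them without fitting: fitting
    would merge genuinely different ring radii and orientations.
    """
    a, b = _as_paired(a, b)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rmsd_superposed(a, b) -> float:
    """Minimal RMSD over rigid transforms (Kabsch optimal superposition).

    Falls back to a translation-only fit (with a warning) when fewer than
    three non-collinear points are available.
    """
    a, b = _as_paired(a, b)
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    if len(a) < 3 or np.linalg.matrix_rank(ac, tol=1e-9) < 2:
        warnings.warn("fewer than 3 non-collinear points; translation-only fit")
        return float(np.sqrt(np.mean(np.sum((ac - bc) ** 2, axis=1))))
    rot, _ = Rotation.align_vectors(ac, bc)
    return float(np.sqrt(np.mean(np.sum((ac - rot.apply(bc)) ** 2, axis=1))))
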