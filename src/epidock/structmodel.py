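"""Structure data model, PDB I/O and rigid-body geometry.

The in-memory model is a light hierarchy (chain -> residue -> atom) carrying
only what the downstream geometry needs: names, elements and coordinates.
Residues are addressed everywhere in the package by the triple
``(chain_id, residue_number, insertion_code)`` so that antibody numbering
schemes with insertion codes round-trip losslessly.

Parsing is delegated to :mod:`gemmi`; writing uses a small fixed-column
PDB v3.3 formatter whose output re-reads coordinate-identically to three
decimals.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "Residue",
    "StructureModel",
    "RigidTransform",
    "StructureError",
    "read_pdb",
    "write_pdb",
    "kabsch",
    "kabsch_superpose",
]

#: key addressing one residue: (chain id, residue number, insertion code)
ResidueKey = Tuple[str, int, str]

AMINO_ACIDS_3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "UNK",
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class StructureError(ValueError):
    """Malformed structure input or an impossible structural operation."""


@dataclass
class AtomRecord:
    """One atom: name, element, coordinates and altloc/occupancy metadata."""

    serial: int
    name: str
    element: str
    residue_key: ResidueKey
    coordinates: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (3,) or not np.all(np.isfinite(self.coordinates)):
            raise StructureError(
                f"atom {self.name}: coordinates must be a finite 3-vector"
            )
        if not self.element:
            self.element = _infer_element(self.name)
        self.element = self.element.upper()

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


def _infer_element(atom_name: str) -> str:
    """Infer an element symbol from a PDB atom name when the column is blank."""
    stripped = atom_name.strip()
    if not stripped:
        raise StructureError("cannot infer element from empty atom name")
    # two-letter elements common in proteins
    if stripped[:2].upper() in ("SE", "FE", "ZN", "MG", "CL", "BR", "NA"):
        return stripped[:2].upper()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    raise StructureError(f"cannot infer element from atom name {atom_name!r}")


@dataclass
class Residue:
    key: ResidueKey
    name: str
    atoms: List[AtomRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureError(f"residue {self.key} has no atoms")
        seen = set()
        for atom in self.atoms:
            if atom.name in seen:
                raise StructureError(
                    f"residue {self.key}: duplicate atom name {atom.name!r} "
                    "after altloc resolution"
                )
            seen.add(atom.name)

    def atom(self, name: str) -> Optional[AtomRecord]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")


class StructureModel:
    """Ordered chains of residues plus free-form metadata.

    Chain ids are unique; residue keys are unique within a chain.
    """

    def __init__(
        self,
        chains: Dict[str, List[Residue]],
        metadata: Optional[dict] = None,
    ) -> None:
        self.chains: Dict[str, List[Residue]] = {}
        for cid, residues in chains.items():
            if cid in self.chains:
                raise StructureError(f"duplicate chain id {cid!r}")
            keys = [r.key for r in residues]
            if len(set(keys)) != len(keys):
                raise StructureError(f"duplicate residue keys in chain {cid!r}")
            self.chains[cid] = list(residues)
        self.metadata = dict(metadata or {})

    # ------------------------------------------------------------------ views
    def residues(self) -> Iterator[Residue]:
        for residues in self.chains.values():
            yield from residues

    def atoms(self, include_hydrogens: bool = True) -> Iterator[AtomRecord]:
        for res in self.residues():
            for atom in res.atoms:
                if include_hydrogens or not atom.is_hydrogen:
                    yield atom

    def residue(self, key: ResidueKey) -> Residue:
        chain = self.chains.get(key[0])
        if chain is not None:
            for res in chain:
                if res.key == key:
                    return res
        raise KeyError(key)

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains.values())

    def coordinates(self, include_hydrogens: bool = True) -> np.ndarray:
        pts = [a.coordinates for a in self.atoms(include_hydrogens)]
        if not pts:
            return np.empty((0, 3))
        return np.vstack(pts)

    def subset(self, chain_ids: Iterable[str]) -> "StructureModel":
        """New model containing only the given chains (shared residue objects)."""
        wanted = list(chain_ids)
        missing = [c for c in wanted if c not in self.chains]
        if missing:
            raise StructureError(f"chains not present: {missing}")
        return StructureModel(
            {c: self.chains[c] for c in wanted}, metadata=dict(self.metadata)
        )

    def transformed(self, transform: "RigidTransform") -> "StructureModel":
        """Deep-copied model with *transform* applied to every atom."""
        new_chains: Dict[str, List[Residue]] = {}
        for cid, residues in self.chains.items():
            new_res = []
            for res in residues:
                new_atoms = [
                    AtomRecord(
                        serial=a.serial,
                        name=a.name,
                        element=a.element,
                        residue_key=a.residue_key,
                        coordinates=transform.apply(a.coordinates),
                        occupancy=a.occupancy,
                        altloc=a.altloc,
                    )
                    for a in res.atoms
                ]
                new_res.append(Residue(key=res.key, name=res.name, atoms=new_atoms))
            new_chains[cid] = new_res
        return StructureModel(new_chains, metadata=dict(self.metadata))


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise StructureError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-8):
            raise StructureError("rotation matrix is not orthogonal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-8):
            raise StructureError("rotation determinant is not +1 (improper rotation)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self.compose(other)).apply(x) == self.apply(other.apply(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)


# ---------------------------------------------------------------------- I/O

def read_pdb(
    path: os.PathLike | str,
    model_index: int = 0,
    altloc_policy: str = "highest_occupancy",
    keep_hetero: bool = False,
) -> StructureModel:
    """Read one model of a PDB file into a :class:`StructureModel`.

    Waters and non-polymer ligands (HETATM) are excluded by default;
    hydrogens are retained but flagged via :attr:`AtomRecord.is_hydrogen`.

    Parameters
    ----------
    model_index
        Zero-based model number within the file.
    altloc_policy
        ``"highest_occupancy"`` keeps, for each atom name, the alternate
        location with the highest occupancy (ties: first encountered);
        ``"first"`` keeps the first encountered.
    """
    if altloc_policy not in ("first", "highest_occupancy"):
        raise ValueError(f"unknown altloc policy {altloc_policy!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such PDB file: {path}")
    structure = gemmi.read_structure(str(path))
    if len(structure) == 0:
        raise StructureError(f"{path}: no models / no ATOM records")
    if model_index < 0 or model_index >= len(structure):
        raise StructureError(
            f"{path}: model {model_index} absent (file has {len(structure)} model(s))"
        )
    model = structure[model_index]

    chains: Dict[str, List[Residue]] = {}
    serial = 0
    for chain in model:
        residues: List[Residue] = []
        for res in chain:
            if res.name in _WATER_NAMES:
                continue
            is_polymer = res.name in AMINO_ACIDS_3 or res.het_flag == "A"
            if not is_polymer and not keep_hetero:
                continue
            icode = res.seqid.icode.strip()
            key: ResidueKey = (chain.name, res.seqid.num, icode)
            # altloc resolution: group by atom name
            by_name: Dict[str, List[gemmi.Atom]] = {}
            for atom in res:
                by_name.setdefault(atom.name, []).append(atom)
            atoms: List[AtomRecord] = []
            for name, variants in by_name.items():
                if altloc_policy == "highest_occupancy" and len(variants) > 1:
                    chosen = max(variants, key=lambda a: a.occ)
                else:
                    chosen = variants[0]
                serial += 1
                atoms.append(
                    AtomRecord(
                        serial=serial,
                        name=name,
                        element=chosen.element.name or "",
                        residue_key=key,
                        coordinates=np.array(
                            [chosen.pos.x, chosen.pos.y, chosen.pos.z]
                        ),
                        occupancy=chosen.occ,
                        altloc=(chosen.altloc or "").strip(),
                    )
                )
            if atoms:
                residues.append(Residue(key=key, name=res.name, atoms=atoms))
        if residues:
            existing = chains.get(chain.name)
            if existing is None:
                chains[chain.name] = residues
            else:  # gemmi may split a chain into polymer/non-polymer subchains
                existing.extend(residues)
    if not chains:
        raise StructureError(f"{path}: no polymer ATOM records after filtering")
    return StructureModel(
        chains, metadata={"source": str(path), "model_index": model_index}
    )


def write_pdb(model: StructureModel, path: os.PathLike | str) -> None:
    """Write fixed-column PDB v3.3 ATOM records (coordinates to 3 decimals)."""
    if model.n_atoms == 0:
        raise StructureError("refusing to write an empty model")
    for cid in model.chains:
        if len(cid) != 1:
            raise StructureError(
                f"chain id {cid!r} does not fit the single-column PDB chain field"
            )
    lines = []
    serial = 0
    for cid, residues in model.chains.items():
        for res in residues:
            for atom in res.atoms:
                serial += 1
                name = atom.name
                # PDB alignment rule: 1-3 char names start in column 14
                fname = f" {name:<3s}" if len(name) < 4 else name
                x, y, z = atom.coordinates
                lines.append(
                    f"ATOM  {serial:5d} {fname:<4s}{atom.altloc or ' ':1s}"
                    f"{res.name:>3s} {cid:1s}{res.key[1]:4d}{res.key[2] or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
        lines.append(f"TER   {serial + 1:5d}      {residues[-1].name:>3s} {cid:1s}"
                     f"{residues[-1].key[1]:4d}")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ----------------------------------------------------------------- geometry

def kabsch(
    mobile: np.ndarray, reference: np.ndarray
) -> Tuple[RigidTransform, float]:
    """Optimal rigid superposition of paired point sets (Kabsch/SVD).

    Returns the transform minimising RMSD(T(mobile), reference) and that
    minimal RMSD. Requires >= 3 non-collinear pairs.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise StructureError("paired coordinate arrays must both be (n, 3)")
    n = P.shape[0]
    if n < 3:
        raise StructureError(f"superposition needs >=3 atom pairs, got {n}")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    # collinearity check: effectively rank-1 centered cloud
    sv = np.linalg.svd(P0, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise StructureError("degenerate (collinear) atom selection")
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cq - R @ cp
    transform = RigidTransform(R, t)
    diff = transform.apply(P) - Q
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return transform, rmsd


def paired_coordinates(
    mobile: StructureModel,
    reference: StructureModel,
    atom_name: str = "CA",
    key_map: str = "exact",
) -> Tuple[np.ndarray, np.ndarray]:
    """Collect coordinates of atoms shared by both models.

    ``key_map="exact"`` pairs residues by the full (chain, number, icode)
    key; ``"number"`` ignores the chain id, pairing by (number, icode) —
    useful when the same molecule carries different chain ids in two files.
    """
    def index(m: StructureModel) -> Dict[tuple, np.ndarray]:
        out = {}
        for res in m.residues():
            a = res.atom(atom_name)
            if a is not None:
                k = res.key if key_map == "exact" else res.key[1:]
                out[k] = a.coordinates
        return out

    im, ir = index(mobile), index(reference)
    shared = [k for k in im if k in ir]
    if len(shared) < 3:
        raise StructureError(
            f"only {len(shared)} shared {atom_name} atoms between models"
        )
    return (
        np.vstack([im[k] for k in shared]),
        np.vstack([ir[k] for k in shared]),
    )


def kabsch_superpose(
    mobile: StructureModel,
    reference: StructureModel,
    atom_name: str = "CA",
    key_map: str = "exact",
) -> Tuple[RigidTransform, float]:
    """Superpose *mobile* onto *reference* over shared named atoms."""
    P, Q = paired_coordinates(mobile, reference, atom_name, key_map)
    return kabsch(P, Q)
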