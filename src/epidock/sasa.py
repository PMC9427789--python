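"""Solvent-accessible surface area (Shrake-Rupley) and exposure selection.

The accessible surface of each atom is traced by a probe sphere (default
radius 1.4 A) rolled over van der Waals spheres. The deterministic
estimator places a golden-section spiral lattice of test points on each
expanded sphere (radius r_vdw + r_probe) and counts points not occluded by
any neighbouring expanded sphere:

    area_i = (exposed_i / n_points) * 4 pi (r_i + r_probe)^2

A seeded Monte-Carlo estimator with per-atom standard errors serves as an
independent statistical oracle for the lattice version.

Relative solvent accessibility (RSA) normalises per-residue area by a
published per-residue-type theoretical maximum (Tien et al. 2013,
Gly-X-Gly); an alternative mode normalises by the observed per-type maximum
within the structure itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structmodel import AtomRecord, ResidueKey, StructureModel

__all__ = [
    "SasaParams",
    "SasaResult",
    "RsaTable",
    "shrake_rupley",
    "monte_carlo_sasa",
    "relative_accessibility",
    "select_exposed",
    "MAX_ASA_THEORETICAL",
]

#: Bondi-type van der Waals radii for protein elements (Angstrom).
DEFAULT_RADII: Dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "D": 1.20,
    "P": 1.80,
    "SE": 1.90,
}

#: Theoretical maximum accessible areas per residue type (Tien et al. 2013,
#: Gly-X-Gly tripeptide), Angstrom^2.
MAX_ASA_THEORETICAL: Dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


@dataclass
class SasaParams:
    probe_radius: float = 1.4
    n_points: int = 960
    radii_set: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RADII))
    fallback_radius: Optional[float] = 1.8
    include_hydrogens: bool = False

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be positive")
        if self.n_points < 60:
            raise ValueError("n_points must be >= 60")
        if any(r <= 0 for r in self.radii_set.values()):
            raise ValueError("all van der Waals radii must be positive")

    def radius_of(self, atom: AtomRecord) -> float:
        r = self.radii_set.get(atom.element)
        if r is None:
            r = self.fallback_radius
        if r is None:
            raise KeyError(atom.element)
        return r


@dataclass
class SasaResult:
    per_atom: Dict[Tuple[ResidueKey, str], float]
    per_residue: Dict[ResidueKey, float]
    total: float
    per_atom_se: Optional[Dict[Tuple[ResidueKey, str], float]] = None

    @classmethod
    def from_atom_areas(
        cls,
        keys: List[Tuple[ResidueKey, str]],
        areas: np.ndarray,
        ses: Optional[np.ndarray] = None,
    ) -> "SasaResult":
        per_atom = {k: float(a) for k, a in zip(keys, areas)}
        per_residue: Dict[ResidueKey, float] = {}
        for (rkey, _), a in per_atom.items():
            per_residue[rkey] = per_residue.get(rkey, 0.0) + a
        return cls(
            per_atom=per_atom,
            per_residue=per_residue,
            total=float(areas.sum()),
            per_atom_se={k: float(s) for k, s in zip(keys, ses)} if ses is not None else None,
        )


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic near-uniform unit-sphere lattice (golden-section spiral)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _atom_arrays(
    model: StructureModel, params: SasaParams
) -> Tuple[List[Tuple[ResidueKey, str]], np.ndarray, np.ndarray]:
    keys: List[Tuple[ResidueKey, str]] = []
    coords: List[np.ndarray] = []
    radii: List[float] = []
    unknown: List[str] = []
    for atom in model.atoms(include_hydrogens=params.include_hydrogens):
        try:
            r = params.radius_of(atom)
        except KeyError:
            unknown.append(f"{atom.residue_key}/{atom.name} ({atom.element})")
            continue
        keys.append((atom.residue_key, atom.name))
        coords.append(atom.coordinates)
        radii.append(r + params.probe_radius)
    if unknown:
        raise ValueError(
            "no van der Waals radius (and no fallback) for atoms: "
            + ", ".join(unknown)
        )
    if not keys:
        raise ValueError("model contains no atoms with a known radius")
    return keys, np.vstack(coords), np.asarray(radii)


def _exposed_fractions(
    coords: np.ndarray,
    radii: np.ndarray,
    points_for: callable,
) -> Tuple[np.ndarray, np.ndarray]:
    """Fraction of test points on each expanded sphere outside all neighbours.

    ``points_for(i, radius)`` yields the (m, 3) test points for atom ``i``
    on the unit sphere (scaled/translated here).
    """
    n = len(radii)
    tree = cKDTree(coords)
    rmax = radii.max()
    fractions = np.empty(n)
    counts = np.empty(n, dtype=int)
    for i in range(n):
        unit = points_for(i)
        pts = coords[i] + radii[i] * unit
        neigh = tree.query_ball_point(coords[i], radii[i] + rmax)
        neigh = [j for j in neigh if j != i]
        if neigh:
            nc = coords[neigh]
            nr = radii[neigh]
            keep = np.linalg.norm(coords[i] - nc, axis=1) < radii[i] + nr
            nc, nr = nc[keep], nr[keep]
        else:
            nc = np.empty((0, 3))
            nr = np.empty(0)
        if len(nc):
            d2 = ((pts[:, None, :] - nc[None, :, :]) ** 2).sum(axis=2)
            exposed = ~np.any(d2 < (nr ** 2)[None, :], axis=1)
        else:
            exposed = np.ones(len(pts), dtype=bool)
        counts[i] = len(pts)
        fractions[i] = exposed.mean()
    return fractions, counts


def shrake_rupley(model: StructureModel, params: Optional[SasaParams] = None) -> SasaResult:
    """Deterministic Shrake-Rupley SASA on a fixed spiral lattice."""
    params = params or SasaParams()
    keys, coords, radii = _atom_arrays(model, params)
    unit = golden_spiral_points(params.n_points)
    fractions, _ = _exposed_fractions(coords, radii, lambda i: unit)
    areas = fractions * 4.0 * np.pi * radii ** 2
    return SasaResult.from_atom_areas(keys, areas)


def monte_carlo_sasa(
    model: StructureModel,
    params: Optional[SasaParams] = None,
    n_samples: int = 2000,
    seed: int = 0,
) -> SasaResult:
    """Unbiased SASA estimate by uniform sampling on each expanded sphere.

    The per-atom standard error of the area estimate (binomial) is stored in
    :attr:`SasaResult.per_atom_se`.
    """
    if n_samples < 100:
        raise ValueError("n_samples must be >= 100")
    params = params or SasaParams()
    keys, coords, radii = _atom_arrays(model, params)
    rng = np.random.default_rng(seed)
    samples = rng.standard_normal((len(radii), n_samples, 3))
    samples /= np.linalg.norm(samples, axis=2, keepdims=True)
    fractions, counts = _exposed_fractions(coords, radii, lambda i: samples[i])
    sphere = 4.0 * np.pi * radii ** 2
    areas = fractions * sphere
    ses = sphere * np.sqrt(fractions * (1.0 - fractions) / counts)
    return SasaResult.from_atom_areas(keys, areas, ses)


@dataclass
class RsaEntry:
    absolute: float
    reference_max: float
    rsa: float
    resname: str


@dataclass
class RsaTable:
    per_residue: Dict[ResidueKey, RsaEntry]
    reference_set_name: str
    excluded: List[ResidueKey] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chain": k[0],
                "resnum": k[1],
                "icode": k[2],
                "resname": e.resname,
                "abs_sasa_A2": e.absolute,
                "ref_max_A2": e.reference_max,
                "rsa_percent": e.rsa,
            }
            for k, e in self.per_residue.items()
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def relative_accessibility(
    sasa: SasaResult,
    model: StructureModel,
    reference_set: str = "tien2013_theoretical",
) -> RsaTable:
    """Per-residue RSA = 100 * absolute / reference-max.

    ``reference_set`` is either ``"tien2013_theoretical"`` (published
    Gly-X-Gly maxima) or ``"observed_max"`` (maximum observed area of the
    same residue type within this structure). Residue types without a
    reference value are flagged in :attr:`RsaTable.excluded`.
    """
    names = {res.key: res.name for res in model.residues()}
    if reference_set == "tien2013_theoretical":
        ref = MAX_ASA_THEORETICAL
    elif reference_set == "observed_max":
        ref = {}
        for key, area in sasa.per_residue.items():
            name = names.get(key, "UNK")
            ref[name] = max(ref.get(name, 0.0), area)
    else:
        raise ValueError(f"unknown reference set {reference_set!r}")

    per_residue: Dict[ResidueKey, RsaEntry] = {}
    excluded: List[ResidueKey] = []
    for key, area in sasa.per_residue.items():
        name = names.get(key, "UNK")
        ref_max = ref.get(name)
        if ref_max is None or ref_max <= 0:
            excluded.append(key)
            continue
        per_residue[key] = RsaEntry(
            absolute=area,
            reference_max=ref_max,
            rsa=100.0 * area / ref_max,
            resname=name,
        )
    return RsaTable(
        per_residue=per_residue,
        reference_set_name=reference_set,
        excluded=excluded,
    )


def select_exposed(
    rsa: RsaTable,
    threshold_percent: float = 20.0,
    restrict_to: Optional[Iterable[ResidueKey]] = None,
) -> List[ResidueKey]:
    """Residues with RSA strictly above the threshold, in residue order.

    "More than 20%" is read strictly: a residue at exactly the threshold is
    excluded.
    """
    if not rsa.per_residue:
        raise ValueError("empty RSA table")
    allowed = set(restrict_to) if restrict_to is not None else None
    picked = [
        key
        for key, entry in rsa.per_residue.items()
        if entry.rsa > threshold_percent and (allowed is None or key in allowed)
    ]
    return sorted(picked, key=lambda k: (k[0], k[1], k[2]))
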