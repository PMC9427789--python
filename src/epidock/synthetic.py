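"""Synthetic fixtures with known ground truth for every pipeline stage.

All generators are pure functions of their parameters and seed: structures
with analytically known surface areas (sphere pairs), miniature Fv-antigen
complexes with a constructed contact set, docking-pose sets that are
rigid-body perturbations (near-native) or wrong-face placements (decoys) of
a reference complex, 4PL-generated ELISA panels with known Kd values, and
ortholog sequence pairs with planted differences.

Toy complexes use a pseudo-side-chain representation (CA plus one centroid
atom per residue): coarse enough for sub-second surface computations, rich
enough for meaningful accessibility loss at constructed contacts.

Each generator draws from its own RNG stream derived from (seed, generator
name) so that fixtures for different stages never couple.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .alascan import BindingCurve, four_pl
from .antibody import CHOTHIA_CDRS, FvAnnotation, annotate_fv
from .interface import Pose
from .structmodel import AtomRecord, Residue, ResidueKey, RigidTransform, StructureModel

__all__ = [
    "stream",
    "make_sphere_pair",
    "two_sphere_cap_area",
    "make_fv_complex",
    "make_pose_set",
    "make_elisa_panel",
    "make_ortholog_pair",
]

AA20 = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]
AA1 = "ACDEFGHIKLMNPQRSTVWY"

# residue names used for constructed paratope/epitope positions; none of
# A/G/P so that scan-design proposals keep them
_SCAN_FRIENDLY = ["ARG", "TYR", "ASP", "SER", "LEU", "HIS", "GLU", "THR", "PHE", "LYS"]


def stream(seed: int, name: str) -> np.random.Generator:
    """Independent RNG stream for one generator, derived from (seed, name)."""
    tag = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, tag])


# ------------------------------------------------------------- sphere pair

def make_sphere_pair(
    separation: float, radius: float = 1.7, element: str = "C"
) -> StructureModel:
    """Two single-atom chains at the stated separation along x.

    The analytic SASA/BSA of this system is known in closed form, which
    makes it the primary oracle for the surface-area code.
    """
    if separation <= 0:
        raise ValueError("separation must be positive")
    chains = {}
    for cid, x in (("A", 0.0), ("B", separation)):
        key: ResidueKey = (cid, 1, "")
        atom = AtomRecord(
            serial=1, name="CA", element=element, residue_key=key,
            coordinates=np.array([x, 0.0, 0.0]),
        )
        chains[cid] = [Residue(key=key, name="ALA", atoms=[atom])]
    return StructureModel(chains, metadata={"kind": "sphere_pair", "radius": radius})


def two_sphere_cap_area(expanded_radius: float, separation: float) -> float:
    """Spherical-cap area hidden on each of two equal spheres at distance d.

    For equal expanded radii R and center distance d < 2R, each sphere
    loses a cap of height h = R - d/2 with area 2*pi*R*h; this also equals
    the half-sum buried surface area of the pair.
    """
    R, d = expanded_radius, separation
    if d >= 2 * R:
        return 0.0
    return 2.0 * np.pi * R * (R - d / 2.0)


# --------------------------------------------------------- mini Fv complex

def _residue(
    cid: str, num: int, name: str, ca: np.ndarray, cb_offset: np.ndarray, serial: int
) -> Residue:
    key: ResidueKey = (cid, num, "")
    atoms = [
        AtomRecord(serial=serial, name="CA", element="C", residue_key=key,
                   coordinates=np.asarray(ca, dtype=float)),
    ]
    if name != "GLY":
        atoms.append(
            AtomRecord(serial=serial + 1, name="CB", element="C", residue_key=key,
                       coordinates=np.asarray(ca, dtype=float) + cb_offset)
        )
    return Residue(key=key, name=name, atoms=atoms)


@dataclass
class FvComplexSpec:
    seed: int = 0
    n_antigen: int = 30
    contact_gap: float = 4.5       # CA-CA distance across constructed contacts (A)
    noncontact_height: float = 18.0
    jitter: float = 0.15           # coordinate noise (A), keeps fixtures generic
    #: paratope residues placed in the contact plane, by (chain, Chothia number)
    paratope_sites: Tuple[Tuple[str, int], ...] = (
        ("H", 31), ("H", 33), ("H", 52), ("H", 95), ("H", 98), ("H", 100),
        ("L", 32), ("L", 50), ("L", 91), ("L", 96),
    )
    n_contacts: int = 8            # how many paratope sites receive an antigen partner


def make_fv_complex(
    spec: Optional[FvComplexSpec] = None,
) -> Tuple[Pose, FvAnnotation, Dict[str, Set[ResidueKey]]]:
    """Miniature antigen docked against a two-chain Fv with known contacts.

    The Fv (chains H and L, Chothia-compatible numbering 20-104) lies in a
    slab below z = 0 with designated paratope residues raised into the
    contact plane; the antigen (chain A) floats above with ``n_contacts``
    residues lowered onto distinct paratope sites at ``contact_gap``.
    Returns the pose, its Fv annotation and the constructed ground truth:
    ``{"antigen": ..., "antibody": ...}`` contact residue-key sets.
    """
    spec = spec or FvComplexSpec()
    rng = stream(spec.seed, "fv_complex")
    if spec.n_contacts > min(len(spec.paratope_sites), spec.n_antigen):
        raise ValueError("n_contacts exceeds available paratope sites or antigen size")

    paratope_plane: Dict[Tuple[str, int], np.ndarray] = {}
    chains: Dict[str, List[Residue]] = {}
    serial = 1
    # lay each Fv chain out as a compact grid slab below the contact plane
    # (10 residues per row keeps the toy ~45 A across, so small rigid-body
    # jiggles move no atom by more than ~2 A)
    for ci, cid in enumerate(("H", "L")):
        residues = []
        numbers = list(range(20, 105))
        sites = {num for c, num in spec.paratope_sites if c == cid}
        for i, num in enumerate(numbers):
            name = _SCAN_FRIENDLY[(i + ci) % len(_SCAN_FRIENDLY)]
            row, col = divmod(i, 10)
            base_y = ci * 50.0 + row * 5.0
            if num in sites:
                ca = np.array([col * 5.0, base_y, 0.0])
                cb = np.array([0.0, 0.0, 1.5])  # side chain points up at the antigen
                paratope_plane[(cid, num)] = ca
            else:
                ca = np.array([col * 5.0, base_y, -6.0 - (row % 2) * 4.0])
                cb = np.array([0.0, 0.0, -1.5])
            ca = ca + rng.normal(0.0, spec.jitter, 3)
            residues.append(_residue(cid, num, name, ca, cb, serial))
            serial += 2
        chains[cid] = residues

    # antigen: contact residues sit right above chosen paratope sites
    contact_sites = [
        spec.paratope_sites[i]
        for i in rng.choice(len(spec.paratope_sites), spec.n_contacts, replace=False)
    ]
    ag_residues = []
    truth_ag: Set[ResidueKey] = set()
    truth_ab: Set[ResidueKey] = {(c, n, "") for c, n in contact_sites}
    for i in range(spec.n_antigen):
        num = 40 + i
        name = _SCAN_FRIENDLY[i % len(_SCAN_FRIENDLY)]
        if i < len(contact_sites):
            below = paratope_plane[contact_sites[i]]
            ca = below + np.array([0.0, 0.0, spec.contact_gap])
            truth_ag.add(("A", num, ""))
        else:
            j = i - len(contact_sites)
            col, row = divmod(j, 2)
            ca = np.array([col * 5.0, 12.0 + row * 5.0, spec.noncontact_height])
        ca = ca + rng.normal(0.0, spec.jitter, 3)
        ag_residues.append(_residue("A", num, name, ca, np.array([0.0, 0.0, 1.5]), serial))
        serial += 2
    chains = {"A": ag_residues, **chains}

    model = StructureModel(chains, metadata={"kind": "fv_complex", "seed": spec.seed})
    pose = Pose(
        pose_id="reference",
        complex=model,
        antigen_chains={"A"},
        antibody_chains={"H", "L"},
    )
    annotation = annotate_fv(model, heavy="H", light="L")
    return pose, annotation, {"antigen": truth_ag, "antibody": truth_ab}


# --------------------------------------------------------------- pose sets

def _random_rotation(rng: np.random.Generator, max_angle_deg: float) -> np.ndarray:
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0.0, max_angle_deg))
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _rotation_about(center: np.ndarray, R: np.ndarray) -> RigidTransform:
    return RigidTransform(R, center - R @ center)


def make_pose_set(
    reference: Pose,
    n: int = 20,
    translation_mag: float = 0.8,
    rotation_mag_deg: float = 4.0,
    decoy_fraction: float = 0.5,
    seed: int = 0,
) -> Tuple[List[Pose], List[bool]]:
    """Near-native perturbations plus wrong-face decoys of a reference pose.

    Near-native poses jiggle the antibody by a small random rotation about
    its centroid plus a small translation. Decoys flip the antibody 180
    degrees about the x-axis through its own centroid — presenting its
    non-paratope face to the antigen at the same stand-off — then apply the
    same small jiggle. Returns (poses, is_near_native labels).
    """
    if n < 2:
        raise ValueError("need n >= 2 poses")
    if not 0.0 <= decoy_fraction <= 1.0:
        raise ValueError("decoy_fraction must lie in [0, 1]")
    rng = stream(seed, "pose_set")
    n_decoys = int(round(n * decoy_fraction))
    labels = [True] * (n - n_decoys) + [False] * n_decoys
    ab_coords = reference.complex.subset(
        sorted(reference.antibody_chains)
    ).coordinates()
    ab_centroid = ab_coords.mean(axis=0)
    flip = _rotation_about(
        ab_centroid, np.diag([1.0, -1.0, -1.0])  # 180 deg about x
    )
    # after flipping, raise the decoy so its (non-paratope) top face sits at
    # the same stand-off from the antigen as the native paratope plane did
    dz = ab_coords[:, 2].max() - flip.apply(ab_coords)[:, 2].max()
    flip = RigidTransform(flip.rotation, flip.translation + np.array([0.0, 0.0, dz]))
    poses: List[Pose] = []
    for i, near in enumerate(labels):
        if translation_mag > 0 or rotation_mag_deg > 0:
            R = _random_rotation(rng, rotation_mag_deg)
            t = rng.uniform(-translation_mag, translation_mag, 3)
            jiggle = _rotation_about(ab_centroid, R)
            jiggle = RigidTransform(jiggle.rotation, jiggle.translation + t)
        else:
            jiggle = RigidTransform.identity()
        transform = jiggle if near else jiggle.compose(flip)
        new_chains: Dict[str, List[Residue]] = {}
        for cid, residues in reference.complex.chains.items():
            if cid in reference.antibody_chains:
                moved = StructureModel({cid: residues}).transformed(transform)
                new_chains[cid] = moved.chains[cid]
            else:
                new_chains[cid] = residues
        poses.append(
            Pose(
                pose_id=f"pose{i:03d}",
                complex=StructureModel(new_chains),
                antigen_chains=set(reference.antigen_chains),
                antibody_chains=set(reference.antibody_chains),
                metadata={"near_native": near},
            )
        )
    return poses, labels


# -------------------------------------------------------------- ELISA panel

def make_elisa_panel(
    true_kds: Mapping[str, float],
    n_points: int = 10,
    top_concentration: float = 600.0,
    dilution_factor: float = 3.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    bottom: float = 0.05,
    top_signal: float = 2.0,
    hill: float = 1.0,
    unit: str = "nM",
) -> List[BindingCurve]:
    """4PL-generated dose-response panel emulating a serial-dilution ELISA.

    One curve per mutant; a "WT" entry is required so that downstream fold
    changes have a reference. The design is a ``dilution_factor``-fold
    serial dilution from ``top_concentration`` (default: three-fold, ten
    points — about 4.3 decades). Ground-truth fold change of mutant m is
    ``true_kds[m] / true_kds["WT"]``.
    """
    if "WT" not in true_kds:
        raise ValueError('panel must include a "WT" mutant as reference')
    if any(kd <= 0 for kd in true_kds.values()):
        raise ValueError("true Kd values must be positive")
    rng = stream(seed, "elisa_panel")
    conc = top_concentration / dilution_factor ** np.arange(n_points)
    curves = []
    for mutant, kd in true_kds.items():
        signal = four_pl(conc, bottom, top_signal, kd, hill)
        if noise_sigma > 0:
            signal = signal + rng.normal(0.0, noise_sigma, n_points)
        curves.append(
            BindingCurve(
                mutant_id=mutant,
                concentrations=conc.copy(),
                signals=signal,
                unit=unit,
            )
        )
    return curves


# ----------------------------------------------------------- ortholog pair

def make_ortholog_pair(
    length: int,
    planted_differences: Mapping[int, str],
    seed: int = 0,
    reference_letters: Optional[Mapping[int, str]] = None,
) -> Tuple[str, str]:
    """Random reference sequence and a query differing exactly where planted.

    ``planted_differences`` maps 1-based positions to the query residue at
    that position. ``reference_letters`` optionally pins the reference
    residue at chosen positions (e.g. to emulate a known species pair).
    A planted query letter equal to the reference letter at that position
    is resolved by re-drawing the reference letter, so the planted
    difference is always real.
    """
    rng = stream(seed, "ortholog_pair")
    for pos in planted_differences:
        if not 1 <= pos <= length:
            raise ValueError(f"planted position {pos} outside sequence length {length}")
    ref = [AA1[i] for i in rng.integers(0, len(AA1), length)]
    for pos, letter in (reference_letters or {}).items():
        if not 1 <= pos <= length:
            raise ValueError(f"reference position {pos} outside sequence length {length}")
        if letter.upper() not in AA1:
            raise ValueError(f"invalid reference letter {letter!r}")
        ref[pos - 1] = letter.upper()
    query = list(ref)
    for pos, letter in planted_differences.items():
        letter = letter.upper()
        if letter not in AA1:
            raise ValueError(f"invalid planted letter {letter!r}")
        if ref[pos - 1] == letter:
            if reference_letters and pos in reference_letters:
                raise ValueError(
                    f"position {pos}: planted query letter equals the pinned "
                    "reference letter; no difference would remain"
                )
            choices = [c for c in AA1 if c != letter]
            ref[pos - 1] = choices[int(rng.integers(0, len(choices)))]
        query[pos - 1] = letter
    return "".join(ref), "".join(query)
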