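"""PISA-style interface analysis of one docking pose.

Interface membership is defined by accessibility loss: a residue is at the
interface when its SASA computed in the isolated binding partner exceeds
its SASA in the complex by at least a small threshold (default 0.1 A^2,
suppressing quadrature noise). Buried surface area follows the PISA
half-sum convention,

    BSA = (SASA_antigen + SASA_antibody - SASA_complex) / 2,

so that values are on the same scale as PISA "interface area" numbers.
Per-region percentages partition the antibody-side buried area over the
six CDRs and the framework (CDR_total + FWR = 100 by construction).

Cross-molecule atom contacts are typed geometrically with a fixed
precedence (salt bridge > hydrogen bond > attractive charge > nonpolar);
pi-system interactions are folded into the attractive-charge class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .antibody import FvAnnotation
from .sasa import SasaParams, SasaResult, shrake_rupley
from .structmodel import ResidueKey, StructureModel

__all__ = [
    "Pose",
    "InterfaceResidue",
    "InterfaceReport",
    "Contact",
    "ContactCutoffs",
    "interface_residues",
    "buried_surface_area",
    "region_contributions",
    "classify_contacts",
    "analyze_pose",
]

REGION_LABELS = ("H1", "H2", "H3", "L1", "L2", "L3")


@dataclass
class Pose:
    """One candidate antibody-antigen arrangement.

    ``binding_energy`` (e.g. a docking score; lower = better) is input
    metadata and is never computed here.
    """

    pose_id: str
    complex: StructureModel
    antigen_chains: Set[str]
    antibody_chains: Set[str]
    binding_energy: Optional[float] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.antigen_chains = set(self.antigen_chains)
        self.antibody_chains = set(self.antibody_chains)
        if not self.antigen_chains or not self.antibody_chains:
            raise ValueError("antigen and antibody chain sets must be non-empty")
        if self.antigen_chains & self.antibody_chains:
            raise ValueError("antigen and antibody chain sets must be disjoint")
        missing = (self.antigen_chains | self.antibody_chains) - set(
            self.complex.chains
        )
        if missing:
            raise ValueError(f"pose {self.pose_id}: chains absent from model: {missing}")

    def antigen(self) -> StructureModel:
        return self.complex.subset(sorted(self.antigen_chains))

    def antibody(self) -> StructureModel:
        return self.complex.subset(sorted(self.antibody_chains))


@dataclass
class InterfaceResidue:
    residue_key: ResidueKey
    side: str          # "antigen" | "antibody"
    delta_sasa: float  # A^2 buried on complexation
    region: Optional[str] = None


@dataclass
class InterfaceReport:
    pose_id: str
    bsa: float
    interface_residues: List[InterfaceResidue]
    region_percent: Dict[str, float] = field(default_factory=dict)

    def side(self, which: str) -> List[InterfaceResidue]:
        return [r for r in self.interface_residues if r.side == which]

    def antibody_keys(self) -> Set[ResidueKey]:
        return {r.residue_key for r in self.side("antibody")}

    def antigen_keys(self) -> Set[ResidueKey]:
        return {r.residue_key for r in self.side("antigen")}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "pose_id": self.pose_id,
                    "chain": r.residue_key[0],
                    "resnum": r.residue_key[1],
                    "icode": r.residue_key[2],
                    "side": r.side,
                    "delta_sasa_A2": r.delta_sasa,
                    "region": r.region or "",
                }
                for r in self.interface_residues
            ]
        )

    def summary_json(self) -> str:
        return json.dumps(
            {
                "pose_id": self.pose_id,
                "bsa_A2": self.bsa,
                "region_percent": self.region_percent,
            },
            indent=2,
        )


def _delta_per_residue(
    pose: Pose, params: SasaParams
) -> Tuple[Dict[ResidueKey, float], float]:
    """Per-residue SASA loss on complexation and the half-sum BSA."""
    complex_sasa = shrake_rupley(pose.complex, params)
    ag_sasa = shrake_rupley(pose.antigen(), params)
    ab_sasa = shrake_rupley(pose.antibody(), params)
    iso: Dict[ResidueKey, float] = {}
    iso.update(ag_sasa.per_residue)
    iso.update(ab_sasa.per_residue)
    delta = {
        key: iso[key] - complex_sasa.per_residue.get(key, 0.0) for key in iso
    }
    bsa = 0.5 * (ag_sasa.total + ab_sasa.total - complex_sasa.total)
    return delta, bsa


def interface_residues(
    pose: Pose,
    params: Optional[SasaParams] = None,
    delta_threshold: float = 0.1,
) -> List[InterfaceResidue]:
    """Residues whose SASA drops by at least ``delta_threshold`` on binding."""
    params = params or SasaParams()
    delta, _ = _delta_per_residue(pose, params)
    out = []
    for key, d in delta.items():
        if d >= delta_threshold:
            side = "antigen" if key[0] in pose.antigen_chains else "antibody"
            out.append(InterfaceResidue(residue_key=key, side=side, delta_sasa=d))
    out.sort(key=lambda r: (r.residue_key[0], r.residue_key[1], r.residue_key[2]))
    return out


def buried_surface_area(pose: Pose, params: Optional[SasaParams] = None) -> float:
    """Interface area in the PISA half-sum convention (A^2)."""
    params = params or SasaParams()
    _, bsa = _delta_per_residue(pose, params)
    return bsa


def region_contributions(
    interface: Sequence[InterfaceResidue],
    annotation: FvAnnotation,
    denominator: str = "antibody",
) -> Dict[str, float]:
    """Percent of buried area per antibody region.

    ``denominator="antibody"`` normalises by the antibody-side buried area
    (so CDR_total + FWR = 100); ``"total"`` normalises by both sides.
    """
    ab_side = [r for r in interface if r.side == "antibody"]
    if not ab_side:
        raise ValueError("no antibody-side interface residues to partition")
    by_region: Dict[str, float] = {label: 0.0 for label in REGION_LABELS}
    fwr = 0.0
    for res in ab_side:
        try:
            label = annotation.numbering[res.residue_key][1]
        except KeyError:
            raise ValueError(
                f"antibody-side interface residue {res.residue_key} is not annotated"
            ) from None
        res.region = label
        if label in by_region:
            by_region[label] += res.delta_sasa
        else:
            fwr += res.delta_sasa
    ab_total = sum(by_region.values()) + fwr
    if denominator == "antibody":
        denom = ab_total
    elif denominator == "total":
        denom = sum(r.delta_sasa for r in interface)
    else:
        raise ValueError(f"unknown denominator mode {denominator!r}")
    pct = {label: 100.0 * v / denom for label, v in by_region.items()}
    pct["CDR_total"] = sum(pct[label] for label in REGION_LABELS)
    pct["FWR"] = 100.0 * fwr / denom
    return pct


# ------------------------------------------------------------- contacts

@dataclass
class ContactCutoffs:
    hbond: float = 3.5
    salt: float = 4.0
    charge: float = 5.6
    nonpolar: float = 4.5

    @property
    def max_cutoff(self) -> float:
        return max(self.hbond, self.salt, self.charge, self.nonpolar)


@dataclass
class Contact:
    antigen_atom: Tuple[ResidueKey, str]
    antibody_atom: Tuple[ResidueKey, str]
    distance: float
    type: str  # hydrogen_bond | salt_bridge | attractive_charge | nonpolar


# sidechain atom dictionaries (backbone N is a donor, backbone O/OXT acceptors)
_DONORS: Dict[str, Set[str]] = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
    "ASN": {"ND2"}, "GLN": {"NE2"}, "HIS": {"ND1", "NE2"}, "TRP": {"NE1"},
    "LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"},
}
_ACCEPTORS: Dict[str, Set[str]] = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "HIS": {"ND1", "NE2"}, "MET": {"SD"},
}
_POSITIVE: Dict[str, Set[str]] = {
    "LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"}, "HIS": {"ND1", "NE2"},
}
_NEGATIVE: Dict[str, Set[str]] = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"},
}


def _atom_roles(resname: str, atom_name: str, element: str):
    donor = atom_name == "N" or atom_name in _DONORS.get(resname, set())
    acceptor = (
        atom_name in ("O", "OXT")
        or atom_name in _ACCEPTORS.get(resname, set())
    )
    positive = atom_name in _POSITIVE.get(resname, set())
    negative = atom_name in _NEGATIVE.get(resname, set()) or atom_name == "OXT"
    nonpolar = element == "C"
    return donor, acceptor, positive, negative, nonpolar


def classify_contacts(
    pose: Pose,
    cutoffs: Optional[ContactCutoffs] = None,
    include_hydrogens: bool = False,
) -> List[Contact]:
    """Geometrically typed cross-molecule atom contacts.

    Each antigen-antibody atom pair within range is reported once with the
    most specific applicable type: salt_bridge (opposite formal charges
    within the salt cutoff) > hydrogen_bond (donor/acceptor pair within the
    H-bond cutoff) > attractive_charge (opposite charges within the longer
    electrostatic cutoff) > nonpolar (carbon-carbon within the apolar
    cutoff).
    """
    cutoffs = cutoffs or ContactCutoffs()

    def collect(model: StructureModel):
        atoms = []
        for res in model.residues():
            for a in res.atoms:
                if a.is_hydrogen and not include_hydrogens:
                    continue
                atoms.append((res.key, a.name, res.name, a.element, a.coordinates))
        return atoms

    ag = collect(pose.antigen())
    ab = collect(pose.antibody())
    if not ag or not ab:
        return []
    ag_xyz = np.vstack([a[4] for a in ag])
    ab_xyz = np.vstack([a[4] for a in ab])
    tree = cKDTree(ab_xyz)
    pairs = tree.query_ball_point(ag_xyz, cutoffs.max_cutoff)
    contacts: List[Contact] = []
    for i, neighbours in enumerate(pairs):
        ag_key, ag_name, ag_res, ag_el, ag_c = ag[i]
        ag_roles = _atom_roles(ag_res, ag_name, ag_el)
        for j in neighbours:
            ab_key, ab_name, ab_res, ab_el, ab_c = ab[j]
            d = float(np.linalg.norm(ag_c - ab_c))
            ab_roles = _atom_roles(ab_res, ab_name, ab_el)
            ctype = _contact_type(ag_roles, ab_roles, d, cutoffs)
            if ctype is not None:
                contacts.append(
                    Contact(
                        antigen_atom=(ag_key, ag_name),
                        antibody_atom=(ab_key, ab_name),
                        distance=d,
                        type=ctype,
                    )
                )
    contacts.sort(
        key=lambda c: (c.antigen_atom[0], c.antigen_atom[1], c.antibody_atom[0],
                       c.antibody_atom[1])
    )
    return contacts


def _contact_type(roles_a, roles_b, distance, cutoffs: ContactCutoffs):
    donor_a, acceptor_a, pos_a, neg_a, np_a = roles_a
    donor_b, acceptor_b, pos_b, neg_b, np_b = roles_b
    opposite = (pos_a and neg_b) or (neg_a and pos_b)
    if opposite and distance <= cutoffs.salt:
        return "salt_bridge"
    if ((donor_a and acceptor_b) or (acceptor_a and donor_b)) and distance <= cutoffs.hbond:
        return "hydrogen_bond"
    if opposite and distance <= cutoffs.charge:
        return "attractive_charge"
    if np_a and np_b and distance <= cutoffs.nonpolar:
        return "nonpolar"
    return None


def contacts_to_frame(contacts: Sequence[Contact]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "antigen_chain": c.antigen_atom[0][0],
                "antigen_resnum": c.antigen_atom[0][1],
                "antigen_atom": c.antigen_atom[1],
                "antibody_chain": c.antibody_atom[0][0],
                "antibody_resnum": c.antibody_atom[0][1],
                "antibody_atom": c.antibody_atom[1],
                "distance_A": c.distance,
                "type": c.type,
            }
            for c in contacts
        ]
    )


def analyze_pose(
    pose: Pose,
    annotation: Optional[FvAnnotation] = None,
    params: Optional[SasaParams] = None,
    delta_threshold: float = 0.1,
) -> InterfaceReport:
    """Full interface report for one pose (BSA, residues, region partition)."""
    params = params or SasaParams()
    delta, bsa = _delta_per_residue(pose, params)
    residues = []
    for key, d in delta.items():
        if d >= delta_threshold:
            side = "antigen" if key[0] in pose.antigen_chains else "antibody"
            residues.append(InterfaceResidue(residue_key=key, side=side, delta_sasa=d))
    residues.sort(key=lambda r: (r.residue_key[0], r.residue_key[1], r.residue_key[2]))
    report = InterfaceReport(pose_id=pose.pose_id, bsa=bsa, interface_residues=residues)
    if annotation is not None and any(r.side == "antibody" for r in residues):
        report.region_percent = region_contributions(residues, annotation)
    return report
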