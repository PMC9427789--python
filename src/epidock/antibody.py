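"""Fv annotation (Chothia CDR spans vs framework) and CDR statistics.

Residue numbers are taken as already being in the Chothia scheme (either
native to the input model or supplied through a numbering table); automatic
renumbering from sequence is deliberately out of scope. CDR boundaries
follow the standard Chothia table; insertion-coded residues (e.g. H52A)
belong to the span of their parent number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import pandas as pd

from .structmodel import ResidueKey, StructureModel

__all__ = [
    "CHOTHIA_CDRS",
    "FvAnnotation",
    "CdrStats",
    "annotate_fv",
    "region_of",
    "cdr_charge",
    "cdr_stats",
    "select_scan_positions",
    "BUROSUMAB_HCDR3",
]

#: Chothia CDR spans (inclusive residue-number ranges in Chothia numbering).
CHOTHIA_CDRS: Dict[str, Tuple[int, int]] = {
    "H1": (26, 32),
    "H2": (52, 56),
    "H3": (95, 102),
    "L1": (24, 34),
    "L2": (50, 56),
    "L3": (89, 97),
}

#: Burosumab heavy-chain CDR3 (Chothia 95-102), from the published antibody
#: sequence. Net formal charge -3 (three aspartates, no basic residues).
BUROSUMAB_HCDR3: str = "DIVDAFDF"

FORMAL_CHARGE = {"D": -1, "E": -1, "K": +1, "R": +1}

#: Residues counted as polar or charged for CDR composition statistics.
POLAR_CHARGED = set("DEKRHNQSTYWC")

#: plausible Chothia Fv numbering range
_FV_NUMBER_RANGE = (1, 130)

_PROPOSAL_EXCLUDED = {"ALA", "GLY", "PRO"}


@dataclass
class FvAnnotation:
    heavy_chain: str
    light_chain: str
    #: residue key -> (scheme position string, region label)
    numbering: Dict[ResidueKey, Tuple[str, str]]
    #: region label -> ordered residue keys
    regions: Dict[str, List[ResidueKey]]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chain": k[0],
                "resnum": k[1],
                "icode": k[2],
                "scheme_position": pos,
                "region": region,
            }
            for k, (pos, region) in self.numbering.items()
        ]
        return pd.DataFrame(rows)

    @property
    def cdr_keys(self) -> List[ResidueKey]:
        out: List[ResidueKey] = []
        for label in ("H1", "H2", "H3", "L1", "L2", "L3"):
            out.extend(self.regions.get(label, []))
        return out


@dataclass
class CdrStats:
    region: str
    length: int
    net_charge: int
    polar_charged_fraction: float


def annotate_fv(
    model: StructureModel,
    heavy: str,
    light: str,
    numbering_table: Optional[Mapping[ResidueKey, str]] = None,
    cdr_spans: Optional[Mapping[str, Tuple[int, int]]] = None,
) -> FvAnnotation:
    """Assign every heavy/light residue to a CDR or framework region.

    ``numbering_table`` optionally maps author residue keys to Chothia
    position strings (e.g. "52A"); without it, the model's own residue
    numbers are taken to be Chothia numbers already.
    """
    spans = dict(cdr_spans) if cdr_spans is not None else CHOTHIA_CDRS

    def region_for(number: int, role: str) -> str:
        prefix = "H" if role == "heavy" else "L"
        for label, (lo, hi) in spans.items():
            if label.startswith(prefix) and lo <= number <= hi:
                return label
        return f"FW_{prefix}"

    for cid in (heavy, light):
        if cid not in model.chains:
            raise ValueError(f"chain {cid!r} not present in model")

    numbering: Dict[ResidueKey, Tuple[str, str]] = {}
    regions: Dict[str, List[ResidueKey]] = {
        label: [] for label in ("H1", "H2", "H3", "L1", "L2", "L3", "FW_H", "FW_L")
    }
    for cid, role in ((heavy, "heavy"), (light, "light")):
        for res in model.chains[cid]:
            if numbering_table is not None and res.key in numbering_table:
                pos_str = str(numbering_table[res.key])
                digits = "".join(ch for ch in pos_str if ch.isdigit() or ch == "-")
                number = int(digits)
            else:
                number = res.key[1]
                pos_str = f"{number}{res.key[2]}"
            lo, hi = _FV_NUMBER_RANGE
            if not lo <= number <= hi:
                raise ValueError(
                    f"residue {res.key}: scheme number {number} outside the "
                    f"plausible Fv range {lo}-{hi}"
                )
            label = region_for(number, role)
            numbering[res.key] = (pos_str, label)
            regions[label].append(res.key)
    return FvAnnotation(
        heavy_chain=heavy, light_chain=light, numbering=numbering, regions=regions
    )


def region_of(annotation: FvAnnotation, residue: ResidueKey) -> str:
    try:
        return annotation.numbering[residue][1]
    except KeyError:
        raise KeyError(f"residue {residue} is not annotated") from None


def cdr_charge(
    annotation: FvAnnotation,
    sequence: Mapping[ResidueKey, str],
    region: str,
    histidine_charge: float = 0.0,
) -> float:
    """Net formal charge of a region: D/E -> -1, K/R -> +1, H -> configurable.

    Histidine's charge at assay pH is ambiguous; default treats it neutral.
    Returns an int when histidine_charge is integral.
    """
    if region not in annotation.regions:
        raise ValueError(f"unknown region {region!r}")
    total = 0.0
    for key in annotation.regions[region]:
        try:
            letter = sequence[key].upper()
        except KeyError:
            raise ValueError(f"no sequence letter for residue {key}") from None
        if letter == "H":
            total += histidine_charge
        elif letter in FORMAL_CHARGE:
            total += FORMAL_CHARGE[letter]
        elif letter not in "ACDEFGHIKLMNPQRSTVWY":
            raise ValueError(f"unknown amino-acid letter {letter!r} at {key}")
    return int(total) if float(total).is_integer() else total


def cdr_stats(
    annotation: FvAnnotation,
    sequence: Mapping[ResidueKey, str],
    region: str,
    histidine_charge: float = 0.0,
) -> CdrStats:
    keys = annotation.regions[region]
    letters = [sequence[k].upper() for k in keys]
    n_polar = sum(1 for x in letters if x in POLAR_CHARGED)
    return CdrStats(
        region=region,
        length=len(keys),
        net_charge=int(cdr_charge(annotation, sequence, region, histidine_charge)),
        polar_charged_fraction=100.0 * n_polar / len(keys) if keys else 0.0,
    )


def select_scan_positions(
    annotation: FvAnnotation,
    rsa,  # RsaTable
    threshold_percent: float = 20.0,
    flank: int = 2,
) -> List[ResidueKey]:
    """Alanine-scan design: solvent-exposed CDR residues plus framework flanks.

    Candidates are every CDR residue plus ``flank`` framework residues on
    each side of each CDR (in chain order); of these, residues with RSA
    strictly above the threshold are kept, and alanine/glycine/proline
    positions are dropped (self-mutation is vacuous; G/P are structural).
    """
    from .sasa import select_exposed  # local import to avoid cycle

    exposed = set(select_exposed(rsa, threshold_percent))
    candidates: Dict[ResidueKey, None] = {}
    # chain order of annotated residues per chain
    by_chain: Dict[str, List[ResidueKey]] = {}
    for key in annotation.numbering:
        by_chain.setdefault(key[0], []).append(key)
    for chain, keys in by_chain.items():
        labels = [annotation.numbering[k][1] for k in keys]
        for i, (key, label) in enumerate(zip(keys, labels)):
            if label.startswith("FW"):
                continue
            candidates[key] = None
            # flanking framework residues around CDR boundaries
            if i == 0 or labels[i - 1] != label:  # CDR start
                for j in range(max(0, i - flank), i):
                    if labels[j].startswith("FW"):
                        candidates[keys[j]] = None
            if i == len(keys) - 1 or labels[i + 1] != label:  # CDR end
                for j in range(i + 1, min(len(keys), i + 1 + flank)):
                    if labels[j].startswith("FW"):
                        candidates[keys[j]] = None
    picked = []
    for key in candidates:
        if key not in exposed:
            continue
        entry = rsa.per_residue.get(key)
        if entry is not None and entry.resname in _PROPOSAL_EXCLUDED:
            continue
        picked.append(key)
    return sorted(picked, key=lambda k: (k[0], k[1], k[2]))
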