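"""Seven-criterion docking-pose assessment, filtering and ranking.

A candidate pose is judged by (1) stereo blockage of the antigen's receptor
binding site, (2) binding energy (input metadata, e.g. a docking score),
(3) percent agreement with paratope alanine-scanning data, (4) buried
surface area, (5) %FWR, (6) %CDR and (7) %H3 contributions to the
interface. Poses failing hard filters (minimum interface area, plausible
%CDR window, minimum blockage grade) are set aside with the reason
recorded; survivors are ordered lexicographically by a documented key
(concordance desc, blockage desc, binding energy asc, BSA desc, pose id),
which makes the qualitative dominance argument of pose selection
reproducible.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .alascan import Bin, HotspotTable
from .interface import InterfaceReport, Pose, interface_residues
from .sasa import SasaParams
from .structmodel import (
    ResidueKey,
    StructureModel,
    kabsch,
    paired_coordinates,
)

__all__ = [
    "BlockageGrade",
    "BlockageReport",
    "ConcordanceReport",
    "CriteriaRow",
    "PoseRankingResult",
    "RankFilters",
    "receptor_blockage",
    "paratope_concordance",
    "assemble_criteria",
    "rank_poses",
    "criteria_to_frame",
    "criteria_from_frame",
]


class BlockageGrade(enum.IntEnum):
    LOW = 0
    MEDIUM = 1
    HIGH = 2

    @property
    def label(self) -> str:
        return self.name.lower()


@dataclass
class BlockageReport:
    pose_id: str
    receptor_footprint: Set[Tuple[int, str]]   # antigen (resnum, icode)
    antibody_footprint: Set[Tuple[int, str]]
    overlap_fraction: float
    clash_count: int
    grade: BlockageGrade
    superposition_rmsd: float = float("nan")


def _footprint_numbers(keys: Iterable[ResidueKey]) -> Set[Tuple[int, str]]:
    # antigen chain ids may differ between pose and reference files; compare
    # by residue number + insertion code
    return {(k[1], k[2]) for k in keys}


def receptor_blockage(
    pose: Pose,
    reference_complex: StructureModel,
    reference_antigen_chains: Iterable[str],
    receptor_chains: Iterable[str],
    params: Optional[SasaParams] = None,
    superposition_atom: str = "CA",
    delta_threshold: float = 0.1,
    clash_cutoff: float = 2.5,
    grade_thresholds: Tuple[float, float] = (0.5, 0.2),
) -> BlockageReport:
    """How much of the receptor's footprint on the antigen the pose occludes.

    The pose's antigen is superposed (Kabsch over shared CA atoms) onto the
    antigen of the reference antigen-receptor complex. The receptor
    footprint is the set of antigen residues at the antigen-receptor
    interface of the reference; the antibody footprint is the set of
    antigen residues at the pose's interface. The report carries the
    overlap fraction |intersection| / |receptor footprint|, atom clashes
    (< ``clash_cutoff``) between the superposed antibody and the receptor,
    and a config-thresholded grade (default: high >= 0.5, medium >= 0.2).
    """
    params = params or SasaParams()
    ref_ag = list(reference_antigen_chains)
    rec = list(receptor_chains)

    ref_pose = Pose(
        pose_id="reference",
        complex=reference_complex.subset(ref_ag + rec),
        antigen_chains=set(ref_ag),
        antibody_chains=set(rec),
    )
    receptor_fp = _footprint_numbers(
        r.residue_key
        for r in interface_residues(ref_pose, params, delta_threshold)
        if r.side == "antigen"
    )
    if not receptor_fp:
        raise ValueError("reference complex has no antigen-receptor interface")

    antibody_fp = _footprint_numbers(
        r.residue_key
        for r in interface_residues(pose, params, delta_threshold)
        if r.side == "antigen"
    )

    # superpose the pose antigen onto the reference antigen
    P, Q = paired_coordinates(
        pose.antigen(),
        reference_complex.subset(ref_ag),
        atom_name=superposition_atom,
        key_map="number",
    )
    transform, rmsd = kabsch(P, Q)
    moved = pose.complex.transformed(transform)
    ab_xyz = moved.subset(sorted(pose.antibody_chains)).coordinates(
        include_hydrogens=False
    )
    rec_xyz = reference_complex.subset(rec).coordinates(include_hydrogens=False)
    clash_count = 0
    if len(ab_xyz) and len(rec_xyz):
        tree = cKDTree(rec_xyz)
        clash_count = int(sum(len(hits) for hits in tree.query_ball_point(ab_xyz, clash_cutoff)))

    overlap = len(antibody_fp & receptor_fp) / len(receptor_fp)
    hi, med = grade_thresholds
    grade = (
        BlockageGrade.HIGH
        if overlap >= hi
        else BlockageGrade.MEDIUM if overlap >= med else BlockageGrade.LOW
    )
    return BlockageReport(
        pose_id=pose.pose_id,
        receptor_footprint=receptor_fp,
        antibody_footprint=antibody_fp,
        overlap_fraction=overlap,
        clash_count=clash_count,
        grade=grade,
        superposition_rmsd=rmsd,
    )


@dataclass
class ConcordanceReport:
    pose_id: str
    #: rows: (residue key, experimental bin, predicted-at-interface flag)
    per_residue: List[Tuple[ResidueKey, Bin, bool]]
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def percent_correlation(self) -> float:
        total = self.tp + self.tn + self.fp + self.fn
        return 100.0 * (self.tp + self.tn) / total if total else 0.0


def paratope_concordance(
    pose_interface: InterfaceReport,
    hotspots: HotspotTable,
    positive_bin: Bin = Bin.STAR,
) -> ConcordanceReport:
    """Agreement between scanning data and the pose's antibody interface.

    A tested paratope residue is experimentally positive when its fold-
    decrease bin is at least ``positive_bin``, and predicted positive when
    it appears on the antibody side of the pose interface. The score is
    balanced agreement, 100 * (TP + TN) / tested.
    """
    tested = [r for r in hotspots.records.values() if r.residue_key is not None]
    if not tested:
        raise ValueError("hotspot table carries no residue-keyed paratope records")
    predicted = pose_interface.antibody_keys()
    rows: List[Tuple[ResidueKey, Bin, bool]] = []
    tp = tn = fp = fn = 0
    for rec in tested:
        exp_pos = rec.bin >= positive_bin
        pred_pos = rec.residue_key in predicted
        rows.append((rec.residue_key, rec.bin, pred_pos))
        if exp_pos and pred_pos:
            tp += 1
        elif exp_pos and not pred_pos:
            fn += 1
        elif not exp_pos and pred_pos:
            fp += 1
        else:
            tn += 1
    return ConcordanceReport(
        pose_id=pose_interface.pose_id, per_residue=rows, tp=tp, tn=tn, fp=fp, fn=fn
    )


@dataclass
class CriteriaRow:
    pose_id: str
    blockage_grade: BlockageGrade
    binding_energy: Optional[float]
    percent_correlation: float
    bsa: float
    fwr_percent: float
    cdr_percent: float
    h3_percent: float


def assemble_criteria(
    poses: Sequence[Pose],
    interface_reports: Mapping[str, InterfaceReport],
    blockage_reports: Mapping[str, BlockageReport],
    concordance_reports: Mapping[str, ConcordanceReport],
) -> List[CriteriaRow]:
    """One complete seven-criterion row per pose; missing reports are errors."""
    rows = []
    for pose in poses:
        pid = pose.pose_id
        for name, reports in (
            ("interface", interface_reports),
            ("blockage", blockage_reports),
            ("concordance", concordance_reports),
        ):
            if pid not in reports:
                raise KeyError(f"pose {pid!r}: missing {name} report")
        iface = interface_reports[pid]
        pct = iface.region_percent
        if not pct:
            if iface.side("antibody"):
                raise ValueError(
                    f"pose {pid!r}: interface report lacks region partition"
                )
            # no antibody-side buried area: the pose forms no real interface;
            # zeroed percentages make it fail the %CDR/BSA filters downstream
            pct = {label: 0.0 for label in ("H1", "H2", "H3", "L1", "L2", "L3",
                                            "CDR_total", "FWR")}
        rows.append(
            CriteriaRow(
                pose_id=pid,
                blockage_grade=blockage_reports[pid].grade,
                binding_energy=pose.binding_energy,
                percent_correlation=concordance_reports[pid].percent_correlation,
                bsa=iface.bsa,
                fwr_percent=pct["FWR"],
                cdr_percent=pct["CDR_total"],
                h3_percent=pct["H3"],
            )
        )
    return rows


@dataclass
class RankFilters:
    min_bsa: float = 800.0
    cdr_percent_range: Tuple[float, float] = (50.0, 95.0)
    min_blockage: BlockageGrade = BlockageGrade.LOW


@dataclass
class PoseRankingResult:
    passed: List[str]
    failed: Dict[str, List[str]]
    ordering_key_trace: Dict[str, tuple]

    def to_json(self) -> str:
        return json.dumps(
            {
                "passed": self.passed,
                "failed": self.failed,
                "ordering_key_trace": {
                    k: list(v) for k, v in self.ordering_key_trace.items()
                },
            },
            indent=2,
            sort_keys=True,
        )


def _sort_key(row: CriteriaRow) -> tuple:
    energy_missing = row.binding_energy is None
    return (
        -row.percent_correlation,
        -int(row.blockage_grade),
        energy_missing,  # poses lacking an energy sort after those with one
        row.binding_energy if not energy_missing else 0.0,
        -row.bsa,
        row.pose_id,
    )


def rank_poses(
    rows: Sequence[CriteriaRow],
    filters: Optional[RankFilters] = None,
) -> PoseRankingResult:
    """Filter-then-lexicographic ranking of criteria rows (best first).

    Filters: BSA above ``min_bsa``, %CDR within the plausible window,
    blockage at least ``min_blockage``. Order: percent correlation desc,
    blockage grade desc, binding energy asc (absent energies after present
    ones), BSA desc, then pose id as the final alphabetical tie-break.
    """
    if not rows:
        raise ValueError("no criteria rows to rank")
    filters = filters or RankFilters()
    passed_rows: List[CriteriaRow] = []
    failed: Dict[str, List[str]] = {}
    lo, hi = filters.cdr_percent_range
    for row in rows:
        reasons = []
        if row.bsa <= filters.min_bsa:
            reasons.append("min_bsa")
        if not lo <= row.cdr_percent <= hi:
            reasons.append("cdr_percent_range")
        if row.blockage_grade < filters.min_blockage:
            reasons.append("min_blockage")
        if reasons:
            failed[row.pose_id] = reasons
        else:
            passed_rows.append(row)
    passed_rows.sort(key=_sort_key)
    return PoseRankingResult(
        passed=[r.pose_id for r in passed_rows],
        failed=failed,
        ordering_key_trace={r.pose_id: _sort_key(r) for r in rows},
    )


def assess_poses(
    poses: Sequence[Pose],
    annotation,
    hotspots: HotspotTable,
    reference_complex: StructureModel,
    reference_antigen_chains: Iterable[str],
    receptor_chains: Iterable[str],
    params: Optional[SasaParams] = None,
    filters: Optional[RankFilters] = None,
    positive_bin: Bin = Bin.STAR,
    delta_threshold: float = 0.1,
) -> Tuple[List[CriteriaRow], PoseRankingResult]:
    """Run the full per-pose assessment and ranking over a pose set.

    Convenience wrapper chaining interface analysis, receptor blockage,
    scanning concordance, criteria assembly and ranking.
    """
    from .interface import analyze_pose

    params = params or SasaParams()
    ref_ag = list(reference_antigen_chains)
    rec = list(receptor_chains)
    interfaces: Dict[str, InterfaceReport] = {}
    blockages: Dict[str, BlockageReport] = {}
    concordances: Dict[str, ConcordanceReport] = {}
    for pose in poses:
        report = analyze_pose(pose, annotation, params, delta_threshold)
        interfaces[pose.pose_id] = report
        blockages[pose.pose_id] = receptor_blockage(
            pose, reference_complex, ref_ag, rec,
            params=params, delta_threshold=delta_threshold,
        )
        concordances[pose.pose_id] = paratope_concordance(
            report, hotspots, positive_bin
        )
    rows = assemble_criteria(list(poses), interfaces, blockages, concordances)
    return rows, rank_poses(rows, filters)


# ------------------------------------------------------------------ CSV I/O

_CRITERIA_COLUMNS = [
    "pose_id", "blockage", "binding_energy", "pct_correlation",
    "bsa_A2", "pct_fwr", "pct_cdr", "pct_h3",
]


def criteria_to_frame(rows: Sequence[CriteriaRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pose_id": r.pose_id,
                "blockage": r.blockage_grade.label,
                "binding_energy": (
                    r.binding_energy if r.binding_energy is not None else np.nan
                ),
                "pct_correlation": r.percent_correlation,
                "bsa_A2": r.bsa,
                "pct_fwr": r.fwr_percent,
                "pct_cdr": r.cdr_percent,
                "pct_h3": r.h3_percent,
            }
            for r in rows
        ],
        columns=_CRITERIA_COLUMNS,
    )


def criteria_from_frame(frame: pd.DataFrame) -> List[CriteriaRow]:
    rows = []
    for _, rec in frame.iterrows():
        energy = rec["binding_energy"]
        rows.append(
            CriteriaRow(
                pose_id=str(rec["pose_id"]),
                blockage_grade=BlockageGrade[str(rec["blockage"]).upper()],
                binding_energy=None if pd.isna(energy) else float(energy),
                percent_correlation=float(rec["pct_correlation"]),
                bsa=float(rec["bsa_A2"]),
                fwr_percent=float(rec["pct_fwr"]),
                cdr_percent=float(rec["pct_cdr"]),
                h3_percent=float(rec["pct_h3"]),
            )
        )
    return rows
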