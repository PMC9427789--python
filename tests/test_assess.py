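import itertools

import numpy as np
import pytest

from conftest import build_chain, truth_hotspot_table
from epidock.alascan import Bin, FoldChangeRecord, HotspotTable
from epidock.assess import (
    BlockageGrade,
    CriteriaRow,
    RankFilters,
    assemble_criteria,
    assess_poses,
    criteria_from_frame,
    criteria_to_frame,
    paratope_concordance,
    rank_poses,
    receptor_blockage,
)
from epidock.interface import InterfaceReport, InterfaceResidue, Pose
from epidock.sasa import SasaParams
from epidock.structmodel import StructureModel
from epidock.synthetic import make_pose_set

PARAMS = SasaParams(n_points=240)


def row_structure(cid, n, z, spacing=8.0, x0=0.0):
    # zig-zag in y keeps the chain non-collinear for superposition
    spec = [
        (i + 1, "", "SER", [("CA", "C", [x0 + i * spacing, 3.0 * (i % 2), z])])
        for i in range(n)
    ]
    return build_chain(cid, spec)


def blockage_toy(n_covered):
    """Antigen row of 10; receptor covers all 10; antibody covers n_covered."""
    reference = StructureModel(
        {"A": row_structure("A", 10, 0.0), "R": row_structure("R", 10, 4.0)}
    )
    pose_model = StructureModel(
        {"A": row_structure("A", 10, 0.0), "B": row_structure("B", max(n_covered, 1), 4.0)}
    )
    pose = Pose("p", pose_model, {"A"}, {"B"})
    if n_covered == 0:  # antibody far away
        pose_model = StructureModel(
            {"A": row_structure("A", 10, 0.0), "B": row_structure("B", 1, 300.0)}
        )
        pose = Pose("p", pose_model, {"A"}, {"B"})
    return pose, reference


class TestReceptorBlockage:
    def test_full_overlap_high(self):
        pose, reference = blockage_toy(10)
        report = receptor_blockage(pose, reference, ["A"], ["R"], PARAMS)
        assert report.overlap_fraction == pytest.approx(1.0)
        assert report.grade == BlockageGrade.HIGH
        assert report.superposition_rmsd <= 1e-8

    def test_disjoint_low(self):
        pose, reference = blockage_toy(0)
        report = receptor_blockage(pose, reference, ["A"], ["R"], PARAMS)
        assert report.overlap_fraction == 0.0
        assert report.grade == BlockageGrade.LOW

    def test_half_overlap(self):
        pose, reference = blockage_toy(5)
        report = receptor_blockage(pose, reference, ["A"], ["R"], PARAMS)
        assert report.overlap_fraction == pytest.approx(0.5)
        assert report.grade == BlockageGrade.HIGH  # default high cut is 0.5

    def test_clash_detection(self):
        pose, reference = blockage_toy(10)  # antibody atoms coincide with receptor
        report = receptor_blockage(pose, reference, ["A"], ["R"], PARAMS)
        assert report.clash_count >= 10

    def test_overlap_invariant_under_pose_transform(self):
        from epidock.structmodel import RigidTransform

        pose, reference = blockage_toy(5)
        base = receptor_blockage(pose, reference, ["A"], ["R"], PARAMS)
        K = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 0]], dtype=float)
        R = np.eye(3) + np.sin(0.7) * K + (1 - np.cos(0.7)) * (K @ K)
        moved = pose.complex.transformed(RigidTransform(R, np.array([3.0, -7.0, 11.0])))
        moved_pose = Pose("p", moved, {"A"}, {"B"})
        report = receptor_blockage(moved_pose, reference, ["A"], ["R"], PARAMS)
        assert report.overlap_fraction == pytest.approx(base.overlap_fraction)


def concordance_inputs(n_tested, positives, predicted):
    records = {}
    for i in range(n_tested):
        key = ("H", i + 1, "")
        pos = i in positives
        records[f"m{i}"] = FoldChangeRecord(
            mutant_id=f"m{i}",
            mode="kd_ratio",
            fold=None if pos else 1.0,
            censored=pos,
            censor_bound=100.0,
            bin=Bin.STAR3 if pos else Bin.NONE,
            residue_key=key,
        )
    iface = InterfaceReport(
        pose_id="p",
        bsa=500.0,
        interface_residues=[
            InterfaceResidue(("H", i + 1, ""), "antibody", 5.0) for i in predicted
        ],
    )
    return iface, HotspotTable(records)


class TestParatopeConcordance:
    def test_all_correct_is_100(self):
        iface, hotspots = concordance_inputs(10, {0, 1}, {0, 1})
        report = paratope_concordance(iface, hotspots)
        assert report.percent_correlation == pytest.approx(100.0)

    def test_all_wrong_is_0(self):
        iface, hotspots = concordance_inputs(4, {0, 1}, {2, 3})
        report = paratope_concordance(iface, hotspots)
        assert report.percent_correlation == pytest.approx(0.0)

    def test_counting_example(self):
        # 56 tested, 5 positives; 4 recovered, 3 false positives
        positives = set(range(5))
        predicted = {0, 1, 2, 3, 10, 11, 12}
        iface, hotspots = concordance_inputs(56, positives, predicted)
        report = paratope_concordance(iface, hotspots)
        assert (report.tp, report.fn, report.fp, report.tn) == (4, 1, 3, 48)
        assert report.percent_correlation == pytest.approx(100 * 52 / 56)

    def test_adding_correct_prediction_never_decreases(self):
        for extra in range(5, 10):
            iface_a, hotspots = concordance_inputs(10, {0, 1}, {0})
            iface_b, _ = concordance_inputs(10, {0, 1}, {0, 1})
            a = paratope_concordance(iface_a, hotspots).percent_correlation
            b = paratope_concordance(iface_b, hotspots).percent_correlation
            assert b >= a

    def test_empty_table_rejected(self):
        iface, _ = concordance_inputs(3, set(), set())
        with pytest.raises(ValueError):
            paratope_concordance(iface, HotspotTable({}))


def fig_rows():
    """Criteria rows for the three top scenario poses (printed interface
    metrics; concordance/blockage orderings as reported)."""
    return [
        CriteriaRow("pose27", BlockageGrade.HIGH, -120.0, 92.0, 906.7, 22.23, 77.77, 22.21),
        CriteriaRow("pose39", BlockageGrade.MEDIUM, -110.0, 88.0, 859.3, 13.47, 86.53, 15.91),
        CriteriaRow("pose180", BlockageGrade.HIGH, -105.0, 85.0, 920.8, 13.96, 86.04, 14.05),
    ]


class TestRankPoses:
    def test_worked_example_pose27_first(self):
        result = rank_poses(fig_rows())
        assert result.passed[0] == "pose27"
        assert result.passed == ["pose27", "pose39", "pose180"]
        assert not result.failed

    def test_small_bsa_filtered(self):
        rows = fig_rows() + [
            CriteriaRow("poseX", BlockageGrade.HIGH, -130.0, 99.0, 700.0, 20.0, 80.0, 25.0)
        ]
        result = rank_poses(rows)
        assert "poseX" in result.failed
        assert result.failed["poseX"] == ["min_bsa"]

    def test_identical_rows_tie_break_alphabetical(self):
        a = CriteriaRow("poseA", BlockageGrade.HIGH, -1.0, 90.0, 900.0, 20.0, 80.0, 20.0)
        b = CriteriaRow("poseB", BlockageGrade.HIGH, -1.0, 90.0, 900.0, 20.0, 80.0, 20.0)
        assert rank_poses([b, a]).passed == ["poseA", "poseB"]

    def test_permutation_invariant(self):
        rows = fig_rows()
        expected = rank_poses(rows).to_json()
        for perm in itertools.permutations(rows):
            assert rank_poses(list(perm)).to_json() == expected

    def test_missing_energy_sorts_after(self):
        a = CriteriaRow("poseA", BlockageGrade.HIGH, None, 90.0, 900.0, 20.0, 80.0, 20.0)
        b = CriteriaRow("poseB", BlockageGrade.HIGH, -5.0, 90.0, 900.0, 20.0, 80.0, 20.0)
        assert rank_poses([a, b]).passed == ["poseB", "poseA"]

    def test_filters_sound(self):
        rows = fig_rows()
        result = rank_poses(rows, RankFilters(min_bsa=900.0))
        assert set(result.passed) | set(result.failed) == {r.pose_id for r in rows}
        assert not (set(result.passed) & set(result.failed))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            rank_poses([])


class TestAssembleCriteria:
    def test_csv_round_trip(self):
        rows = fig_rows()
        frame = criteria_to_frame(rows)
        back = criteria_from_frame(frame)
        assert [r.pose_id for r in back] == [r.pose_id for r in rows]
        for orig, new in zip(rows, back):
            assert new.bsa == pytest.approx(orig.bsa)
            assert new.blockage_grade == orig.blockage_grade
            assert new.h3_percent == pytest.approx(orig.h3_percent)

    def test_missing_report_names_pose(self, fv_complex):
        pose, annotation, truth = fv_complex
        from epidock.interface import analyze_pose

        report = analyze_pose(pose, annotation, PARAMS)
        with pytest.raises(KeyError, match="reference"):
            assemble_criteria([pose], {pose.pose_id: report}, {}, {})


class TestEndToEnd:
    def test_near_native_ranks_first(self, fv_complex):
        reference, annotation, truth = fv_complex
        hotspots = truth_hotspot_table(annotation, truth["antibody"])
        poses, labels = make_pose_set(reference, n=10, decoy_fraction=0.5, seed=42)
        near = {p.pose_id for p, is_near in zip(poses, labels) if is_near}
        rows, result = assess_poses(
            poses,
            annotation,
            hotspots,
            reference.complex,
            ["A"],
            ["H", "L"],
            params=PARAMS,
            filters=RankFilters(min_bsa=50.0, cdr_percent_range=(50.0, 100.0)),
        )
        assert result.passed, "no pose survived filtering"
        assert result.passed[0] in near
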