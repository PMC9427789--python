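import numpy as np
import pytest

from conftest import build_chain
from epidock.sasa import (
    MAX_ASA_THEORETICAL,
    RsaEntry,
    RsaTable,
    SasaParams,
    monte_carlo_sasa,
    relative_accessibility,
    select_exposed,
    shrake_rupley,
)
from epidock.structmodel import RigidTransform, StructureModel
from epidock.synthetic import make_sphere_pair, two_sphere_cap_area

EXPANDED_R = 1.7 + 1.4  # carbon + probe


def carbon_cluster(rng, n, box=6.0):
    spec = [
        (i + 1, "", "ALA", [("CA", "C", rng.uniform(0, box, 3))])
        for i in range(n)
    ]
    return StructureModel({"A": build_chain("A", spec)})


class TestShrakeRupley:
    def test_single_atom_analytic(self):
        model = make_sphere_pair(separation=500.0)
        result = shrake_rupley(model, SasaParams(n_points=960))
        per_atom = 4 * np.pi * EXPANDED_R**2
        for area in result.per_atom.values():
            assert area == pytest.approx(per_atom, rel=0.02)

    def test_distant_atoms_additive(self):
        model = make_sphere_pair(separation=100.0)
        result = shrake_rupley(model)
        iso = 4 * np.pi * EXPANDED_R**2
        assert result.total == pytest.approx(2 * iso, abs=1e-9)

    @pytest.mark.parametrize("separation", [1.0, 2.5, 3.1, 4.5, 5.9])
    def test_two_sphere_cap_formula(self, separation):
        model = make_sphere_pair(separation)
        result = shrake_rupley(model, SasaParams(n_points=960))
        iso = 4 * np.pi * EXPANDED_R**2
        cap = two_sphere_cap_area(EXPANDED_R, separation)
        expected_per_sphere = iso - cap
        for area in result.per_atom.values():
            assert area == pytest.approx(expected_per_sphere, rel=0.02)

    def test_per_residue_sums_match_per_atom(self, fv_complex):
        pose, _, _ = fv_complex
        result = shrake_rupley(pose.complex, SasaParams(n_points=240))
        regrouped = {}
        for (rkey, _), area in result.per_atom.items():
            regrouped[rkey] = regrouped.get(rkey, 0.0) + area
        for rkey, area in result.per_residue.items():
            assert area == pytest.approx(regrouped[rkey], abs=1e-9)
        assert result.total == pytest.approx(sum(result.per_residue.values()), abs=1e-6)

    def test_deterministic(self):
        model = make_sphere_pair(3.0)
        a = shrake_rupley(model)
        b = shrake_rupley(model)
        assert a.per_atom == b.per_atom

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(7)
        model = carbon_cluster(rng, 8)
        params = SasaParams(n_points=5000)
        base = shrake_rupley(model, params).total
        axis = np.array([1.0, 2.0, 2.0]) / 3.0
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(1.1) * K + (1 - np.cos(1.1)) * (K @ K)
        moved = model.transformed(RigidTransform(R, np.array([5.0, -3.0, 8.0])))
        assert shrake_rupley(moved, params).total == pytest.approx(base, rel=1e-3)

    def test_far_chain_changes_nothing(self):
        rng = np.random.default_rng(8)
        model = carbon_cluster(rng, 6)
        base = shrake_rupley(model)
        far_spec = [(1, "", "ALA", [("CA", "C", [500.0, 500.0, 500.0])])]
        combined = StructureModel(
            {"A": model.chains["A"], "Z": build_chain("Z", far_spec)}
        )
        with_far = shrake_rupley(combined)
        for key, area in base.per_atom.items():
            assert abs(with_far.per_atom[key] - area) <= 1e-9

    def test_unknown_element_without_fallback(self):
        spec = [(1, "", "ALA", [("XX", "XX", [0.0, 0.0, 0.0])])]
        model = StructureModel({"A": build_chain("A", spec)})
        params = SasaParams(fallback_radius=None)
        with pytest.raises(ValueError, match="radius"):
            shrake_rupley(model, params)

    def test_lattice_convergence(self):
        # single-atom-pair error shrinks (in expectation) with lattice density
        rng = np.random.default_rng(9)
        errors = {240: [], 960: [], 5000: []}
        for _ in range(10):
            sep = rng.uniform(1.0, 5.5)
            model = make_sphere_pair(sep)
            iso = 4 * np.pi * EXPANDED_R**2
            truth = 2 * (iso - two_sphere_cap_area(EXPANDED_R, sep))
            for n in errors:
                total = shrake_rupley(model, SasaParams(n_points=n)).total
                errors[n].append(abs(total - truth) / truth)
        assert np.mean(errors[960]) < np.mean(errors[240])
        assert np.mean(errors[5000]) < np.mean(errors[960])


class TestMonteCarlo:
    def test_matches_analytic_single_sphere(self):
        model = make_sphere_pair(separation=100.0)
        result = monte_carlo_sasa(model, n_samples=100_000, seed=11)
        iso = 4 * np.pi * EXPANDED_R**2
        for key, area in result.per_atom.items():
            se = max(result.per_atom_se[key], 1e-12)
            assert abs(area - iso) <= max(3 * se, 1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_lattice_on_random_clusters(self, seed):
        rng = np.random.default_rng(100 + seed)
        model = carbon_cluster(rng, int(rng.integers(3, 11)))
        sr = shrake_rupley(model, SasaParams(n_points=5000))
        mc = monte_carlo_sasa(model, n_samples=20_000, seed=seed)
        se_total = np.sqrt(sum(s**2 for s in mc.per_atom_se.values()))
        assert abs(sr.total - mc.total) <= max(3 * se_total, 0.01)

    def test_seed_determinism(self):
        model = make_sphere_pair(3.0)
        a = monte_carlo_sasa(model, n_samples=1000, seed=5)
        b = monte_carlo_sasa(model, n_samples=1000, seed=5)
        assert a.per_atom == b.per_atom

    def test_rejects_tiny_sample_size(self):
        with pytest.raises(ValueError):
            monte_carlo_sasa(make_sphere_pair(3.0), n_samples=50)


class TestCrossCheckBiotite:
    def test_matches_independent_implementation(self):
        # biotite's Shrake-Rupley with single-atom (Bondi) radii should agree
        # closely on an all-carbon cluster
        biotite_structure = pytest.importorskip("biotite.structure")
        rng = np.random.default_rng(12)
        model = carbon_cluster(rng, 10)
        coords = model.coordinates()
        atoms = biotite_structure.AtomArray(len(coords))
        atoms.coord = coords.astype(np.float32)
        atoms.chain_id[:] = "A"
        atoms.res_id[:] = np.arange(1, len(coords) + 1)
        atoms.res_name[:] = "ALA"
        atoms.atom_name[:] = "CA"
        atoms.element[:] = "C"
        ref = float(
            biotite_structure.sasa(
                atoms, probe_radius=1.4, point_number=2000, vdw_radii="Single"
            ).sum()
        )
        ours = shrake_rupley(model, SasaParams(n_points=2000)).total
        assert ours == pytest.approx(ref, rel=0.02)


class TestRsa:
    def make_table(self, values):
        return RsaTable(
            per_residue={
                ("A", num, ""): RsaEntry(0.0, 100.0, rsa, "SER")
                for num, rsa in values.items()
            },
            reference_set_name="synthetic",
        )

    def test_full_exposure_is_100(self):
        model = make_sphere_pair(100.0)
        sasa = shrake_rupley(model)
        rsa = relative_accessibility(sasa, model, "observed_max")
        for entry in rsa.per_residue.values():
            assert entry.rsa == pytest.approx(100.0)

    def test_theoretical_reference_arithmetic(self):
        model = make_sphere_pair(100.0)
        sasa = shrake_rupley(model)
        rsa = relative_accessibility(sasa, model, "tien2013_theoretical")
        iso = 4 * np.pi * EXPANDED_R**2
        for entry in rsa.per_residue.values():
            assert entry.reference_max == MAX_ASA_THEORETICAL["ALA"]
            assert entry.rsa == pytest.approx(100.0 * iso / 129.0, rel=0.02)

    def test_buried_residue_is_zero(self):
        table = self.make_table({10: 0.0})
        assert table.per_residue[("A", 10, "")].rsa == 0.0
        assert select_exposed(table, 20.0) == []

    def test_nonstandard_residue_excluded(self):
        spec = [(1, "", "XYZ", [("CA", "C", [0.0, 0.0, 0.0])])]
        model = StructureModel({"A": build_chain("A", spec)})
        rsa = relative_accessibility(shrake_rupley(model), model)
        assert ("A", 1, "") in rsa.excluded
        assert not rsa.per_residue


class TestSelectExposed:
    def test_simple_threshold(self):
        table = TestRsa().make_table({10: 25.0, 11: 5.0})
        assert select_exposed(table, 20.0) == [("A", 10, "")]

    def test_exact_threshold_excluded(self):
        table = TestRsa().make_table({10: 20.0})
        assert select_exposed(table, 20.0) == []

    def test_all_buried_gives_empty(self):
        table = TestRsa().make_table({i: 0.0 for i in range(5)})
        assert select_exposed(table, 20.0) == []

    def test_restrict_to(self):
        table = TestRsa().make_table({10: 50.0, 11: 50.0, 12: 50.0})
        picked = select_exposed(table, 20.0, restrict_to=[("A", 11, "")])
        assert picked == [("A", 11, "")]

    def test_empty_table_is_error(self):
        with pytest.raises(ValueError):
            select_exposed(RsaTable({}, "x"), 20.0)
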