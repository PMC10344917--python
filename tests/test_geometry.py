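"""Clash counting, pose similarity, strain gates, Kabsch, SASA and BSA."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ternary_sar.geometry import (
    GeometryError,
    ModelMetrics,
    StructureModel,
    assembly_filter,
    buried_surface_area,
    count_clashes,
    kabsch_rmsd,
    model_selection,
    sasa,
    warhead_similarity,
)
from ternary_sar.synthetic import (
    GeneratorSpec,
    generate_toy_complex,
    two_sphere_analytic_areas,
)


def _model(coords, components, subs=None, radii=None, elements=None):
    n = len(coords)
    return StructureModel(
        coords=np.asarray(coords, float),
        elements=tuple(elements or ["C"] * n),
        components=tuple(components),
        sub_labels=tuple(subs) if subs else None,
        radii=None if radii is None else np.asarray(radii, float),
    )


class TestClashes:
    def test_cutoff_is_strict(self):
        assert count_clashes([[0, 0, 0]], [[2.1, 0, 0]]) == 1
        assert count_clashes([[0, 0, 0]], [[2.3, 0, 0]]) == 0
        assert count_clashes([[0, 0, 0]], [[2.2, 0, 0]]) == 0

    def test_matches_brute_force_on_random_systems(self, rng):
        for _ in range(100):
            a = rng.uniform(-5, 5, size=(rng.integers(1, 20), 3))
            b = rng.uniform(-5, 5, size=(rng.integers(1, 20), 3))
            brute = sum(
                1
                for p in a
                for q in b
                if np.linalg.norm(p - q) < 2.2
            )
            assert count_clashes(a, b) == brute

    def test_empty_subset_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert count_clashes(np.empty((0, 3)), [[0, 0, 0]]) == 0


class TestAssemblyFilter:
    @pytest.mark.parametrize(
        "pp, pl, keep",
        [(5, 2, True), (6, 0, False), (0, 3, False), (0, 0, True)],
    )
    def test_printed_thresholds(self, pp, pl, keep):
        verdict, reasons = assembly_filter(ModelMetrics(clashes_pp=pp, clashes_pl=pl))
        assert verdict is keep
        assert bool(reasons) is (not keep)

    def test_unpopulated_counts_rejected(self):
        with pytest.raises(GeometryError):
            assembly_filter(ModelMetrics())


class TestModelSelection:
    @pytest.mark.parametrize(
        "strain, rmsd, prune, select",
        [
            (0.5, 2.0, True, True),
            (0.7, 2.0, True, False),
            (4.5, 1.0, False, False),
            (0.5, 3.5, True, False),
        ],
    )
    def test_two_stage_gates(self, strain, rmsd, prune, select):
        verdict = model_selection(strain, rmsd)
        assert verdict["prune_pass"] is prune
        assert verdict["select_pass"] is select

    def test_missing_strain_pruned_with_reason(self):
        verdict = model_selection(None, 1.0)
        assert not verdict["prune_pass"]
        assert verdict["reason"] == "no strain available"


class TestKabsch:
    def test_identity(self):
        a = np.random.default_rng(0).normal(size=(8, 3))
        assert kabsch_rmsd(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_transform_recovers_zero(self, rng):
        for _ in range(20):
            a = rng.normal(size=(12, 3))
            rot = Rotation.random(rng=rng).as_matrix()
            b = a @ rot.T + rng.normal(size=3)
            assert kabsch_rmsd(a, b) == pytest.approx(0.0, abs=1e-9)

    def test_symmetric(self, rng):
        a = rng.normal(size=(10, 3))
        b = rng.normal(size=(10, 3))
        assert kabsch_rmsd(a, b) == pytest.approx(kabsch_rmsd(b, a), rel=1e-10)

    def test_uniform_displacement_absorbed_by_translation(self):
        # shifting every atom equally is a pure translation: RMSD 0
        a = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0]], float)
        b = a + np.array([0.0, 0.0, 1.0])
        assert kabsch_rmsd(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_known_in_plane_distortion(self):
        # stretch a unit square along x by +d on each side after optimal
        # alignment: residual is exactly d at every corner
        d = 0.3
        a = np.array([[1, 1, 0], [1, -1, 0], [-1, -1, 0], [-1, 1, 0]], float)
        b = a.copy()
        b[:, 0] *= 1 + d
        assert kabsch_rmsd(a, b) == pytest.approx(d, rel=1e-9)

    def test_count_mismatch_rejected(self):
        with pytest.raises(GeometryError):
            kabsch_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))


class TestWarheadSimilarity:
    def _base_model(self):
        rng = np.random.default_rng(42)
        ligase = rng.normal(scale=3, size=(10, 3)) + [0, 0, 8]
        # anisotropic warhead: elongated along x, flat-ish in z
        warhead = np.column_stack([
            np.linspace(-3, 3, 8),
            0.4 * rng.normal(size=8),
            0.1 * rng.normal(size=8),
        ])
        coords = np.vstack([ligase, warhead])
        comps = ["ligase"] * 10 + ["protac"] * 8
        subs = [None] * 10 + ["target_warhead"] * 8
        return _model(coords, comps, subs)

    def test_self_similarity(self):
        m = self._base_model()
        cog, a1, a2, similar = warhead_similarity(m, m)
        assert cog == pytest.approx(0.0, abs=1e-9)
        assert a1 == pytest.approx(0.0, abs=1e-6)
        assert similar

    def test_translation_beyond_cutoff(self):
        m = self._base_model()
        mask = m.sub_label_mask("target_warhead")
        coords = m.coords.copy()
        coords[mask] += [0, 7.0, 0]
        shifted = _model(coords, m.components, m.sub_labels)
        cog, a1, a2, similar = warhead_similarity(m, shifted)
        assert cog == pytest.approx(7.0, abs=1e-9)
        assert not similar

    def test_rotation_about_minor_axis_reads_as_first_axis_angle(self):
        m = self._base_model()
        mask = m.sub_label_mask("target_warhead")
        coords = m.coords.copy()
        w = coords[mask]
        center = w.mean(axis=0)
        rot = Rotation.from_euler("z", 25, degrees=True).as_matrix()
        coords[mask] = (w - center) @ rot.T + center
        rotated = _model(coords, m.components, m.sub_labels)
        cog, a1, a2, similar = warhead_similarity(m, rotated)
        assert a1 == pytest.approx(25.0, abs=2.0)
        assert not similar

    def test_too_few_warhead_atoms(self):
        m = _model(
            [[0, 0, 0], [1, 0, 0], [2, 0, 0], [0, 1, 0]],
            ["ligase", "ligase", "ligase", "protac"],
            [None, None, None, "target_warhead"],
        )
        with pytest.raises(GeometryError):
            warhead_similarity(m, m, align_on_ligase=False)


class TestSasa:
    def test_single_sphere_analytic(self):
        m = _model([[0, 0, 0]], ["ligase"], radii=[1.6], elements=["S"])
        assert sasa(m, probe=1.4) == pytest.approx(4 * math.pi * 3.0**2, rel=5e-3)

    def test_distant_spheres_additive(self):
        m = _model(
            [[0, 0, 0], [50, 0, 0]], ["ligase", "target"],
            radii=[1.6, 1.6], elements=["S", "S"],
        )
        single = 4 * math.pi * 3.0**2
        assert sasa(m) == pytest.approx(2 * single, rel=5e-3)

    def test_two_sphere_cap_formula(self):
        # centers 2 A apart, expanded radius 3: lost caps h = 2 each
        m = _model(
            [[0, 0, 0], [2, 0, 0]], ["ligase", "target"],
            radii=[1.6, 1.6], elements=["S", "S"],
        )
        analytic = two_sphere_analytic_areas(1.6, 2.0, 1.4)["sasa_total"]
        assert sasa(m, n_points=960) == pytest.approx(analytic, rel=5e-3)

    def test_quadrature_converges(self):
        m = _model(
            [[0, 0, 0], [2, 0, 0]], ["ligase", "target"],
            radii=[1.6, 1.6], elements=["S", "S"],
        )
        analytic = two_sphere_analytic_areas(1.6, 2.0, 1.4)["sasa_total"]
        err_coarse = abs(sasa(m, n_points=240) - analytic)
        err_fine = abs(sasa(m, n_points=4000) - analytic)
        assert err_fine < err_coarse

    def test_hydrogens_ignored_by_default(self):
        m = _model(
            [[0, 0, 0], [1.0, 0, 0]], ["ligase", "ligase"], elements=["C", "H"]
        )
        only_c = _model([[0, 0, 0]], ["ligase"], elements=["C"])
        assert sasa(m) == pytest.approx(sasa(only_c))

    def test_unknown_element_named_in_error(self):
        with pytest.raises(GeometryError, match="Xx"):
            _model([[0, 0, 0]], ["ligase"], elements=["Xx"])


class TestBsa:
    def test_disjoint_components_zero(self):
        m = _model(
            [[0, 0, 0], [50, 0, 0], [100, 0, 0]],
            ["ligase", "protac", "target"],
            radii=[1.6, 1.6, 1.6], elements=["S", "S", "S"],
        )
        areas = buried_surface_area(m)
        assert areas["bsa_total"] == pytest.approx(0.0, abs=1e-6)
        assert areas["bsa_protein_protein"] == 0.0

    def test_two_sphere_overlap_value(self):
        # ligase+target pair split as two components, no PROTAC burial
        m = _model(
            [[0, 0, 0], [2, 0, 0], [200, 0, 0]],
            ["ligase", "target", "protac"],
            radii=[1.6, 1.6, 1.6], elements=["S", "S", "S"],
        )
        truth = two_sphere_analytic_areas(1.6, 2.0, 1.4)["bsa"]
        areas = buried_surface_area(m)
        assert areas["bsa_total"] == pytest.approx(truth, rel=0.01)
        assert areas["bsa_protein_protein"] == pytest.approx(truth, rel=0.01)
        assert areas["bsa_protein_protac"] == pytest.approx(0.0, abs=0.5)

    def test_toy_complex_matches_analytic_truth(self):
        model, truth = generate_toy_complex(GeneratorSpec())
        areas = buried_surface_area(model, n_points=4000)
        assert areas["bsa_total"] == pytest.approx(truth["bsa_total"], rel=0.01)
        assert areas["bsa_protein_protein"] == pytest.approx(
            truth["bsa_protein_protein"], rel=0.01
        )
        assert areas["bsa_protein_protac"] == pytest.approx(
            truth["bsa_protein_protac"], rel=0.01
        )

    def test_terms_sum_to_total(self):
        model, _ = generate_toy_complex(GeneratorSpec(), separation=2.5)
        areas = buried_surface_area(model)
        assert areas["bsa_protein_protein"] + areas["bsa_protein_protac"] == (
            pytest.approx(areas["bsa_total"])
        )

    def test_rigid_motion_invariance_within_quadrature(self, rng):
        # the deterministic lattice is fixed in space, so rotating the
        # molecule perturbs the estimate only at the quadrature-error level
        model, _ = generate_toy_complex(GeneratorSpec())
        base = buried_surface_area(model)["bsa_total"]
        rot = Rotation.random(rng=rng).as_matrix()
        moved = model.transformed(rot, np.array([3.0, -7.0, 11.0]))
        assert buried_surface_area(moved)["bsa_total"] == pytest.approx(
            base, rel=0.01
        )

    def test_relabeling_permutation_invariance(self):
        model, _ = generate_toy_complex(GeneratorSpec())
        swapped = StructureModel(
            coords=model.coords,
            elements=model.elements,
            components=tuple(
                {"ligase": "target", "target": "ligase"}.get(c, c)
                for c in model.components
            ),
            radii=model.radii,
        )
        a = buried_surface_area(model)
        b = buried_surface_area(swapped)
        assert a["bsa_total"] == pytest.approx(b["bsa_total"])
        assert a["bsa_protein_protein"] == pytest.approx(b["bsa_protein_protein"])

    def test_missing_component_rejected(self):
        m = _model([[0, 0, 0], [2, 0, 0]], ["ligase", "target"],
                   radii=[1.6, 1.6], elements=["S", "S"])
        with pytest.raises(GeometryError):
            buried_surface_area(m)
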