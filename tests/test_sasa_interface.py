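"""Shrake–Rupley SASA against closed-form sphere geometry and an
independent library, and interface metrics on engineered fixtures."""

import numpy as np
import pytest

from sdscam.structmetrics import (
    buried_surface_area,
    interface_residues,
    shrake_rupley_sasa,
    sphere_points,
)
from sdscam.structmetrics.model import StructureModel
from sdscam.structmetrics.sasa import VDW_RADII
from sdscam.synthcells import ToyStructureSpec, generate_toy_dimer

from conftest import single_atom_model

R_C = VDW_RADII["C"] + 1.4  # inflated carbon radius


def _atoms(rows):
    """rows: (chain, res_id, res_name, atom_name, element, xyz)"""
    return StructureModel.from_arrays(
        [r[0] for r in rows], [r[1] for r in rows], [r[2] for r in rows],
        [r[3] for r in rows], [r[4] for r in rows],
        np.array([r[5] for r in rows], float),
    )


def _two_sphere_accessible(t: float) -> float:
    """Closed form: accessible area of one of two equal spheres of radius
    R_C whose centers are t apart (spherical-cap occlusion)."""
    cap_height = R_C - t / 2.0
    return 4 * np.pi * R_C**2 - 2 * np.pi * R_C * cap_height


class TestSasa:
    def test_isolated_carbon_matches_sphere_area(self):
        result = shrake_rupley_sasa(single_atom_model("C"))
        assert result.total == pytest.approx(4 * np.pi * 3.1**2, rel=1e-6)
        assert result.total == pytest.approx(120.76, abs=0.01)

    def test_far_apart_atoms_sum_isolated_areas(self):
        model = _atoms([
            ("A", 1, "ALA", "CA", "C", (0, 0, 0)),
            ("A", 2, "ALA", "CA", "C", (50, 0, 0)),
        ])
        result = shrake_rupley_sasa(model)
        assert result.total == pytest.approx(2 * 4 * np.pi * 3.1**2, rel=1e-6)

    @pytest.mark.parametrize("t", [1.5, 3.0, 4.5])
    def test_overlapping_spheres_match_cap_formula(self, t):
        model = _atoms([
            ("A", 1, "ALA", "CA", "C", (0, 0, 0)),
            ("A", 2, "ALA", "CA", "C", (t, 0, 0)),
        ])
        result = shrake_rupley_sasa(model)
        expected = 2 * _two_sphere_accessible(t)
        assert abs(result.total - expected) / expected < 0.01

    def test_point_count_convergence(self):
        model = generate_toy_dimer(
            ToyStructureSpec(n_residues=40, translation=np.array([6.0, 0.0, 0.0]))
        )
        coarse = shrake_rupley_sasa(model, n_points=960).total
        fine = shrake_rupley_sasa(model, n_points=4000).total
        assert abs(coarse - fine) / fine < 0.02

    def test_matches_independent_library(self):
        """Cross-check against biotite's Shrake–Rupley with the same vdW
        radii, probe, and a comparable point count."""
        import biotite.structure as struc

        model = generate_toy_dimer(
            ToyStructureSpec(
                n_residues=30, seed=2, translation=np.array([8.0, 0.0, 0.0])
            )
        )
        mine = shrake_rupley_sasa(model, n_points=2000)

        arr = struc.AtomArray(len(model))
        arr.coord = model.coords
        arr.chain_id = model.chain_ids.astype(str)
        arr.res_id = model.res_ids
        arr.res_name = model.res_names.astype(str)
        arr.atom_name = model.atom_names.astype(str)
        arr.element = model.elements.astype(str)
        theirs = struc.sasa(
            arr, probe_radius=1.4, point_number=2000,
            vdw_radii=np.full(len(model), VDW_RADII["C"]),
        )
        assert abs(mine.total - theirs.sum()) / theirs.sum() < 0.02

    def test_unknown_element_gets_fallback_radius_with_warning(self):
        model = single_atom_model("ZZ")
        with pytest.warns(UserWarning, match="fallback"):
            result = shrake_rupley_sasa(model)
        assert result.total == pytest.approx(4 * np.pi * (1.8 + 1.4) ** 2, rel=1e-6)

    def test_deterministic_point_set(self):
        assert np.array_equal(sphere_points(960), sphere_points(960))
        norms = np.linalg.norm(sphere_points(500), axis=1)
        assert np.allclose(norms, 1.0, atol=1e-12)

    def test_hetero_excluded_by_default(self):
        model = _atoms([("A", 1, "ALA", "CA", "C", (0, 0, 0))])
        water = StructureModel.from_arrays(
            ["A"], [101], ["HOH"], ["O"], ["O"], np.array([[10.0, 0, 0]]),
            hetero=[True],
        )
        from sdscam.structmetrics.interface import _concatenate

        merged = _concatenate(model, water)
        with_het = shrake_rupley_sasa(merged, include_hetero=True)
        without = shrake_rupley_sasa(merged)
        assert len(without.per_atom) == 1
        assert len(with_het.per_atom) == 2


class TestBuriedSurfaceArea:
    def test_far_apart_protomers_bury_nothing(self):
        a = single_atom_model("C", (0, 0, 0))
        b = single_atom_model("C", (100, 0, 0), chain="B")
        report = buried_surface_area(a, b)
        assert report.bsa_total == pytest.approx(0.0, abs=1e-9)
        assert report.contacts == []

    @pytest.mark.parametrize("t", [2.0, 4.0])
    def test_two_sphere_protomers_match_cap_oracle(self, t):
        a = single_atom_model("C", (0, 0, 0))
        b = single_atom_model("C", (t, 0, 0), chain="B")
        report = buried_surface_area(a, b)
        expected = 2 * 2 * np.pi * R_C * (R_C - t / 2.0)  # both caps
        assert abs(report.bsa_total - expected) / expected < 0.01
        assert report.bsa_half == pytest.approx(report.bsa_total / 2)

    def test_symmetry_in_protomer_order(self):
        model = generate_toy_dimer(
            ToyStructureSpec(n_residues=25, translation=np.array([4.0, 0.0, 0.0]))
        )
        a, b = model.chain("A"), model.chain("B")
        ab = buried_surface_area(a, b)
        ba = buried_surface_area(b, a)
        assert ab.bsa_total == pytest.approx(ba.bsa_total, abs=1e-6)

    def test_bsa_zero_iff_no_contacts(self):
        model = generate_toy_dimer(
            ToyStructureSpec(n_residues=20, translation=np.array([60.0, 0.0, 0.0]))
        )
        report = buried_surface_area(model.chain("A"), model.chain("B"))
        assert report.bsa_total == pytest.approx(0.0, abs=1e-9)
        assert report.contacts == []

    def test_identical_coordinates_rejected(self):
        a = single_atom_model("C")
        with pytest.raises(ValueError, match="identical"):
            buried_surface_area(a, a)


class TestInterfaceResidues:
    def test_engineered_contact_found_exactly(self):
        a = _atoms([
            ("A", 10, "TYR", "OH", "O", (0, 0, 0)),
            ("A", 11, "ALA", "CA", "C", (0, 0, 20)),
        ])
        b = _atoms([
            ("B", 55, "ASN", "ND2", "N", (3.5, 0, 0)),
            ("B", 56, "GLY", "CA", "C", (30, 0, 0)),
        ])
        contacts = interface_residues(a, b, cutoff=4.5)
        assert len(contacts) == 1
        c = contacts[0]
        assert (c.res_id_a, c.res_id_b) == (10, 55)
        assert c.min_distance == pytest.approx(3.5)
        assert not c.salt_bridge

    def test_salt_bridge_annotated(self):
        arg = _atoms([("A", 404, "ARG", "NH1", "N", (0, 0, 0))])
        asp = _atoms([("B", 578, "ASP", "OD1", "O", (3.0, 0, 0))])
        contacts = interface_residues(arg, asp)
        assert contacts[0].salt_bridge
        # beyond the 4.0 A salt-bridge cutoff the pair is contact-only
        asp_far = _atoms([("B", 578, "ASP", "OD1", "O", (4.3, 0, 0))])
        contacts = interface_residues(arg, asp_far, cutoff=4.5)
        assert len(contacts) == 1 and not contacts[0].salt_bridge

    def test_sorted_by_distance(self):
        a = _atoms([
            ("A", 1, "ALA", "CA", "C", (0, 0, 0)),
            ("A", 2, "ALA", "CA", "C", (0, 8, 0)),
        ])
        b = _atoms([
            ("B", 1, "ALA", "CA", "C", (4.0, 0, 0)),
            ("B", 2, "ALA", "CA", "C", (2.0, 8, 0)),
        ])
        contacts = interface_residues(a, b)
        assert [c.min_distance for c in contacts] == sorted(
            c.min_distance for c in contacts
        )

    def test_empty_for_far_protomers(self):
        a = single_atom_model("C", (0, 0, 0))
        b = single_atom_model("C", (50, 0, 0), chain="B")
        assert interface_residues(a, b) == []
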