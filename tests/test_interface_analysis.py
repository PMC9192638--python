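"""SASA quadrature, context-limited buried surface area, and contacts."""

import numpy as np
import pytest

from ribomotion.interface_analysis import (
    Contact,
    ContactConfigError,
    RadiusTableError,
    SasaParams,
    buried_surface_area,
    fibonacci_sphere,
    find_contacts,
    sasa,
)
from ribomotion.structure_model import AtomRecord, SelectionExpr, SelectionError, StructureModel
from ribomotion.rigid_geometry import rotation_about_axis


def atom(x, y, z, element="C", name=None, chain="A", resnum=1, resname="ALA"):
    return AtomRecord(chain, resnum, "", resname, name or element, element,
                      (float(x), float(y), float(z)))


def two_sphere_accessible_total(r1, r2, d):
    """Analytic accessible area of two intersecting spheres (radii already expanded)."""
    if d >= r1 + r2:
        return 4 * np.pi * (r1 ** 2 + r2 ** 2)
    total = 0.0
    for ra, rb in ((r1, r2), (r2, r1)):
        x = (d * d + ra * ra - rb * rb) / (2 * d)  # center-a to intersection plane
        cap_h = ra - x
        total += 4 * np.pi * ra ** 2 - 2 * np.pi * ra * cap_h
    return total


class TestSasa:
    def test_single_atom_matches_analytic_sphere(self):
        params = SasaParams(radii={"X": 1.9}, probe_radius=1.4)
        areas, total = sasa([atom(0, 0, 0, element="X")], params)
        analytic = 4 * np.pi * 3.3 ** 2
        assert total == pytest.approx(analytic, rel=0.01)
        assert areas[0] == total

    def test_disjoint_atoms_additive(self):
        atoms = [atom(0, 0, 0), atom(100, 0, 0, resnum=2)]
        _, total = sasa(atoms)
        _, single = sasa([atoms[0]])
        assert total == pytest.approx(2 * single, rel=1e-9)

    @pytest.mark.parametrize("d", [1.0, 2.5, 4.0, 5.5])
    def test_two_overlapping_spheres_match_analytic_caps(self, d):
        params = SasaParams(points_per_atom=2000)
        atoms = [atom(0, 0, 0), atom(d, 0, 0, resnum=2)]
        _, total = sasa(atoms, params)
        expanded = 1.70 + 1.4
        analytic = two_sphere_accessible_total(expanded, expanded, d)
        assert total == pytest.approx(analytic, rel=0.01)

    def test_invariant_under_rigid_motion(self, rng):
        atoms = [atom(*p, resnum=i + 1) for i, p in enumerate(rng.random((20, 3)) * 10)]
        t = rotation_about_axis(53.0, [1, 2, 0], point=[4, 4, 4], extra_translation=[7, -2, 1])
        moved = [AtomRecord(a.chain_id, a.residue_number, "", a.residue_name, a.atom_name,
                            a.element, tuple(t.apply(a.xyz[None])[0])) for a in atoms]
        _, total0 = sasa(atoms)
        _, total1 = sasa(moved)
        # the quadrature lattice is fixed in the lab frame, so invariance
        # holds to the documented ~1% quadrature tolerance, not exactly
        assert total1 == pytest.approx(total0, rel=0.01)

    def test_context_atoms_only_occlude(self):
        target = [atom(0, 0, 0)]
        context = [atom(3.0, 0, 0, resnum=2)]
        _, alone = sasa(target)
        _, occluded = sasa(target, context_atoms=context)
        assert occluded < alone
        # context atom's own area is not included
        assert occluded < 4 * np.pi * (1.70 + 1.4) ** 2

    def test_adding_context_never_increases_area(self, rng):
        target = [atom(*p, resnum=i + 1) for i, p in enumerate(rng.random((10, 3)) * 8)]
        totals = []
        context = []
        for i, p in enumerate(rng.random((5, 3)) * 8):
            _, t = sasa(target, context_atoms=context)
            totals.append(t)
            context.append(atom(*p, chain="B", resnum=i + 1))
        _, t = sasa(target, context_atoms=context)
        totals.append(t)
        assert all(b <= a + 1e-9 for a, b in zip(totals, totals[1:]))

    def test_quadrature_convergence_on_doubling(self, rng):
        atoms = [atom(*p, resnum=i + 1) for i, p in enumerate(rng.random((15, 3)) * 9)]
        _, t1 = sasa(atoms, SasaParams(points_per_atom=960))
        _, t2 = sasa(atoms, SasaParams(points_per_atom=1920))
        assert abs(t1 - t2) / t2 < 0.01

    def test_matches_biotite_oracle(self, rng):
        """Independent cross-check against biotite's Shrake-Rupley."""
        import biotite.structure as struc
        coords = rng.random((25, 3)) * 12
        atoms = [atom(*p, resnum=i + 1) for i, p in enumerate(coords)]
        arr = struc.AtomArray(len(atoms))
        arr.coord = coords.astype(np.float32)
        arr.chain_id[:] = "A"
        arr.res_id[:] = np.arange(1, len(atoms) + 1)
        arr.res_name[:] = "ALA"
        arr.atom_name[:] = "C"
        arr.element[:] = "C"
        radii = np.full(len(atoms), 1.70)
        oracle = struc.sasa(arr, probe_radius=1.4, point_number=1500, vdw_radii=radii)
        _, ours = sasa(atoms, SasaParams(points_per_atom=1500))
        assert ours == pytest.approx(float(oracle.sum()), rel=0.01)

    def test_unknown_element_lists_offender(self):
        with pytest.raises(RadiusTableError, match="XX"):
            sasa([atom(0, 0, 0, element="XX")])

    def test_hydrogens_excluded_unless_flagged(self):
        heavy = [atom(0, 0, 0)]
        with_h = heavy + [atom(1.0, 0, 0, element="H", resnum=1, name="H1")]
        _, t_default = sasa(with_h)
        _, t_heavy = sasa(heavy)
        assert t_default == pytest.approx(t_heavy)
        _, t_h = sasa(with_h, SasaParams(include_hydrogens=True))
        assert t_h != pytest.approx(t_heavy)


class TestBuriedSurfaceArea:
    def _complex(self, gap=100.0):
        comp = [atom(x * 4.0, 0, 0, chain="F", resnum=i + 1)
                for i, x in enumerate(range(5))]
        other = [atom(x * 4.0, gap, 0, chain="L", resnum=i + 1)
                 for i, x in enumerate(range(5))]
        return StructureModel("complex", comp + other)

    def test_no_context_within_radius_gives_zero(self):
        model = self._complex(gap=100.0)
        res = buried_surface_area(model, SelectionExpr.parse("chain:F"), context_radius=30.0)
        assert res.n_context_atoms == 0
        assert res.buried == pytest.approx(0.0, abs=1e-9)

    def test_occluding_slab_matches_two_run_difference(self):
        model = self._complex(gap=4.5)
        comp_expr = SelectionExpr.parse("chain:F")
        res = buried_surface_area(model, comp_expr, context_radius=30.0)
        # brute-force oracle: two explicit SASA runs
        comp = [a for a in model.atoms if a.chain_id == "F"]
        other = [a for a in model.atoms if a.chain_id == "L"]
        _, alone = sasa(comp)
        _, together = sasa(comp, context_atoms=other)
        assert res.buried == pytest.approx(alone - together, abs=1e-9)
        assert res.buried > 0
        assert res.buried <= res.sasa_alone

    def test_infinite_radius_equals_all_context(self):
        model = self._complex(gap=8.0)
        expr = SelectionExpr.parse("chain:F")
        r_inf = buried_surface_area(model, expr, context_radius=np.inf)
        r_big = buried_surface_area(model, expr, context_radius=1e6)
        assert r_inf.buried == pytest.approx(r_big.buried, abs=1e-9)

    def test_per_residue_breakdown_sums_to_total(self):
        model = self._complex(gap=4.5)
        res = buried_surface_area(model, SelectionExpr.parse("chain:F"))
        assert sum(res.per_residue_buried.values()) == pytest.approx(res.buried, abs=1e-6)

    def test_empty_component_raises(self):
        model = self._complex()
        with pytest.raises(SelectionError):
            buried_surface_area(model, SelectionExpr.parse("chain:Z"))


class TestFindContacts:
    def _model(self, atoms):
        return StructureModel("m", atoms)

    def test_far_atoms_no_contacts(self):
        m = self._model([atom(0, 0, 0, chain="A"), atom(10, 0, 0, chain="B")])
        out = find_contacts(m, SelectionExpr.parse("chain:A"), SelectionExpr.parse("chain:B"))
        assert out == []

    def test_n_o_pair_is_hbond_candidate(self):
        m = self._model([atom(0, 0, 0, element="N", chain="A"),
                         atom(2.9, 0, 0, element="O", chain="B")])
        out = find_contacts(m, SelectionExpr.parse("chain:A"), SelectionExpr.parse("chain:B"))
        assert len(out) == 1
        assert out[0].contact_class == "hbond-candidate"
        assert out[0].distance == pytest.approx(2.9)

    def test_carbon_pair_is_vdw(self):
        m = self._model([atom(0, 0, 0, chain="A"), atom(3.8, 0, 0, chain="B")])
        out = find_contacts(m, SelectionExpr.parse("chain:A"), SelectionExpr.parse("chain:B"))
        assert [c.contact_class for c in out] == ["vdw"]

    def test_stacked_rings_detected_and_match_all_pairs_scan(self):
        # idealized six-membered rings stacked 3.5 Å apart along z
        def ring(chain, resname, z, names):
            pts = []
            for i, nm in enumerate(names):
                th = 2 * np.pi * i / 6
                el = nm[0]
                pts.append(AtomRecord(chain, 1, "", resname, nm, el,
                                      (1.4 * np.cos(th), 1.4 * np.sin(th), z)))
            return pts

        names = ("N1", "C2", "N3", "C4", "C5", "C6")
        m = self._model(ring("A", "C", 0.0, names) + ring("B", "U", 3.5, names))
        out = find_contacts(m, SelectionExpr.parse("chain:A"), SelectionExpr.parse("chain:B"))
        stacks = [c for c in out if c.contact_class == "stacking-candidate"]
        assert len(stacks) == 1
        assert stacks[0].distance == pytest.approx(3.5, abs=1e-6)
        # brute-force all-pairs scan confirms the vdw contact list
        vdw = {(c.atom_a, c.atom_b) for c in out if c.contact_class != "stacking-candidate"}
        brute = set()
        for a in m.atoms:
            for b in m.atoms:
                if a.chain_id == "A" and b.chain_id == "B":
                    if np.linalg.norm(a.xyz - b.xyz) <= 4.0:
                        brute.add((a.key, b.key))
        assert vdw == brute

    def test_overlapping_selections_rejected(self):
        m = self._model([atom(0, 0, 0, chain="A"), atom(3, 0, 0, chain="B")])
        with pytest.raises(ContactConfigError):
            find_contacts(m, SelectionExpr.parse("chain:A"), SelectionExpr.all())


class TestFibonacciSphere:
    def test_unit_norm_and_centroid_balance(self):
        pts = fibonacci_sphere(960)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
        assert np.abs(pts.mean(axis=0)).max() < 5e-3
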