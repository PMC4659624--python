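"""Surface areas, hydrogen bonds, cation-π and interface waters."""

import numpy as np
import pytest

from helixswitch.interface_analysis import (
    CationPiCriteria,
    HBondCriteria,
    VDW_RADII,
    buried_interface_area,
    count_interface_waters,
    detect_cation_pi,
    detect_hbonds,
    interface_report,
    sasa,
)
from helixswitch.model_io import Atom, StructureModel

from conftest import random_rigid_transform


def carbon(serial, xyz, res_seq=1, chain="A", name="C1"):
    return Atom(serial, name, "C", "LIG", res_seq, chain, np.asarray(xyz, float), het=True)


def one_atom_model(element="C", xyz=(0.0, 0.0, 0.0), chain="A", res_seq=1):
    return StructureModel(
        1,
        [Atom(1, element, element, "LIG", res_seq, chain, np.asarray(xyz, float), het=True)],
    )


def sphere_area(r):
    return 4.0 * np.pi * r**2


def two_sphere_exposed_areas(r1, r2, d):
    """Analytic exposed areas of two overlapping spheres (cap formula)."""
    if d >= r1 + r2:
        return sphere_area(r1), sphere_area(r2)
    h1 = r1 - (d**2 + r1**2 - r2**2) / (2 * d)
    h2 = r2 - (d**2 + r2**2 - r1**2) / (2 * d)
    return sphere_area(r1) - 2 * np.pi * r1 * h1, sphere_area(r2) - 2 * np.pi * r2 * h2


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        areas = sasa(one_atom_model("C"))
        expected = sphere_area(VDW_RADII["C"] + 1.4)
        assert areas.sum() == pytest.approx(expected, rel=0.01)

    def test_distant_atoms_additive(self):
        model = StructureModel(1, [carbon(1, (0, 0, 0)), carbon(2, (100, 0, 0), name="C2")])
        areas = sasa(model)
        expected = sphere_area(VDW_RADII["C"] + 1.4)
        assert areas[0] == pytest.approx(expected, rel=0.01)
        assert areas[1] == pytest.approx(expected, rel=0.01)

    @pytest.mark.parametrize("d", [1.0, 2.5, 4.0, 5.5])
    def test_two_sphere_overlap_matches_cap_formula(self, d):
        model = StructureModel(1, [carbon(1, (0, 0, 0)), carbon(2, (d, 0, 0), name="C2")])
        areas = sasa(model, n_points=960)
        r = VDW_RADII["C"] + 1.4
        exp1, exp2 = two_sphere_exposed_areas(r, r, d)
        assert areas[0] == pytest.approx(exp1, rel=0.02)
        assert areas[1] == pytest.approx(exp2, rel=0.02)

    def test_rigid_motion_invariance(self, ideal_helix, rng):
        # orientation sensitivity of the quadrature shrinks with the point
        # count: ~0.5% at the 960-point default, <0.1% at 10^4 points
        base_default = sasa(ideal_helix).sum()
        base_fine = sasa(ideal_helix, n_points=10_000).sum()
        for _ in range(20):
            t = random_rigid_transform(rng)
            moved = ideal_helix.with_coords(t.apply(ideal_helix.coords))
            assert sasa(moved).sum() == pytest.approx(base_default, rel=1e-2)
            assert sasa(moved, n_points=10_000).sum() == pytest.approx(base_fine, rel=1e-3)

    def test_quadrature_converges(self, ideal_helix):
        truth = sasa(ideal_helix, n_points=7680).sum()
        errors = [abs(sasa(ideal_helix, n_points=n).sum() - truth) for n in (240, 960, 3840)]
        assert errors[0] >= errors[1] >= errors[2]

    def test_unknown_element_rejected(self):
        with pytest.raises(KeyError, match="radius"):
            sasa(one_atom_model("XX"))

    def test_too_few_points_rejected(self, ideal_helix):
        with pytest.raises(ValueError, match="at least 100"):
            sasa(ideal_helix, n_points=10)


class TestBuriedArea:
    def test_distant_partners_zero(self):
        a = one_atom_model("C", (0, 0, 0))
        b = one_atom_model("C", (100, 0, 0), chain="B")
        assert buried_interface_area(a, b) == pytest.approx(0.0, abs=0.5)

    def test_symmetry_exact(self, scene_core):
        rec, pep = scene_core.receptor, scene_core.peptide_empty
        assert buried_interface_area(rec, pep) == buried_interface_area(pep, rec)

    def test_apolar_bounded_by_total(self, scene_core):
        rec, pep = scene_core.receptor, scene_core.peptide_empty
        total = buried_interface_area(rec, pep)
        apolar = buried_interface_area(rec, pep, apolar_only=True)
        assert 0.0 <= apolar <= total + 1e-6

    def test_toy_contact_matches_cap_overlap_oracle(self):
        # single C against single C at 2.0 Å: burial from the cap formula
        d = 2.0
        a = one_atom_model("C", (0, 0, 0))
        b = one_atom_model("C", (d, 0, 0), chain="B")
        r = VDW_RADII["C"] + 1.4
        exp1, exp2 = two_sphere_exposed_areas(r, r, d)
        buried_oracle = (sphere_area(r) - exp1 + sphere_area(r) - exp2) / 2.0
        assert buried_interface_area(a, b) == pytest.approx(buried_oracle, rel=0.02)

    def test_shared_atoms_rejected(self, scene_core):
        with pytest.raises(ValueError, match="share"):
            buried_interface_area(scene_core.receptor, scene_core.receptor)


def _nh_donor(serial, xyz, res_seq=1, chain="A"):
    """A backbone amide N with its CA antecedent behind it (along -x)."""
    xyz = np.asarray(xyz, float)
    return [
        Atom(serial, "N", "N", "ALA", res_seq, chain, xyz),
        Atom(serial + 1, "CA", "C", "ALA", res_seq, chain, xyz + [-1.46, 0.0, 0.0]),
    ]


def _carbonyl(serial, o_xyz, res_seq=1, chain="B", direction=(1.0, 0.0, 0.0)):
    o_xyz = np.asarray(o_xyz, float)
    d = np.asarray(direction, float)
    return [
        Atom(serial, "C", "C", "ALA", res_seq, chain, o_xyz + 1.23 * d),
        Atom(serial + 1, "O", "O", "ALA", res_seq, chain, o_xyz),
    ]


class TestHBonds:
    def test_constructed_positive(self):
        a = StructureModel(1, _nh_donor(1, (0, 0, 0)))
        b = StructureModel(1, _carbonyl(10, (2.9, 0, 0)))
        bonds = detect_hbonds(a, b)
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.9)
        assert bonds[0].donor.name == "N"
        assert bonds[0].acceptor.name == "O"

    def test_beyond_cutoff_none(self):
        a = StructureModel(1, _nh_donor(1, (0, 0, 0)))
        b = StructureModel(1, _carbonyl(10, (4.2, 0, 0)))
        assert detect_hbonds(a, b) == []

    def test_antecedent_angle_proxy_gates(self):
        # acceptor BEHIND the donor (on the CA side): antecedent-D...A < 90 deg
        a = StructureModel(1, _nh_donor(1, (0, 0, 0)))
        b = StructureModel(1, _carbonyl(10, (-2.9, 0, 0), direction=(-1, 0, 0)))
        assert detect_hbonds(a, b) == []

    def test_explicit_hydrogen_angle(self):
        donor = [
            Atom(1, "N", "N", "ALA", 1, "A", np.zeros(3)),
            Atom(2, "CA", "C", "ALA", 1, "A", np.array([-1.46, 0.0, 0.0])),
            Atom(3, "H", "H", "ALA", 1, "A", np.array([1.0, 0.0, 0.0])),
        ]
        a = StructureModel(1, donor)
        good = StructureModel(1, _carbonyl(10, (2.9, 0.0, 0.0)))
        assert len(detect_hbonds(a, good)) == 1
        # acceptor at right angle through the H: D-H...A ~ 107 deg < 120
        bad = StructureModel(1, _carbonyl(10, (1.0, 2.8, 0.0)))
        assert detect_hbonds(a, bad) == []

    def test_matches_bruteforce_scan(self, scene_core):
        a, b = scene_core.receptor, scene_core.peptide_intermediate
        crit = HBondCriteria()
        got = {(h.donor.key, h.acceptor.key) for h in detect_hbonds(a, b)}
        from helixswitch.interface_analysis import _donor_antecedent, _is_acceptor, _is_donor

        expected = set()
        for dm, am in ((a, b), (b, a)):
            lookup = {at.key: at for at in dm.atoms}
            for d in dm.atoms:
                if not _is_donor(d):
                    continue
                for acc in am.atoms:
                    if not _is_acceptor(acc):
                        continue
                    dist = np.linalg.norm(d.xyz - acc.xyz)
                    if dist > crit.d_max:
                        continue
                    ante_name = _donor_antecedent(d)
                    ante = lookup.get((d.chain_id, d.res_seq, ante_name))
                    if ante is not None:
                        v1 = ante.xyz - d.xyz
                        v2 = acc.xyz - d.xyz
                        cos = v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2)
                        if np.degrees(np.arccos(np.clip(cos, -1, 1))) < crit.proxy_angle_min:
                            continue
                    expected.add((d.key, acc.key))
        assert got == expected


def _tyr_ring(chain="A", res_seq=1, centroid=(0.0, 0.0, 0.0), normal=(0.0, 0.0, 1.0)):
    centroid = np.asarray(centroid, float)
    normal = np.asarray(normal, float)
    normal = normal / np.linalg.norm(normal)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(ref @ normal) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
    atoms = []
    for k, name in enumerate(names):
        ang = np.radians(60.0 * k)
        xyz = centroid + 1.39 * (np.cos(ang) * e1 + np.sin(ang) * e2)
        atoms.append(Atom(k + 1, name, "C", "TYR", res_seq, chain, xyz))
    return StructureModel(1, atoms)


def _arg_cation(xyz, chain="B", res_seq=2):
    return StructureModel(
        1, [Atom(50, "CZ", "C", "ARG", res_seq, chain, np.asarray(xyz, float))]
    )


class TestCationPi:
    def test_face_on_detected(self):
        ring = _tyr_ring()
        cation = _arg_cation((0.0, 0.0, 4.0))
        hits = detect_cation_pi(ring, cation)
        assert len(hits) == 1
        assert hits[0].distance == pytest.approx(4.0)
        assert hits[0].angle == pytest.approx(0.0, abs=1e-6)

    def test_in_plane_rejected_by_angle_gate(self):
        ring = _tyr_ring()
        cation = _arg_cation((4.0, 0.0, 0.0))
        assert detect_cation_pi(ring, cation) == []

    def test_beyond_distance_rejected(self):
        ring = _tyr_ring()
        cation = _arg_cation((0.0, 0.0, 6.5))
        assert detect_cation_pi(ring, cation) == []

    def test_incomplete_ring_skipped_with_warning(self):
        ring = _tyr_ring()
        partial = StructureModel(1, list(ring.atoms[:4]))
        cation = _arg_cation((0.0, 0.0, 4.0))
        with pytest.warns(UserWarning, match="misses ring atoms"):
            assert detect_cation_pi(partial, cation) == []

    def test_matches_bruteforce_scan(self, scene_core):
        from helixswitch.interface_analysis import _cations, _rings

        a, b = scene_core.receptor, scene_core.peptide_empty
        crit = CationPiCriteria()
        got = {(h.cation_residue, h.ring_residue) for h in detect_cation_pi(a, b)}
        expected = set()
        for rm, cm in ((a, b), (b, a)):
            for ring_id, centroid, normal in _rings(rm):
                for cat_id, pos in _cations(cm):
                    vec = pos - centroid
                    dist = np.linalg.norm(vec)
                    if not 1e-9 < dist <= crit.d_max:
                        continue
                    ang = np.degrees(np.arccos(np.clip(abs(normal @ vec) / dist, -1, 1)))
                    if ang <= crit.angle_max:
                        expected.add((cat_id, ring_id))
        assert got == expected
        assert got  # the planted Tyr391-R131 pair is present


def _scene_with_waters(water_positions):
    atoms = _nh_donor(1, (0, 0, 0), chain="A") + _carbonyl(10, (3.0, 0, 0), chain="B")
    for i, pos in enumerate(water_positions):
        atoms.append(Atom(100 + i, "O", "O", "HOH", 500 + i, "W", np.asarray(pos, float), het=True))
    return StructureModel(1, atoms)


class TestInterfaceWaters:
    def test_bridging_water_counted(self):
        scene = _scene_with_waters([(1.5, 1.0, 0.0)])
        n, ids = count_interface_waters(scene, "chain A", "chain B")
        assert n == 1 and ids == [("W", 500)]

    def test_one_sided_water_not_counted(self):
        scene = _scene_with_waters([(-3.0, 0.5, 0.0)])  # 3 Å from A, ~7.5 Å from B
        n, _ = count_interface_waters(scene, "chain A", "chain B")
        assert n == 0

    def test_monotone_in_cutoff(self, rng):
        positions = rng.uniform(-6, 9, size=(30, 3))
        scene = _scene_with_waters(positions)
        counts = [
            count_interface_waters(scene, "chain A", "chain B", cutoff)[0]
            for cutoff in (2.0, 3.0, 3.5, 5.0, 8.0)
        ]
        assert counts == sorted(counts)

    def test_bruteforce_recount(self, rng):
        positions = rng.uniform(-6, 9, size=(20, 3))
        scene = _scene_with_waters(positions)
        n, ids = count_interface_waters(scene, "chain A", "chain B", 3.5)
        a_coords = np.array([a.xyz for a in scene.atoms if a.chain_id == "A"])
        b_coords = np.array([a.xyz for a in scene.atoms if a.chain_id == "B"])
        expected = []
        for a in scene.atoms:
            if a.res_name != "HOH":
                continue
            da = np.min(np.linalg.norm(a_coords - a.xyz, axis=1))
            db = np.min(np.linalg.norm(b_coords - a.xyz, axis=1))
            if da <= 3.5 and db <= 3.5:
                expected.append((a.chain_id, a.res_seq))
        assert ids == expected and n == len(expected)

    def test_no_waters_notice(self, scene_core):
        with pytest.warns(UserWarning, match="no waters"):
            n, ids = count_interface_waters(
                scene_core.peptide_empty, "resid 382-386", "resid 387-392"
            )
        assert (n, ids) == (0, [])


class TestInterfaceReport:
    def test_report_fields_consistent(self, scene_core):
        rep = interface_report(scene_core.receptor, scene_core.peptide_empty)
        assert rep.buried_area >= rep.apolar_buried_area >= 0.0
        assert len(rep.hbonds) >= 1
        assert len(rep.cation_pi) == 1
        d = rep.to_dict()
        assert d["n_hbonds"] == len(rep.hbonds)
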