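"""Structure I/O, selection and generic-numbering behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from helixswitch.model_io import (
    Atom,
    GenericNumberMap,
    PDBParseError,
    SelectionError,
    StructureModel,
    Trajectory,
    assign_generic_numbers,
    read_structure,
    select,
    write_structure,
)
from helixswitch.synthetic import HelixSpec, build_ideal_helix


def _water(serial, res_seq, xyz):
    return Atom(serial, "O", "O", "HOH", res_seq, "W", np.asarray(xyz, float), het=True)


@st.composite
def random_models(draw):
    n = draw(st.integers(min_value=1, max_value=15))
    atoms = []
    names = ["N", "CA", "C", "O"]
    for i in range(n):
        atoms.append(
            Atom(
                serial=i + 1,
                name=names[i % 4],
                element=names[i % 4][0],
                res_name="ALA",
                res_seq=1 + i // 4,
                chain_id=draw(st.sampled_from("AB")) if i % 4 == 0 else atoms[-1].chain_id,
                xyz=np.array(
                    [
                        draw(st.floats(-999.0, 999.0, allow_nan=False)),
                        draw(st.floats(-999.0, 999.0, allow_nan=False)),
                        draw(st.floats(-999.0, 999.0, allow_nan=False)),
                    ]
                ),
                occupancy=draw(st.floats(0.0, 1.0)),
                b_factor=draw(st.floats(0.0, 99.0)),
            )
        )
    # make keys unique: chain may repeat residue/name combos across chains only
    seen, unique = set(), []
    for a in atoms:
        if a.key not in seen:
            seen.add(a.key)
            unique.append(a)
    return StructureModel(1, unique)


class TestReadWrite:
    def test_single_model_roundtrip(self, ideal_helix, tmp_path):
        path = tmp_path / "helix.pdb"
        write_structure(ideal_helix, path)
        back = read_structure(path)
        assert isinstance(back, StructureModel)
        assert len(back) == len(ideal_helix)
        np.testing.assert_allclose(back.coords, ideal_helix.coords, atol=5e-4)
        assert [a.key for a in back.atoms] == [a.key for a in ideal_helix.atoms]

    def test_second_write_is_bit_stable(self, ideal_helix, tmp_path):
        p1, p2 = tmp_path / "a.pdb", tmp_path / "b.pdb"
        write_structure(ideal_helix, p1)
        write_structure(read_structure(p1), p2)
        assert p1.read_text() == p2.read_text()

    def test_multi_model(self, ideal_helix, tmp_path):
        models = []
        for k in range(3):
            m = ideal_helix.with_coords(ideal_helix.coords + k)
            m.model_id = k + 1
            models.append(m)
        path = tmp_path / "traj.pdb"
        write_structure(models, path)
        back = read_structure(path)
        assert isinstance(back, list) and len(back) == 3
        assert [m.model_id for m in back] == [1, 2, 3]
        back_one = read_structure(path, model_index=2)
        np.testing.assert_allclose(back_one.coords, models[1].coords, atol=5e-4)

    def test_waters_and_hetatm_retained(self, tmp_path):
        model = StructureModel(
            1,
            [
                Atom(1, "CA", "C", "ALA", 1, "A", np.zeros(3)),
                Atom(2, "C", "C", "ALA", 1, "A", np.array([1.5, 0, 0])),
                Atom(3, "N", "N", "ALA", 1, "A", np.array([0, 1.5, 0])),
                _water(4, 101, [5.0, 5.0, 5.0]),
            ],
        )
        path = tmp_path / "wet.pdb"
        write_structure(model, path)
        back = read_structure(path)
        assert back.atoms[-1].res_name == "HOH"
        assert back.atoms[-1].het
        assert "HETATM" in path.read_text()

    def test_malformed_coordinate_names_line(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text(
            "ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00 10.00           N\n"
            "ATOM      2  CA  ALA A   1       xxx.00   2.000   3.000  1.00 10.00           C\n"
        )
        with pytest.raises(PDBParseError, match="line 2"):
            read_structure(path)

    def test_truncated_record_rejected(self, tmp_path):
        path = tmp_path / "short.pdb"
        path.write_text("ATOM      1  N   ALA A   1       1.000\n")
        with pytest.raises(PDBParseError, match="line 1"):
            read_structure(path)

    def test_empty_model_block_rejected(self, tmp_path):
        path = tmp_path / "empty_model.pdb"
        path.write_text("MODEL        1\nENDMDL\nEND\n")
        with pytest.raises(PDBParseError, match="empty MODEL"):
            read_structure(path)

    def test_no_atoms_rejected(self, tmp_path):
        path = tmp_path / "nothing.pdb"
        path.write_text("REMARK nothing here\nEND\n")
        with pytest.raises(PDBParseError):
            read_structure(path)

    def test_out_of_range_coordinate_raises(self, tmp_path):
        atom = Atom(1, "CA", "C", "ALA", 1, "A", np.array([10000.5, 0.0, 0.0]))
        with pytest.raises(ValueError, match="fixed-width"):
            write_structure(StructureModel(1, [atom]), tmp_path / "big.pdb")

    def test_empty_atom_list_raises(self, tmp_path):
        empty = select(
            StructureModel(1, [Atom(1, "CA", "C", "ALA", 1, "A", np.zeros(3))]),
            "chain Z",
        )
        with pytest.raises(ValueError, match="no atoms"):
            write_structure(empty, tmp_path / "none.pdb")

    def test_atom_line_columns(self, tmp_path):
        atom = Atom(1, "CA", "C", "GLY", 7, "B", np.array([1.234, 2.345, 3.456]))
        path = tmp_path / "one.pdb"
        write_structure(StructureModel(1, [atom]), path)
        line = path.read_text().splitlines()[0]
        assert line[0:6] == "ATOM  "
        assert line[12:16] == " CA "
        assert line[17:20] == "GLY"
        assert line[21] == "B"
        assert line[30:38] == "   1.234"
        assert line[38:46] == "   2.345"
        assert line[46:54] == "   3.456"

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40 10.00           C\n"
            "ATOM      2  CA BALA A   1       9.000   0.000   0.000  0.60 10.00           C\n"
        )
        model = read_structure(path)
        assert len(model) == 1
        assert model.atoms[0].xyz[0] == pytest.approx(9.0)

    def test_altloc_tie_prefers_letter_order(self, tmp_path):
        path = tmp_path / "alt_tie.pdb"
        path.write_text(
            "ATOM      1  CA BALA A   1       9.000   0.000   0.000  0.50 10.00           C\n"
            "ATOM      2  CA AALA A   1       0.000   0.000   0.000  0.50 10.00           C\n"
        )
        model = read_structure(path)
        assert model.atoms[0].xyz[0] == pytest.approx(0.0)  # altloc A wins

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(model=random_models())
    def test_fuzzed_roundtrip_lossless_at_pdb_precision(self, model, tmp_path_factory):
        path = tmp_path_factory.mktemp("fuzz") / "m.pdb"
        write_structure(model, path)
        back = read_structure(path)
        np.testing.assert_allclose(back.coords, model.coords, atol=5e-4)
        assert [a.key for a in back.atoms] == [a.key for a in model.atoms]

    def test_cross_check_against_gemmi(self, ideal_helix, tmp_path):
        gemmi = pytest.importorskip("gemmi")
        path = tmp_path / "x.pdb"
        write_structure(ideal_helix, path)
        st_ = gemmi.read_pdb(str(path))
        ref = [
            (at.name, res.seqid.num, round(at.pos.x, 3), round(at.pos.y, 3), round(at.pos.z, 3))
            for ch in st_[0]
            for res in ch
            for at in res
        ]
        mine = [
            (a.name, a.res_seq, round(a.xyz[0], 3), round(a.xyz[1], 3), round(a.xyz[2], 3))
            for a in read_structure(path).atoms
        ]
        assert ref == mine


class TestSelect:
    def test_backbone_resid_chain(self):
        helix = build_ideal_helix(HelixSpec(first_res_seq=382, chain_id="A"))
        sub = select(helix, "backbone and chain A and resid 382-392")
        assert len(sub) == 44  # 4 backbone atoms x 11 residues

    def test_water_on_dry_structure_flagged(self, ideal_helix):
        with pytest.warns(UserWarning, match="matched no atoms"):
            sub = select(ideal_helix, "water")
        assert len(sub.atoms) == 0
        assert sub.meta["empty_selection"]

    def test_selection_is_pure(self, ideal_helix):
        before = ideal_helix.coords.copy()
        select(ideal_helix, "name CA")
        np.testing.assert_array_equal(ideal_helix.coords, before)

    def test_syntax_errors(self, ideal_helix):
        for expr in ("bogus", "resid x", "chain", "not"):
            with pytest.raises(SelectionError):
                select(ideal_helix, expr)

    @pytest.mark.parametrize(
        "expr",
        ["backbone", "name CA CB", "resid 3-7", "heavy", "protein", "not water", "chain P and resid 2-9"],
    )
    def test_equivalence_with_bruteforce_predicate(self, ideal_helix, expr):
        from helixswitch.model_io import AMINO_ACIDS, BACKBONE_NAMES, WATER_RESNAMES

        predicates = {
            "backbone": lambda a: a.name in BACKBONE_NAMES and a.res_name in AMINO_ACIDS,
            "name CA CB": lambda a: a.name in {"CA", "CB"},
            "resid 3-7": lambda a: 3 <= a.res_seq <= 7,
            "heavy": lambda a: a.element != "H",
            "protein": lambda a: a.res_name in AMINO_ACIDS,
            "not water": lambda a: a.res_name not in WATER_RESNAMES,
            "chain P and resid 2-9": lambda a: a.chain_id == "P" and 2 <= a.res_seq <= 9,
        }
        expected = [a.key for a in ideal_helix.atoms if predicates[expr](a)]
        got = [a.key for a in select(ideal_helix, expr).atoms]
        assert got == expected

    @pytest.mark.parametrize(
        "e1,e2",
        [("backbone", "resid 2-5"), ("chain P", "name CA"), ("heavy", "resid 1-3")],
    )
    def test_composition_equals_conjunction(self, ideal_helix, e1, e2):
        lhs = select(select(ideal_helix, e1), e2)
        rhs = select(ideal_helix, f"{e1} and {e2}")
        assert [a.key for a in lhs.atoms] == [a.key for a in rhs.atoms]


class TestTrajectory:
    def test_mismatched_composition_rejected(self, ideal_helix):
        other = StructureModel(2, list(ideal_helix.atoms[:-1]))
        with pytest.raises(ValueError, match="frame 1"):
            Trajectory([ideal_helix, other], [0.0, 1.0])

    def test_times_must_increase(self, ideal_helix):
        with pytest.raises(ValueError, match="strictly increasing"):
            Trajectory([ideal_helix, ideal_helix], [1.0, 1.0])


class TestGenericNumbers:
    ANCHORS = pd.DataFrame(
        [{"chain": "A", "res_seq": 131, "bw_label": "3.50",
          "segment_start": 127, "segment_end": 139}]
    )

    def test_propagation_matches_conserved_positions(self):
        gmap = assign_generic_numbers(None, self.ANCHORS)
        assert gmap.lookup("A", 131) == "3.50"
        assert gmap.lookup("A", 135) == "3.54"
        assert gmap.lookup("A", 138) == "3.57"
        assert gmap.lookup("A", 127) == "3.46"

    def test_identity_anchor(self):
        anchors = pd.DataFrame(
            [{"chain": "A", "res_seq": 135, "bw_label": "3.50",
              "segment_start": 135, "segment_end": 135}]
        )
        assert assign_generic_numbers(None, anchors).lookup("A", 135) == "3.50"

    def test_lookup_outside_segments_is_explicit(self):
        gmap = assign_generic_numbers(None, self.ANCHORS)
        with pytest.raises(KeyError, match="outside"):
            gmap.lookup("A", 200)
        assert gmap.get("A", 200) is None

    def test_disagreeing_anchors_rejected(self):
        anchors = pd.DataFrame(
            [
                {"chain": "A", "res_seq": 131, "bw_label": "3.50",
                 "segment_start": 127, "segment_end": 139},
                {"chain": "A", "res_seq": 132, "bw_label": "3.52",
                 "segment_start": 127, "segment_end": 139},
            ]
        )
        with pytest.raises(ValueError, match="disagree"):
            assign_generic_numbers(None, anchors)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        anchor_res=st.integers(-50, 400),
        pos=st.integers(30, 60),
        tm=st.integers(1, 7),
        lo_off=st.integers(0, 10),
        hi_off=st.integers(0, 10),
        query_off=st.integers(-10, 10),
    )
    def test_fuzz_vs_direct_arithmetic(self, anchor_res, pos, tm, lo_off, hi_off, query_off):
        start, end = anchor_res - lo_off, anchor_res + hi_off
        anchors = pd.DataFrame(
            [{"chain": "X", "res_seq": anchor_res, "bw_label": f"{tm}.{pos}",
              "segment_start": start, "segment_end": end}]
        )
        gmap = assign_generic_numbers(None, anchors)
        query = anchor_res + query_off
        if start <= query <= end:
            assert gmap.lookup("X", query) == f"{tm}.{pos + query_off}"
        else:
            with pytest.raises(KeyError):
                gmap.lookup("X", query)

    def test_position_difference_equals_residue_difference(self):
        gmap = assign_generic_numbers(None, self.ANCHORS)
        positions = {r: int(gmap.lookup("A", r).split(".")[1]) for r in range(127, 140)}
        for r1 in positions:
            for r2 in positions:
                assert positions[r1] - positions[r2] == r1 - r2
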