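"""Structure/trajectory I/O, segment registry, selections, tabular formats."""

import numpy as np
import pytest

from ncsmd import (
    NCS1_SEGMENTS,
    SegmentTable,
    read_params,
    read_restraints,
    read_structure,
    read_trajectory,
    select,
    write_params,
    write_restraints,
    write_structure,
)
from ncsmd.structures import NBParam, NonbondedParams

from conftest import make_multimodel_lines, pdb_atom_line


class TestReadStructure:
    def test_minimal_read(self, tiny_pdb):
        s = read_structure(tiny_pdb, model_index=1)
        assert s.n_atoms == 3
        assert list(s.names) == ["N", "CA", "C"]
        assert s.positions[1] == pytest.approx([1.458, 0.0, 0.0])
        assert s.masses[0] == pytest.approx(14.007, abs=0.01)

    def test_missing_model_and_chain_are_named(self, tiny_pdb):
        with pytest.raises(ValueError, match="1 model"):
            read_structure(tiny_pdb, model_index=2)
        with pytest.raises(ValueError, match="chains \\['A'\\]"):
            read_structure(tiny_pdb, chain="B")

    def test_hetatm_excluded_by_default(self, write_pdb):
        path = write_pdb(
            [
                pdb_atom_line(1, "CA", "ALA", "A", 1, 0, 0, 0),
                pdb_atom_line(2, "CA", "GLY", "A", 2, 3, 0, 0),
                pdb_atom_line(3, "CA", "CA", "A", 201, 9, 9, 9, record="HETATM", element="CA"),
                pdb_atom_line(4, "O", "HOH", "A", 301, 8, 8, 8, record="HETATM", element="O"),
            ]
        )
        s = read_structure(path)
        assert list(s.residue_ids) == [1, 2]
        kept = read_structure(path, keep_het=True)
        assert 201 in kept.residue_ids and 301 in kept.residue_ids

    def test_altloc_keeps_highest_occupancy_tie_goes_to_A(self, write_pdb):
        path = write_pdb(
            [
                pdb_atom_line(1, "CA", "ALA", "A", 1, 0, 0, 0, altloc="B", occ=0.7),
                pdb_atom_line(2, "CA", "ALA", "A", 1, 1, 0, 0, altloc="A", occ=0.3),
                pdb_atom_line(3, "N", "ALA", "A", 1, 2, 0, 0, altloc="B", occ=0.5, element="N"),
                pdb_atom_line(4, "N", "ALA", "A", 1, 3, 0, 0, altloc="A", occ=0.5, element="N"),
                pdb_atom_line(5, "C", "ALA", "A", 1, 4, 1, 0),
            ]
        )
        s = read_structure(path)
        assert s.n_atoms == 3
        ca = s.positions[list(s.names).index("CA")]
        n = s.positions[list(s.names).index("N")]
        assert ca[0] == pytest.approx(0.0)  # occupancy 0.7 wins
        assert n[0] == pytest.approx(3.0)  # occupancy tie -> altloc A

    def test_insertion_code_rejected(self, write_pdb):
        path = write_pdb(
            [
                pdb_atom_line(1, "CA", "ALA", "A", 1, 0, 0, 0, icode="A"),
                pdb_atom_line(2, "CA", "GLY", "A", 2, 3, 0, 0),
            ]
        )
        with pytest.raises(ValueError, match="insertion code"):
            read_structure(path)

    def test_multimodel_models_differ_in_coordinates_only(self, write_pdb):
        path = write_pdb(
            make_multimodel_lines([[(0, 0, 0), (1.4, 0, 0)], [(0.5, 0, 0), (1.9, 0, 0)]])
        )
        s1 = read_structure(path, model_index=1)
        s2 = read_structure(path, model_index=2)
        assert s1.atom_keys() == s2.atom_keys()
        assert not np.allclose(s1.positions, s2.positions)

    def test_roundtrip_preserves_identity_and_coordinates(self, tmp_path, rng):
        from ncsmd import build_helix

        s = build_helix(["ALA", "GLY", "LEU", "LYS", "GLU"])
        out = tmp_path / "rt.pdb"
        write_structure(s, out)
        back = read_structure(out)
        assert back.atom_keys() == s.atom_keys()
        assert list(back.residue_names) == list(s.residue_names)
        assert np.allclose(back.positions, s.positions, atol=1e-3)


class TestReadTrajectory:
    def test_identical_models_give_identical_frames(self, write_pdb):
        coords = [[(0, 0, 0), (1.4, 0, 0)]] * 5
        traj = read_trajectory(write_pdb(make_multimodel_lines(coords)), dt=50.0)
        assert traj.n_frames == 5
        assert np.allclose(traj.frames, traj.frames[0])

    def test_concatenation_order_across_files(self, write_pdb):
        f1 = write_pdb(make_multimodel_lines([[(float(i), 0, 0), (float(i) + 1.4, 0, 0)] for i in range(3)]), "a.pdb")
        f2 = write_pdb(make_multimodel_lines([[(float(i), 5, 0), (float(i) + 1.4, 5, 0)] for i in range(3)]), "b.pdb")
        traj = read_trajectory([f1, f2], dt=10.0)
        assert traj.n_frames == 6
        assert [f[0][0] for f in traj.frames] == [0, 1, 2, 0, 1, 2]
        assert [f[0][1] for f in traj.frames] == [0, 0, 0, 5, 5, 5]

    def test_time_span(self, write_pdb):
        traj = read_trajectory(
            write_pdb(make_multimodel_lines([[(0, 0, 0), (1.4, 0, 0)]] * 4)), dt=50.0
        )
        assert traj.times[-1] == pytest.approx((4 - 1) * 50.0)

    def test_topology_mismatch_names_first_bad_atom(self, write_pdb):
        lines = make_multimodel_lines([[(0, 0, 0), (1.4, 0, 0)]])
        lines += [
            "MODEL        2",
            pdb_atom_line(1, "N", "GLY", "A", 1, 0, 0, 0, element="N"),
            pdb_atom_line(2, "CB", "GLY", "A", 1, 1.4, 0, 0),
            "ENDMDL",
        ]
        with pytest.raises(ValueError, match="CB"):
            read_trajectory(write_pdb(lines), dt=1.0)


class TestSegmentsAndSelect:
    def test_builtin_registry(self):
        expected = {
            "H1": (11, 18), "H2": (24, 34), "H3": (45, 54), "H4": (62, 72),
            "H5": (82, 93), "H6": (98, 108), "H7": (118, 132), "H8": (146, 155),
            "H9": (166, 174), "B1": (42, 44), "B2": (58, 60), "B3": (79, 81),
            "B4": (115, 117), "B5": (136, 138), "B6": (163, 165),
            "L1": (56, 61), "L2": (133, 145), "L3": (175, 187),
            "PC": (11, 174), "HL": (93, 98),
        }
        for name, rng_ in expected.items():
            assert NCS1_SEGMENTS.range(name) == rng_
        assert NCS1_SEGMENTS.range("β1") == (42, 44)  # unicode strand alias
        assert NCS1_SEGMENTS.range("L3_METHODS") == (176, 190)
        assert all(lo <= hi for lo, hi in NCS1_SEGMENTS.entries.values())

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError, match="first residue"):
            SegmentTable({"X": (5, 2)})

    def test_backbone_selection_counts(self):
        from ncsmd import build_helix

        toy = build_helix(["ALA"] * 4)
        table = SegmentTable({"PC": (1, 2)})
        sel = select(toy, "PC", "backbone", table=table)
        assert len(sel) == 8  # 4 backbone atoms per residue

    def test_segment_restriction(self):
        from ncsmd import build_helix

        s = build_helix(["ALA"] * 20, start_id=5)
        sel = select(s, ["H1"], "backbone")  # H1 = 11..18
        assert set(s.residue_ids[sel.indices]) == set(range(11, 19))

    def test_empty_selection_is_an_error(self):
        from ncsmd import build_helix

        s = build_helix(["ALA"] * 4)  # no hydrogens
        with pytest.raises(ValueError, match="matched no atoms"):
            select(s, "ALL", "protons")

    def test_selection_is_order_stable_and_idempotent(self):
        from ncsmd import build_helix

        s = build_helix(["ALA"] * 20, start_id=5)
        a = select(s, ["H1"], "backbone")
        b = select(s, ["H1"], "backbone")
        assert np.array_equal(a.indices, b.indices)
        assert np.all(np.diff(a.indices) > 0)


class TestParamsIO:
    def test_read_and_total_lookup(self, tmp_path):
        p = tmp_path / "ff.tsv"
        p.write_text(
            "# residue atom charge epsilon rmin_half\n"
            "ALA CA 0.1 0.05 1.9\n"
            "GLU XN -1.0 0.05 1.8\n"
        )
        params = read_params(p)
        assert params.get("ALA", "CA").charge == pytest.approx(0.1)
        assert params.get("GLU", "XN").rmin_half == pytest.approx(1.8)
        with pytest.raises(KeyError, match="LYS"):
            params.get("LYS", "XP")

    @pytest.mark.parametrize(
        "row,err",
        [
            ("ALA CA 0.1 0.05 1.9\nALA CA 0.2 0.05 1.9", "duplicate"),
            ("ALA CA 0.1 -0.05 1.9", "negative epsilon"),
            ("ALA CA 0.1 0.05 0.0", "rmin_half"),
            ("ALA CA 0.1 0.05", "5 fields"),
            ("ALA CA x 0.05 1.9", "malformed"),
        ],
    )
    def test_malformed_tables_rejected(self, tmp_path, row, err):
        p = tmp_path / "bad.tsv"
        p.write_text(row + "\n")
        with pytest.raises(ValueError, match=err):
            read_params(p)

    def test_roundtrip(self, tmp_path):
        params = NonbondedParams(
            {("ALA", "CA"): NBParam(0.1, 0.05, 1.9), ("ALA", "XP"): NBParam(1.0, 0.01, 2.0)}
        )
        path = tmp_path / "ff.tsv"
        write_params(params, path)
        back = read_params(path)
        assert len(back) == 2
        assert back.get("ALA", "XP").charge == pytest.approx(1.0)


class TestRestraintsIO:
    def test_simple_row(self, tmp_path):
        p = tmp_path / "noe.tsv"
        p.write_text("12 HA 15 HN 4.5\n")
        (r,) = read_restraints(p)
        assert (r.res_i, r.atoms_i, r.res_j, r.atoms_j) == (12, ("HA",), 15, ("HN",))
        assert r.upper == pytest.approx(4.5)

    def test_equivalent_proton_groups_cross_product(self, tmp_path):
        p = tmp_path / "noe.tsv"
        p.write_text("3 HB1,HB2 7 HD1,HD2,HD3 5.0\n")
        (r,) = read_restraints(p)
        assert r.n_pairs == 6

    @pytest.mark.parametrize("row", ["12 HA 15 HN -4.5", "12 HA 15 HN x", "12 HA 15 4.5"])
    def test_malformed_rows_rejected(self, tmp_path, row):
        p = tmp_path / "noe.tsv"
        p.write_text(row + "\n")
        with pytest.raises(ValueError):
            read_restraints(p)

    def test_roundtrip(self, tmp_path):
        p = tmp_path / "noe.tsv"
        p.write_text("3 HB1,HB2 7 HN 5.0\n12 HA 15 HN 4.5\n")
        rst = read_restraints(p)
        out = tmp_path / "out.tsv"
        write_restraints(rst, out)
        back = read_restraints(out)
        assert [(r.res_i, r.atoms_i, r.res_j, r.atoms_j, r.upper) for r in back] == [
            (r.res_i, r.atoms_i, r.res_j, r.atoms_j, pytest.approx(r.upper)) for r in rst
        ]
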