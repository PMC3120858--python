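"""Structure, topology, trajectory and energy-table I/O."""

import io

import numpy as np
import pytest

from flipsite.errors import (
    ConfigurationError,
    RTFParseError,
    SchemaError,
    StructureError,
    StructureParseError,
)
from flipsite.structure_io import (
    EnergySeries,
    Frame,
    Trajectory,
    merge_parameters,
    read_charge_topology,
    read_energy_table,
    read_structure,
    read_trajectory,
    write_energy_table,
    write_structure,
    write_trajectory,
)
from flipsite.synthetic_data import ToyComplexSpec, make_toy_complex

from conftest import MINI_PDB_EXPECTED


SINGLE_ATOM_PDB = (
    "ATOM      1  O   HOH W   1       1.000   2.000   3.000"
    "  1.00  0.00           O\n"
)


class TestReadStructure:
    def test_single_atom_identity_parse(self):
        top, frames = read_structure(SINGLE_ATOM_PDB)
        assert top.n_atoms == 1
        atom = top.atoms[0]
        assert (atom.name, atom.residue_name, atom.residue_id, atom.chain) \
            == ("O", "HOH", 1, "W")
        assert atom.charge is None  # charges come from the charge topology
        assert len(frames) == 1
        np.testing.assert_allclose(frames[0].coordinates, [[1.0, 2.0, 3.0]])

    def test_multi_model_gives_one_topology_many_frames(self):
        text = (
            "MODEL        1\n" + SINGLE_ATOM_PDB + "ENDMDL\n"
            "MODEL        2\n"
            + SINGLE_ATOM_PDB.replace("1.000", "4.000") + "ENDMDL\n"
        )
        top, frames = read_structure(text)
        assert top.n_atoms == 1
        assert len(frames) == 2
        assert frames[0].coordinates[0, 0] == pytest.approx(1.0)
        assert frames[1].coordinates[0, 0] == pytest.approx(4.0)

    def test_mini_pdb_matches_manual_transcription(self, mini_pdb_text):
        top, frames = read_structure(mini_pdb_text)
        assert top.n_atoms == len(MINI_PDB_EXPECTED)
        for atom, (name, resname, resid, chain, x, y, z) in zip(
            top.atoms, MINI_PDB_EXPECTED
        ):
            assert atom.name == name
            assert atom.residue_name == resname
            assert atom.residue_id == resid
            assert atom.chain == chain
            np.testing.assert_allclose(
                frames[0].coordinates[atom.index], [x, y, z], atol=1e-3
            )
        # residue grouping: ALA1, SER2, DC5, HOH101, HOH102
        keys = [(r.chain, r.residue_id, r.residue_name) for r in top.residues]
        assert keys == [
            ("A", 1, "ALA"), ("A", 2, "SER"), ("B", 5, "DC"),
            ("W", 101, "HOH"), ("W", 102, "HOH"),
        ]

    def test_malformed_record_error_names_line(self, mini_pdb_text):
        lines = mini_pdb_text.splitlines()
        lines[2] = lines[2][:32] + "oops" + lines[2][36:]
        with pytest.raises(StructureParseError, match="line 3"):
            read_structure("\n".join(lines))

    def test_empty_input_raises(self):
        with pytest.raises(StructureParseError, match="empty"):
            read_structure("REMARK nothing here\n")

    def test_unicode_prime_normalized_to_apostrophe(self):
        text = SINGLE_ATOM_PDB.replace(" O  ", "C4′")
        top, _ = read_structure(text)
        assert top.atoms[0].name == "C4'"

    def test_write_read_round_trip_preserves_structure(self):
        top, traj, _ = make_toy_complex(ToyComplexSpec(n_frames=1))
        text = write_structure(top, traj[0])
        top2, frames2 = read_structure(text)
        assert top2.n_atoms == top.n_atoms
        assert [a.name for a in top2.atoms] == [a.name for a in top.atoms]
        assert [(r.chain, r.residue_id) for r in top2.residues] \
            == [(r.chain, r.residue_id) for r in top.residues]
        np.testing.assert_allclose(
            frames2[0].coordinates, traj[0].coordinates, atol=1e-3
        )


RTF_FIXTURE = """\
* three-residue fixture
RESI AAA  0.00
ATOM X1  CT  0.10
ATOM X2  CT -0.10
BOND X1 X2

RESI BBB -1.00
ATOM Y1  OC -0.50
ATOM Y2  OC -0.50
ACCE Y1
ACCE Y2

RESI CCC  0.00
ATOM Z1  NH -0.47
ATOM ZH  H   0.31
ATOM Z2  CT  0.16
BOND Z1 ZH  Z1 Z2
DONO ZH Z1
"""


class TestChargeTopology:
    def test_net_charge_is_sum_of_atom_charges(self):
        residues = read_charge_topology(RTF_FIXTURE)
        assert residues["AAA"].net_charge == pytest.approx(0.0)
        assert residues["BBB"].net_charge == pytest.approx(-1.0)

    def test_serine_hydroxyl_charges_retrievable_by_name(self, toy_params):
        ser = toy_params["SER"]
        assert ser.atom_charge("OG") == -0.66
        assert ser.atom_charge("HG1") == 0.43

    def test_three_residue_fixture_matches_hand_table(self):
        residues = read_charge_topology(RTF_FIXTURE)
        assert set(residues) == {"AAA", "BBB", "CCC"}
        assert residues["AAA"].atoms == [("X1", "CT", 0.10), ("X2", "CT", -0.10)]
        assert residues["AAA"].bonds == [("X1", "X2")]
        assert residues["BBB"].acceptors == ["Y1", "Y2"]
        assert residues["CCC"].atoms == [
            ("Z1", "NH", -0.47), ("ZH", "H", 0.31), ("Z2", "CT", 0.16)
        ]
        assert residues["CCC"].donors == [("ZH", "Z1")]
        assert residues["CCC"].bonds == [("Z1", "ZH"), ("Z1", "Z2")]

    def test_non_numeric_charge_error_names_line(self):
        bad = "RESI XXX 0.0\nATOM A1 CT 0.1\nATOM A2 CT abc\n"
        with pytest.raises(RTFParseError, match="line 3"):
            read_charge_topology(bad)

    def test_duplicate_atom_name_raises(self):
        bad = "RESI XXX 0.0\nATOM A1 CT 0.1\nATOM A1 CT 0.2\n"
        with pytest.raises(RTFParseError, match="duplicate"):
            read_charge_topology(bad)

    def test_merge_assigns_every_charge_and_keeps_order(self, toy_params):
        rows = [
            ("N", "N"), ("HN", "H"), ("CA", "C"), ("HA", "H"), ("CB", "C"),
            ("HB1", "H"), ("HB2", "H"), ("OG", "O"), ("HG1", "H"),
        ]
        pdb = "".join(
            f"ATOM    {i + 1:3d}  {name:<4s}SER A   2      "
            f"{float(i):6.3f}   0.000   0.000  1.00  0.00           {el}\n"
            for i, (name, el) in enumerate(rows)
        )
        top, _ = read_structure(pdb)
        merged = merge_parameters(top, toy_params)
        assert [a.name for a in merged.atoms] == [n for n, _ in rows]
        by_name = {a.name: a for a in merged.atoms}
        assert by_name["OG"].charge == -0.66
        assert by_name["HG1"].charge == 0.43
        assert merged.total_charge == pytest.approx(0.0, abs=1e-12)
        assert "donor" in by_name["OG"].roles
        assert "acceptor" in by_name["OG"].roles
        assert "hydrogen" in by_name["HG1"].roles
        assert len(merged.bonds) == 8

    def test_merge_with_unknown_residue_raises(self, toy_params):
        top, _ = read_structure(SINGLE_ATOM_PDB)  # residue HOH, not in table
        with pytest.raises(StructureError, match="HOH"):
            merge_parameters(top, toy_params)


def _random_trajectory(rng, n_frames=10, n_atoms=7, dt=5.0):
    frames = [
        Frame(coordinates=rng.normal(size=(n_atoms, 3)) * 10.0, time=k * dt)
        for k in range(n_frames)
    ]
    return Trajectory(frames, dt=dt)


class TestTrajectoryIO:
    def test_xyz_csv_round_trip_is_exact(self):
        rng = np.random.default_rng(7)
        traj = _random_trajectory(rng, n_frames=50)
        text = write_trajectory(traj, None, format="xyz-csv")
        back = read_trajectory(text, format="xyz-csv")
        assert back.n_frames == 50
        for f1, f2 in zip(traj, back):
            np.testing.assert_array_equal(f1.coordinates, f2.coordinates)
            assert f1.time == f2.time

    def test_multi_model_pdb_times_follow_dt(self):
        top, traj, _ = make_toy_complex(ToyComplexSpec(n_frames=10))
        text = write_trajectory(traj, None, format="pdb", topology=top)
        back = read_trajectory(text, format="pdb", topology=top, dt=5.0)
        np.testing.assert_allclose(back.times, np.arange(10) * 5.0)
        np.testing.assert_allclose(
            back[0].coordinates, traj[0].coordinates, atol=1e-3
        )

    def test_pdb_requires_dt(self):
        top, traj, _ = make_toy_complex(ToyComplexSpec(n_frames=2))
        text = write_trajectory(traj, None, format="pdb", topology=top)
        with pytest.raises(ConfigurationError, match="dt"):
            read_trajectory(text, format="pdb", topology=top)

    def test_dcd_round_trip_within_storage_precision(self, tmp_path):
        rng = np.random.default_rng(11)
        traj = _random_trajectory(rng, n_frames=5)
        path = tmp_path / "traj.dcd"
        write_trajectory(traj, path, format="dcd")
        back = read_trajectory(path, format="dcd", n_atoms=7, dt=5.0)
        assert back.n_frames == 5
        for f1, f2 in zip(traj, back):
            np.testing.assert_allclose(f1.coordinates, f2.coordinates,
                                       atol=1e-4)

    def test_atom_count_mismatch_raises(self):
        rng = np.random.default_rng(3)
        traj = _random_trajectory(rng, n_frames=3, n_atoms=7)
        text = write_trajectory(traj, None, format="xyz-csv")
        with pytest.raises(StructureError, match="atom"):
            read_trajectory(text, format="xyz-csv", n_atoms=9)

    def test_truncated_final_frame_dropped_with_warning(self):
        rng = np.random.default_rng(5)
        traj = _random_trajectory(rng, n_frames=4, n_atoms=6)
        text = write_trajectory(traj, None, format="xyz-csv")
        truncated = "\n".join(text.splitlines()[:-2]) + "\n"
        with pytest.warns(UserWarning, match="truncated"):
            back = read_trajectory(truncated, format="xyz-csv", n_atoms=6)
        assert back.n_frames == 3

    def test_times_must_increase(self):
        f = Frame(coordinates=np.zeros((2, 3)), time=0.0)
        with pytest.raises(StructureError, match="increasing"):
            Trajectory([f, f], dt=1.0)


class TestEnergyTables:
    def test_header_only_table_is_empty_series(self):
        series = read_energy_table("time_ps,v_el_kcalmol,v_vdw_kcalmol\n")
        assert len(series) == 0

    def test_three_row_table_verbatim(self):
        text = (
            "time_ps,v_el_kcalmol,v_vdw_kcalmol\n"
            "5.0,-10.25,-3.5\n10.0,-11.0,-3.25\n15.0,-9.75,-4.0\n"
        )
        series = read_energy_table(text)
        np.testing.assert_array_equal(series.times, [5.0, 10.0, 15.0])
        np.testing.assert_array_equal(series.v_el, [-10.25, -11.0, -9.75])
        np.testing.assert_array_equal(series.v_vdw, [-3.5, -3.25, -4.0])

    def test_large_table_round_trip_below_1e9(self):
        rng = np.random.default_rng(13)
        series = EnergySeries(
            state_label="bound",
            times=5.0 * np.arange(1, 1001),
            v_el=rng.normal(-300.0, 50.0, 1000),
            v_vdw=rng.normal(-80.0, 10.0, 1000),
        )
        back = read_energy_table(write_energy_table(series))
        assert np.max(np.abs(back.v_el - series.v_el)) < 1e-9
        assert np.max(np.abs(back.v_vdw - series.v_vdw)) < 1e-9
        assert np.max(np.abs(back.times - series.times)) < 1e-9

    def test_missing_column_error_names_column(self):
        with pytest.raises(SchemaError, match="v_vdw_kcalmol"):
            read_energy_table("time_ps,v_el_kcalmol\n1.0,-1.0\n")

    def test_window_is_half_open_on_the_left(self):
        series = EnergySeries("bound", [5.0, 10.0, 15.0], [1, 2, 3], [0, 0, 0])
        sub = series.window(5.0, 15.0)
        np.testing.assert_array_equal(sub.times, [10.0, 15.0])
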