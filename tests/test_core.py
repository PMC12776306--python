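"""Structure/trajectory data model, selection grammar and geometry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lipidsite.io as lio
from lipidsite.core import (
    AtomGroup,
    Frame,
    Topology,
    Trajectory,
    min_image_distance,
    superpose,
)
from lipidsite.select import SelectionError, select

from conftest import make_trajectory, point_topology


class TestReadStructure:
    def test_toy_pdb_identity(self, toy_pdb):
        top, frame = lio.read_structure(toy_pdb)
        assert top.n_atoms == 3
        assert list(top.atom_names) == ["N", "CA", "C1"]
        assert list(top.residue_numbers) == [1, 1, 2]
        assert list(top.molecule_kinds) == ["protein", "protein", "lipid"]
        np.testing.assert_allclose(frame.coordinates[0], [1.0, 2.0, 3.0], atol=1e-3)

    def test_partition_by_residue(self, toy_pdb):
        top, _ = lio.read_structure(toy_pdb)
        res1 = select(top, "resid 1")
        res2 = select(top, "resid 2")
        assert sorted([*res1.atom_ids, *res2.atom_ids]) == [0, 1, 2]
        assert list(res1.atom_ids) == [0, 1]

    def test_pdb_round_trip(self, arg_topology, tmp_path):
        frame = Frame(np.arange(arg_topology.n_atoms * 3, dtype=float).reshape(-1, 3))
        path = tmp_path / "out.pdb"
        lio.write_pdb(path, arg_topology, frame)
        top2, frame2 = lio.read_structure(path)
        assert list(top2.atom_names) == list(arg_topology.atom_names)
        assert list(top2.residue_numbers) == list(arg_topology.residue_numbers)
        np.testing.assert_allclose(frame2.coordinates, frame.coordinates, atol=1e-3)

    def test_empty_pdb_errors(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("END\n")
        with pytest.raises(Exception):
            lio.read_structure(path)


class TestTrajectoryIO:
    def test_fixture_round_trip_exact(self, tmp_path):
        top = point_topology(2)
        rng = np.random.default_rng(0)
        traj = make_trajectory(top, rng.uniform(0, 10, size=(5, 2, 3)),
                               box=(10, 10, 10), dt=1.0)
        path = tmp_path / "t.tsv"
        lio.write_fixture_trajectory(path, traj)
        back = lio.read_fixture_trajectory(path, top)
        assert back.n_frames == 5
        assert [f.time_ns for f in back.frames] == [0, 1, 2, 3, 4]
        for a, b in zip(traj.frames, back.frames):
            assert np.array_equal(a.coordinates, b.coordinates)  # bit-identical

    def test_atom_count_mismatch(self, tmp_path):
        traj = make_trajectory(point_topology(2), np.zeros((2, 2, 3)) + [[1, 1, 1], [2, 2, 2]])
        path = tmp_path / "t.tsv"
        lio.write_fixture_trajectory(path, traj)
        with pytest.raises(ValueError, match="atoms"):
            lio.read_fixture_trajectory(path, point_topology(3))

    def test_dcd_round_trip(self, tmp_path):
        top = point_topology(4)
        rng = np.random.default_rng(1)
        traj = make_trajectory(top, rng.uniform(0, 30, size=(6, 4, 3)),
                               box=(30, 30, 30), dt=0.5)
        path = tmp_path / "t.dcd"
        lio.write_trajectory(path, traj)
        back = lio.read_trajectory(path, top, frame_interval_ns=0.5)
        assert back.n_frames == 6
        dev = max(
            np.abs(a.coordinates - b.coordinates).max()
            for a, b in zip(traj.frames, back.frames)
        )
        assert dev < 1e-3  # float32 storage in DCD


class TestSelect:
    def test_sidechain_of_arginine(self, arg_topology):
        grp = select(arg_topology, "resid 63 and sidechain")
        names = set(arg_topology.atom_names[grp.atom_ids])
        assert names == {"CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"}

    def test_not_protein_gives_lipids(self, arg_topology):
        grp = select(arg_topology, "not protein")
        assert set(arg_topology.residue_names[grp.atom_ids]) == {"DHA"}

    def test_glycine_sidechain_empty_warns(self, arg_topology):
        with pytest.warns(UserWarning, match="no atoms"):
            grp = select(arg_topology, "resid 64 and sidechain")
        assert len(grp) == 0

    def test_compound_vs_hand_enumeration(self, arg_topology):
        grp = select(arg_topology, "(resid 63 and name CZ NH1 NH2) or resname DHA")
        expected = [
            i for i in range(arg_topology.n_atoms)
            if (arg_topology.residue_numbers[i] == 63
                and arg_topology.atom_names[i] in ("CZ", "NH1", "NH2"))
            or arg_topology.residue_names[i] == "DHA"
        ]
        assert list(grp.atom_ids) == expected

    def test_stability(self, arg_topology):
        a = select(arg_topology, "sidechain or lipid")
        b = select(arg_topology, "sidechain or lipid")
        assert np.array_equal(a.atom_ids, b.atom_ids)

    def test_syntax_error_reports_position(self, arg_topology):
        with pytest.raises(SelectionError, match="position"):
            select(arg_topology, "resid 63 and bogus")
        with pytest.raises(SelectionError):
            select(arg_topology, "resid")


class TestMinImage:
    def test_examples(self):
        assert min_image_distance((1, 1, 1), (9, 1, 1), (10, 10, 10)) == pytest.approx(2.0)
        assert min_image_distance((3, 4, 5), (3, 4, 5), (10, 10, 10)) == 0.0
        assert min_image_distance((0, 0, 0), (3, 4, 0)) == pytest.approx(5.0)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            min_image_distance((np.nan, 0, 0), (0, 0, 0), (10, 10, 10))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_matches_27_image_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        box = rng.uniform(5, 20, 3)
        p = rng.uniform(-30, 30, 3)
        q = rng.uniform(-30, 30, 3)
        images = [
            np.linalg.norm(p - (q + box * np.array([i, j, k])))
            for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
        ]
        # wrap first so the nearest image is within one box shift
        pw, qw = np.mod(p, box), np.mod(q, box)
        oracle = min(
            np.linalg.norm(pw - (qw + box * np.array([i, j, k])))
            for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
        )
        assert min_image_distance(p, q, box) == pytest.approx(oracle, abs=1e-9)


class TestSuperpose:
    @staticmethod
    def _frames():
        rng = np.random.default_rng(42)
        coords = rng.uniform(0, 10, size=(8, 3))
        return Frame(coords)

    def test_identity(self):
        ref = self._frames()
        grp = AtomGroup(point_topology(8), np.arange(8))
        out = superpose(ref, ref, grp)
        np.testing.assert_allclose(out.coordinates, ref.coordinates, atol=1e-12)

    def test_known_rotation_recovered(self):
        ref = self._frames()
        theta = 0.7
        R = np.array([
            [np.cos(theta), -np.sin(theta), 0],
            [np.sin(theta), np.cos(theta), 0],
            [0, 0, 1],
        ])
        mobile = Frame(ref.coordinates @ R.T + [3.0, -2.0, 1.0])
        grp = AtomGroup(point_topology(8), np.arange(8))
        fitted = superpose(mobile, ref, grp)
        rmsd = np.sqrt(((fitted.coordinates - ref.coordinates) ** 2).sum(1).mean())
        assert rmsd < 1e-8

    def test_translation_only(self):
        ref = self._frames()
        mobile = Frame(ref.coordinates + [5.0, 5.0, 5.0])
        grp = AtomGroup(point_topology(8), np.arange(8))
        fitted = superpose(mobile, ref, grp)
        rmsd = np.sqrt(((fitted.coordinates - ref.coordinates) ** 2).sum(1).mean())
        assert rmsd < 1e-10

    def test_idempotent(self):
        ref = self._frames()
        rng = np.random.default_rng(3)
        mobile = Frame(ref.coordinates + rng.normal(0, 0.5, size=ref.coordinates.shape))
        grp = AtomGroup(point_topology(8), np.arange(8))
        once = superpose(mobile, ref, grp)
        twice = superpose(once, ref, grp)
        assert np.abs(twice.coordinates - once.coordinates).max() < 1e-9

    def test_collinear_degenerate(self):
        coords = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        frame = Frame(coords)
        grp = AtomGroup(point_topology(4), np.arange(4))
        with pytest.raises(ValueError, match="collinear|degenerate"):
            superpose(frame, frame, grp)


class TestInvariants:
    def test_frame_times_strictly_increasing(self):
        top = point_topology(1)
        frames = [Frame(np.zeros((1, 3)), time_ns=t) for t in (0.0, 1.0, 1.0)]
        with pytest.raises(ValueError, match="increasing"):
            Trajectory(top, frames, 1.0)

    def test_box_positive(self):
        with pytest.raises(ValueError, match="positive"):
            Frame(np.zeros((1, 3)), box=(0, 10, 10))

    def test_atom_group_deduplicates_and_bounds(self):
        top = point_topology(3)
        grp = AtomGroup(top, np.array([2, 0, 2]))
        assert list(grp.atom_ids) == [0, 2]
        with pytest.raises(ValueError):
            AtomGroup(top, np.array([5]))
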