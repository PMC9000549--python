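import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from channelgate.hydration import (WaterWireCriteria, classify_frame,
                                   occupancy_series, select_channel_waters,
                                   water_adjacency)
from channelgate.model_io import ChannelDefinition, Frame
from channelgate.synthetic import SyntheticSpec, generate_trajectory
from conftest import make_water_frame
from oracles import brute_force_adjacency, brute_force_spanning

# four wall atoms give the frame a pore axis through the origin
WALL = [("CA", "ALA", r, s, (x, y, 0.0))
        for r, s, (x, y) in [(100, "S1", (8, 0)), (140, "S2", (0, 8)),
                             (170, "S3", (-8, 0)), (200, "S4", (0, -8))]]

CHANNEL = ChannelDefinition(membrane_z=(-10.0, 10.0),
                            water_cylinder_radius=6.0, boundary_margin=2.0)


def frame_with_waters(positions):
    return make_water_frame(positions, extra_atoms=WALL)


class TestChannelWaterSelection:
    def test_axis_water_selected(self):
        f = frame_with_waters([[0.0, 0.0, 0.0]])
        assert len(select_channel_waters(f, CHANNEL)) == 1

    def test_far_off_axis_water_excluded(self):
        f = frame_with_waters([[12.0, 0.0, 0.0]])  # 2x cylinder radius
        assert len(select_channel_waters(f, CHANNEL)) == 0

    def test_no_waters_is_empty_not_error(self):
        f = make_water_frame(np.empty((0, 3)), extra_atoms=WALL)
        assert len(select_channel_waters(f, CHANNEL)) == 0

    def test_matches_point_in_cylinder_oracle(self):
        rng = np.random.default_rng(17)
        pts = rng.uniform([-15, -15, -16], [15, 15, 16], size=(100, 3))
        f = frame_with_waters(pts)
        got = set(select_channel_waters(f, CHANNEL))
        expected = set()
        ox = [i for i in range(f.n_atoms)
              if f.topology.resnames[i] == "TIP3"]
        for i in ox:
            x, y, z = f.positions[i]
            if np.hypot(x, y) <= 6.0 and -12.0 <= z <= 12.0:
                expected.add(i)
        assert got == expected


class TestAdjacency:
    def test_pair_below_cutoff_is_edge(self):
        f = frame_with_waters([[0, 0, 0], [0, 0, 2.8]])
        assert len(water_adjacency(np.array([0, 1]), f)) == 1

    def test_exact_cutoff_is_not_edge(self):
        """The criterion is strictly 'less than' the 3.4 Å cutoff."""
        f = frame_with_waters([[0, 0, 0], [0, 0, 3.4]])
        assert water_adjacency(np.array([0, 1]), f) == set()

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-6, 6, size=(50, 3))
        f = frame_with_waters(pts)
        idx = np.arange(50)
        assert water_adjacency(idx, f) == brute_force_adjacency(
            idx, f.positions, 3.4)


class TestFrameClassification:
    @staticmethod
    def chain(spacing=2.8, z_lo=-13.0, z_hi=13.0):
        n = int(np.ceil((z_hi - z_lo) / spacing)) + 1
        return np.column_stack([np.zeros(n), np.zeros(n),
                                np.linspace(z_lo, z_hi, n)])

    def test_planted_spanning_chain_is_continuous(self):
        f = frame_with_waters(self.chain())
        cont, path = classify_frame(f, CHANNEL)
        assert cont
        assert len(path) >= 2
        # path endpoints lie beyond the membrane slab
        zs = f.positions[path][:, 2]
        assert zs.min() <= -10.0 and zs.max() >= 10.0
        # consecutive O-O distances all under the cutoff
        hops = np.diff(f.positions[path], axis=0)
        assert np.all(np.linalg.norm(hops, axis=1) < 3.4)

    def test_single_widened_gap_breaks_the_wire(self):
        pts = self.chain()
        k = len(pts) // 2
        spacing = pts[1, 2] - pts[0, 2]
        pts[k:, 2] += 3.5 - spacing  # one hop becomes 3.5 Å
        cont, path = classify_frame(frame_with_waters(pts), CHANNEL)
        assert not cont
        assert path == []

    def test_matches_component_oracle_on_random_frames(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            pts = rng.uniform([-5, -5, -13], [5, 5, 13], size=(200, 3))
            f = frame_with_waters(pts)
            cont, _ = classify_frame(f, CHANNEL)
            inside = select_channel_waters(f, CHANNEL)
            assert cont == brute_force_spanning(
                inside, f.positions, 3.4, -10.0, 10.0)

    def test_invariant_to_water_index_permutation(self):
        rng = np.random.default_rng(4)
        pts = self.chain()
        perm = rng.permutation(len(pts))
        cont1, _ = classify_frame(frame_with_waters(pts), CHANNEL)
        cont2, _ = classify_frame(frame_with_waters(pts[perm]), CHANNEL)
        assert cont1 == cont2

    def test_invariant_to_in_plane_rigid_motion(self):
        pts = self.chain()
        theta = 0.8
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        moved_frame = make_water_frame(
            (pts + [1.5, -2.0, 0.0]) @ R.T,
            extra_atoms=[(n, rn, r, s, R @ (np.array(p) + [1.5, -2.0, 0.0]))
                         for n, rn, r, s, p in WALL])
        cont, _ = classify_frame(moved_frame, CHANNEL)
        assert cont

    @settings(derandomize=True, max_examples=25)
    @given(extra=st.floats(0.0, 3.0))
    def test_raising_cutoff_never_breaks_continuity(self, extra):
        pts = self.chain(spacing=3.0)
        f = frame_with_waters(pts)
        base = classify_frame(f, CHANNEL, WaterWireCriteria(3.4))[0]
        wider = classify_frame(f, CHANNEL, WaterWireCriteria(3.4 + extra))[0]
        assert wider >= base


class TestOccupancy:
    def test_all_frames_continuous(self):
        spec = SyntheticSpec(n_frames=10, seed=1, wire_fraction=1.0)
        traj, _ = generate_trajectory(spec)
        res = occupancy_series(traj, spec.channel())
        assert res.occupancy == 1.0
        assert res.run_lengths == [10]

    def test_planted_fraction_recovered_exactly(self, small_synthetic):
        spec, traj, manifest = small_synthetic
        res = occupancy_series(traj, spec.channel())
        assert res.occupancy == manifest.wire_fraction
        assert [int(i) for i in res.frame_indices[res.per_frame]] \
            == manifest.wire_frames

    def test_alternating_frames_have_unit_runs(self, water_frame_factory):
        spec = SyntheticSpec(n_frames=6, seed=2, wire_fraction=0.5)
        traj, man = generate_trajectory(spec)
        res = occupancy_series(traj, spec.channel())
        assert all(r >= 1 for r in res.run_lengths)
        assert sum(res.run_lengths) == 3

    def test_equil_start_restricts_frames(self, small_synthetic):
        spec, traj, manifest = small_synthetic
        res = occupancy_series(traj, spec.channel(), equil_start=10)
        expected = np.mean([f >= 10 and f in set(manifest.wire_frames)
                            for f in range(10, 20)])
        assert res.occupancy == expected

    def test_empty_range_is_error(self, small_synthetic):
        spec, traj, _ = small_synthetic
        with pytest.raises(ValueError):
            occupancy_series(traj, spec.channel(), equil_start=99)
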