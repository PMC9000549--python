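import numpy as np
import pytest

from channelgate.hydration import occupancy_series
from channelgate.model_io import Trajectory
from channelgate.synthetic import (ContactSchedule, GroundTruthManifest,
                                   SyntheticSpec, generate_scaffold,
                                   generate_trajectory, load_synthetic_spec,
                                   verify_manifest)


class TestSpecValidation:
    def test_non_integral_wire_count_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            SyntheticSpec(n_frames=10, wire_fraction=0.33)

    def test_zero_radius_scaffold_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            SyntheticSpec(scaffold_radius=0.0)

    def test_spacing_must_straddle_cutoff(self):
        with pytest.raises(ValueError):
            SyntheticSpec(wire_spacing=3.5)
        with pytest.raises(ValueError):
            SyntheticSpec(gap_size=3.0)


class TestScaffold:
    def test_atom_accounting(self):
        spec = SyntheticSpec(n_frames=2, wire_fraction=0.5)
        frame = generate_scaffold(spec)
        channel = spec.channel()
        wall = 4 * spec.n_rings * spec.atoms_per_ring
        # gate residues contribute CA only from the wall...
        wall -= len(channel.gate_residues) * (spec.atoms_per_ring - 1)
        # ...plus their planted sidechains
        from channelgate.synthetic import GATE_SIDECHAINS
        side = sum(len(GATE_SIDECHAINS[name])
                   for _, name in channel.gate_residues)
        assert frame.n_atoms == wall + side

    def test_residue_numbers_lie_in_default_ranges(self):
        spec = SyntheticSpec(n_frames=2, wire_fraction=0.5)
        frame = generate_scaffold(spec)
        channel = spec.channel()
        for label, (lo, hi) in channel.helix_ranges.items():
            nums = frame.topology.resnums[frame.topology.segments == label]
            assert nums.min() >= lo and nums.max() <= hi

    def test_wall_atoms_sit_on_the_stated_radius(self):
        spec = SyntheticSpec(n_frames=2, wire_fraction=0.5)
        frame = generate_scaffold(spec)
        wall = np.isin(frame.topology.names, ["CA"])
        r = np.hypot(frame.positions[wall, 0], frame.positions[wall, 1])
        assert np.allclose(r, spec.scaffold_radius, atol=2e-3)


class TestGeneratedTrajectory:
    def test_bitwise_determinism(self):
        spec_kw = dict(n_frames=12, seed=21, wire_fraction=0.25,
                       decoy_waters=3,
                       helix_schedules={"S4": np.linspace(0, 1, 12)})
        t1, m1 = generate_trajectory(SyntheticSpec(**spec_kw))
        t2, m2 = generate_trajectory(SyntheticSpec(**spec_kw))
        assert np.array_equal(t1.coords, t2.coords)
        assert m1.wire_frames == m2.wire_frames
        assert m1.coords_checksum == m2.coords_checksum

    def test_seed_changes_wire_placement(self):
        a = generate_trajectory(SyntheticSpec(n_frames=20, seed=1,
                                              wire_fraction=0.5))[1]
        b = generate_trajectory(SyntheticSpec(n_frames=20, seed=2,
                                              wire_fraction=0.5))[1]
        assert a.wire_frames != b.wire_frames

    @pytest.mark.parametrize("fraction,expected", [(0.0, 0.0), (1.0, 1.0)])
    def test_extreme_fractions(self, fraction, expected):
        spec = SyntheticSpec(n_frames=8, seed=3, wire_fraction=fraction)
        traj, _ = generate_trajectory(spec)
        assert occupancy_series(traj, spec.channel()).occupancy == expected

    def test_exact_wire_count_at_fraction_03(self):
        spec = SyntheticSpec(n_frames=200, seed=7, wire_fraction=0.3)
        traj, manifest = generate_trajectory(spec)
        assert len(manifest.wire_frames) == 60
        res = occupancy_series(traj, spec.channel())
        assert res.occupancy == 0.30

    def test_decoy_waters_stay_outside_cylinder(self):
        spec = SyntheticSpec(n_frames=4, seed=5, wire_fraction=0.5,
                             decoy_waters=10)
        traj, manifest = generate_trajectory(spec)
        res = occupancy_series(traj, spec.channel())
        assert [int(i) for i in res.frame_indices[res.per_frame]] \
            == manifest.wire_frames


class TestManifestVerification:
    def test_untouched_pair_has_empty_diff(self):
        spec = SyntheticSpec(
            n_frames=10, seed=13, wire_fraction=0.5,
            helix_schedules={"S2": np.linspace(0, -1.5, 10)},
            contact_schedule=[ContactSchedule((108, "ASP"), (204, "ARG"),
                                              list(range(5, 10)))])
        traj, manifest = generate_trajectory(spec)
        report = verify_manifest(traj, manifest, spec.channel())
        assert report["disagreements"] == []
        assert all(report["checks"].values())

    def test_widened_wire_gap_is_flagged(self):
        spec = SyntheticSpec(n_frames=6, seed=2, wire_fraction=0.5)
        traj, manifest = generate_trajectory(spec)
        bad = traj.coords.copy()
        f = manifest.wire_frames[0]
        waters = np.flatnonzero(traj.topology.segments == "WAT")
        k = waters[len(waters) // 2]
        bad[f, waters[waters >= k], 2] += 2.0  # breaks one planted wire
        broken = Trajectory(traj.topology, bad, traj.times)
        report = verify_manifest(broken, manifest, spec.channel(),
                                 check_pore=False)
        assert any(str(f) in d for d in report["disagreements"])

    @pytest.mark.parametrize("seed", range(5))
    def test_seed_sweep_all_clean(self, seed):
        spec = SyntheticSpec(n_frames=8, seed=seed, wire_fraction=0.25)
        traj, manifest = generate_trajectory(spec)
        report = verify_manifest(traj, manifest, spec.channel(),
                                 check_pore=(seed == 0))
        assert report["disagreements"] == []


class TestYamlSpec:
    def test_round_trip_through_yaml(self, tmp_path):
        text = """
n_frames: 10
seed: 4
wire_fraction: 0.5
helix_schedules:
  S4: {linear: 2.0}
  S2: {step: {at: 5, dz: -1.0}}
contact_schedule:
  - acidic: [108, ASP]
    basic: [204, ARG]
    on_frames: [[5, 9]]
gate_drift:
  residue: [146, PHE]
  dz: -2.0
"""
        p = tmp_path / "spec.yaml"
        p.write_text(text)
        spec = load_synthetic_spec(p)
        assert spec.n_frames == 10
        assert spec.helix_schedules["S4"][-1] == 2.0
        assert spec.helix_schedules["S2"][4] == 0.0
        assert spec.helix_schedules["S2"][5] == -1.0
        assert spec.contact_schedule[0].on_frames == [5, 6, 7, 8, 9]
        assert spec.gate_drift == ((146, "PHE"), -2.0)
        traj, manifest = generate_trajectory(spec)
        assert verify_manifest(traj, manifest, spec.channel(),
                               check_pore=False)["disagreements"] == []

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            load_synthetic_spec({"n_frames": 4, "wire_fraction": 0.5,
                                 "bogus": 1})

    def test_manifest_json_round_trip(self, tmp_path):
        spec = SyntheticSpec(n_frames=6, seed=11, wire_fraction=0.5)
        _, manifest = generate_trajectory(spec)
        p = tmp_path / "manifest.json"
        manifest.to_json(p)
        back = GroundTruthManifest.from_json(p)
        assert back.wire_frames == manifest.wire_frames
        assert back.pore_radius_by_z == manifest.pore_radius_by_z
        assert back.coords_checksum == manifest.coords_checksum
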