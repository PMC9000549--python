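import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from channelgate.model_io import (ChannelDefinition, FieldSpec, ParseError,
                                  Topology, TopologyError, Trajectory,
                                  detect_equilibration, field_magnitude,
                                  infer_element, read_trajectory,
                                  vdw_radius_for_element, write_trajectory)
from channelgate.synthetic import SyntheticSpec, generate_trajectory

def _atom_line(serial, name, resname, chain, resseq, x, y, z, segid, element):
    nm = name if len(name) >= 4 else " " + name
    return (f"ATOM  {serial:>5d} {nm:<4s} {resname:<4s}{chain:1s}"
            f"{resseq:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"      {segid:<4s}{element:>2s}")


def _toy_pdb(drop_last_atom_in_model_2=False, break_coords=False):
    atoms = [
        ("CA", "ALA", "A", 97, (10.0, 20.0, 30.0), "S1", "C"),
        ("CB", "ALA", "A", 97, (11.0, 20.0, 30.0), "S1", "C"),
        ("CA", "ALA", "A", 98, (10.0, 21.5, 33.0), "S1", "C"),
        ("OH2", "TIP3", "W", 1001, (1.234, 2.345, 3.456), "WAT", "O"),
        ("OH2", "TIP3", "W", 1002, (1.234, 2.345, 6.100), "WAT", "O"),
    ]
    lines = []
    for model, dx in ((1, 0.0), (2, 0.5)):
        lines.append(f"MODEL     {model:>4d}")
        keep = atoms[:-1] if (model == 2 and drop_last_atom_in_model_2) \
            else atoms
        for i, (nm, rn, ch, rs, (x, y, z), seg, el) in enumerate(keep, 1):
            lines.append(_atom_line(i, nm, rn, ch, rs, x + dx, y, z + dx,
                                    seg, el))
        lines.append("ENDMDL")
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if break_coords:
        text = text.replace("   1.234   2.345   3.456",
                            "   1.2xx   2.345   3.456")
    return text


class TestPdbReading:
    def test_two_model_five_atom_file(self, tmp_path):
        p = tmp_path / "toy.pdb"
        p.write_text(_toy_pdb())
        traj = read_trajectory(p)
        assert traj.n_frames == 2
        assert traj.n_atoms == 5
        assert traj.coords[0, 0, 0] == pytest.approx(10.0)
        assert traj.coords[1, 3, 2] == pytest.approx(3.956)
        assert list(traj.topology.segments[:2]) == ["S1", "S1"]
        # waters recognized
        from channelgate.model_io import water_oxygen_indices
        assert list(water_oxygen_indices(traj.topology)) == [3, 4]

    def test_missing_atom_in_model_is_topology_error(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text(_toy_pdb(drop_last_atom_in_model_2=True))
        with pytest.raises(TopologyError):
            read_trajectory(p)

    def test_malformed_coordinates_named_with_line(self, tmp_path):
        p = tmp_path / "broken.pdb"
        p.write_text(_toy_pdb(break_coords=True))
        with pytest.raises(ParseError, match=r":5"):
            read_trajectory(p)


class TestRoundTrip:
    def test_pdb_round_trip_is_bitwise(self, tmp_path, small_synthetic):
        _, traj, _ = small_synthetic
        p = tmp_path / "synth.pdb"
        write_trajectory(traj, p)
        back = read_trajectory(p)
        assert back.n_frames == traj.n_frames
        assert np.array_equal(back.coords, traj.coords)
        assert back.topology_checksum == traj.topology_checksum

    def test_frame_csv_round_trip(self, tmp_path, small_synthetic):
        _, traj, _ = small_synthetic
        p = tmp_path / "synth.csv"
        write_trajectory(traj, p, format="frame_csv")
        back = read_trajectory(p, format="frame_csv")
        assert np.array_equal(back.coords, traj.coords)

    def test_empty_trajectory_write_is_error(self, tmp_path, small_synthetic):
        _, traj, _ = small_synthetic
        empty = Trajectory(traj.topology, traj.coords[:0], [])
        with pytest.raises(ValueError):
            write_trajectory(empty, tmp_path / "x.pdb")

    def test_hundred_frame_round_trip_count(self, tmp_path):
        spec = SyntheticSpec(n_frames=100, seed=3, wire_fraction=0.5)
        traj, _ = generate_trajectory(spec)
        p = tmp_path / "t.pdb"
        write_trajectory(traj, p)
        assert read_trajectory(p).n_frames == 100


class TestFieldMagnitude:
    def test_zero_potential(self):
        assert field_magnitude(0.0, 36.0).magnitude_mV_per_A == 0.0

    def test_strongest_condition(self):
        # 250 mV across a 36 Å membrane
        assert field_magnitude(250.0, 36.0).magnitude_mV_per_A \
            == pytest.approx(250.0 / 36.0)

    def test_zero_thickness_rejected(self):
        with pytest.raises(ValueError):
            field_magnitude(150.0, 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(v=st.floats(-500, 500), t=st.floats(1.0, 100.0),
           k=st.floats(-3.0, 3.0))
    def test_linear_in_potential_inverse_in_thickness(self, v, t, k):
        base = field_magnitude(v, t).magnitude_mV_per_A
        assert field_magnitude(k * v, t).magnitude_mV_per_A \
            == pytest.approx(k * base, abs=1e-9)
        assert field_magnitude(v, 2 * t).magnitude_mV_per_A \
            == pytest.approx(base / 2, abs=1e-9)


class TestEquilibrationDetection:
    def test_constant_series_is_index_zero(self):
        assert detect_equilibration([1.5] * 40, window=10) == 0

    def test_ramp_then_plateau(self):
        # strict ramp through frame 49, flat from frame 50 on
        series = np.concatenate([np.linspace(0, 2.5, 51)[:50],
                                 np.full(50, 2.5)])
        idx = detect_equilibration(series, window=10, slope_tol=1e-3)
        assert 50 <= idx <= 60
        # direct slope check at the detected window
        seg = series[idx:idx + 10]
        slope = np.polyfit(np.arange(10), seg, 1)[0]
        assert abs(slope) < 1e-3

    def test_short_series_is_error(self):
        with pytest.raises(ValueError):
            detect_equilibration([1, 2, 3, 4, 5], window=10)


class TestElements:
    @pytest.mark.parametrize("name,element", [
        ("OH2", "O"), ("HH11", "H"), ("CA", "C"), ("NE", "N"),
        ("CL", "Cl"), ("OD1", "O")])
    def test_infer_element(self, name, element):
        assert infer_element(name) == element

    def test_unknown_element_defaults_with_warning(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="channelgate.model_io"):
            assert vdw_radius_for_element("Xx") == 1.70


class TestChannelDefinition:
    def test_defaults_match_transmembrane_ranges(self):
        ch = ChannelDefinition()
        assert ch.helix_ranges == {"S1": (97, 120), "S2": (133, 157),
                                   "S3": (166, 188), "S4": (193, 214)}

    def test_overlapping_ranges_rejected(self):
        with pytest.raises(ValueError):
            ChannelDefinition(helix_ranges={"S1": (97, 140), "S2": (133, 157),
                                            "S3": (166, 188), "S4": (193, 214)})

    def test_inverted_membrane_rejected(self):
        with pytest.raises(ValueError):
            ChannelDefinition(membrane_z=(10.0, -10.0))
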