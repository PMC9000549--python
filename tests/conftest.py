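import numpy as np
import pytest

from channelgate.model_io import ChannelDefinition, Frame, Topology
from channelgate.synthetic import SyntheticSpec, generate_trajectory


@pytest.fixture(scope="session")
def default_channel() -> ChannelDefinition:
    return ChannelDefinition()


@pytest.fixture(scope="session")
def small_synthetic():
    """20-frame default-geometry trajectory with a 0.3 planted wire fraction."""
    spec = SyntheticSpec(n_frames=20, seed=7, wire_fraction=0.3)
    traj, manifest = generate_trajectory(spec)
    return spec, traj, manifest


def make_water_frame(positions, extra_atoms=()):
    """Frame of bare water oxygens (TIP3/OH2) at given positions, plus
    optional (name, resname, resnum, segment, xyz) protein atoms."""
    positions = np.asarray(positions, dtype=float)
    names = ["OH2"] * len(positions)
    resnames = ["TIP3"] * len(positions)
    resnums = list(range(1, len(positions) + 1))
    segments = ["WAT"] * len(positions)
    coords = list(positions)
    for name, resname, resnum, segment, xyz in extra_atoms:
        names.append(name)
        resnames.append(resname)
        resnums.append(resnum)
        segments.append(segment)
        coords.append(np.asarray(xyz, dtype=float))
    top = Topology(names, resnames, resnums, segments)
    return Frame(top, np.asarray(coords))


@pytest.fixture
def water_frame_factory():
    return make_water_frame
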