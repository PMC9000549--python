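"""Ground-truth synthetic trajectories for end-to-end pipeline testing.

Builds a four-helix transmembrane scaffold around a z-aligned pore and
animates it with *planted*, exactly-known facts:

* a water chain along the pore axis that spans the membrane in a chosen
  fraction of frames (one super-cutoff gap is inserted in the rest),
* scheduled rigid z-translations of individual helices,
* scheduled formation/breaking of an ideal bidentate Arg–Asp salt
  bridge (explicit hydrogens, linear N–H···O at 2.9 Å),
* an optional linear z-drift of a gate residue's sidechain.

Every planted fact is recorded in a :class:`GroundTruthManifest`, which
the analysis stages are expected to recover exactly — the generator is
the oracle for the whole pipeline.  Geometry is idealized, not physical:
no force field, no thermal motion.  All coordinates are rounded to
3 decimals so a PDB write/read round-trip is bitwise exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .model_io import (ChannelDefinition, Frame, Topology, Trajectory,
                       write_trajectory)

__all__ = [
    "SyntheticSpec",
    "ContactSchedule",
    "GroundTruthManifest",
    "generate_scaffold",
    "generate_trajectory",
    "generate_cylinder_frame",
    "verify_manifest",
    "load_synthetic_spec",
]

OO_CUTOFF = 3.4  # the wire criterion the planted geometry must straddle

# sidechain atom names planted for each gate residue
GATE_SIDECHAINS = {
    "ASP": ["CB", "CG", "OD1", "OD2"],
    "ARG": ["CB", "CG", "CD", "NE", "HE", "CZ", "NH1", "HH11", "HH12",
            "NH2", "HH21", "HH22"],
    "PHE": ["CB", "CG", "CD1", "CD2"],
    "LEU": ["CB", "CG", "CD1", "CD2"],
}


@dataclass
class ContactSchedule:
    """A planted donor–acceptor contact: ``basic`` residue hydrogen-bonds
    its guanidinium to the ``acidic`` residue's carboxylate exactly on
    ``on_frames``."""

    acidic: tuple[int, str]
    basic: tuple[int, str]
    on_frames: list[int]


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic trajectory.

    ``wire_fraction * n_frames`` must be integral so planted occupancy is
    exact.  ``wire_spacing`` must stay below the 3.4 Å adjacency cutoff
    and ``gap_size`` above it, so frame classification is unambiguous.
    """

    n_frames: int = 200
    seed: int = 0
    scaffold_radius: float = 8.0      # atom-center radius of the wall, Å
    scaffold_length: float = 36.0     # z-extent of the helices, Å
    atoms_per_ring: int = 3           # wall atoms per helix per ring
    n_rings: int = 19                 # rings per helix (one residue each)
    membrane_z: tuple[float, float] = (-18.0, 18.0)
    boundary_margin: float = 2.0
    wire_fraction: float = 0.3
    wire_spacing: float = 2.8
    gap_size: float = 4.0
    helix_schedules: dict[str, np.ndarray] = field(default_factory=dict)
    contact_schedule: list[ContactSchedule] = field(default_factory=list)
    gate_drift: tuple[tuple[int, str], float] | None = None
    decoy_waters: int = 0             # waters planted outside the cylinder

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        if self.scaffold_radius <= 0:
            raise ValueError("degenerate scaffold: radius must be positive")
        if not 0.0 <= self.wire_fraction <= 1.0:
            raise ValueError("wire_fraction must lie in [0, 1]")
        k = self.wire_fraction * self.n_frames
        if abs(k - round(k)) > 1e-9:
            raise ValueError(
                f"wire_fraction*n_frames = {k} is not an integer; planted "
                "occupancy would not be exact")
        if not self.wire_spacing < OO_CUTOFF < self.gap_size:
            raise ValueError(
                f"need wire_spacing < {OO_CUTOFF} < gap_size, got "
                f"{self.wire_spacing} / {self.gap_size}")
        if self.n_rings < 2:
            raise ValueError("need at least two rings")
        for label, sched in self.helix_schedules.items():
            arr = np.asarray(sched, dtype=np.float64)
            if arr.shape != (self.n_frames,):
                raise ValueError(
                    f"schedule for {label} must have one offset per frame")
            self.helix_schedules[label] = arr

    @property
    def n_wire_frames(self) -> int:
        return int(round(self.wire_fraction * self.n_frames))

    def channel(self) -> ChannelDefinition:
        return ChannelDefinition(membrane_z=self.membrane_z,
                                 boundary_margin=self.boundary_margin)


@dataclass
class GroundTruthManifest:
    """Every planted fact of one generated trajectory."""

    n_frames: int
    seed: int
    wire_frames: list[int]
    wire_fraction: float
    planted_helix_offsets: dict[str, list[float]]
    planted_contacts: list[ContactSchedule]
    pore_radius_by_z: dict[float, float]   # clean slices only
    gate_drift: tuple[tuple[int, str], float] | None
    coords_checksum: str = ""

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_frames": self.n_frames,
            "seed": self.seed,
            "wire_frames": self.wire_frames,
            "wire_fraction": self.wire_fraction,
            "planted_helix_offsets": {
                k: list(map(float, v))
                for k, v in self.planted_helix_offsets.items()},
            "planted_contacts": [
                {"acidic": list(c.acidic), "basic": list(c.basic),
                 "on_frames": c.on_frames}
                for c in self.planted_contacts],
            "pore_radius_by_z": {str(k): v
                                 for k, v in self.pore_radius_by_z.items()},
            "gate_drift": None if self.gate_drift is None else
            [list(self.gate_drift[0]), self.gate_drift[1]],
            "coords_checksum": self.coords_checksum,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthManifest":
        d = json.loads(Path(path).read_text())
        return cls(
            n_frames=d["n_frames"], seed=d["seed"],
            wire_frames=list(d["wire_frames"]),
            wire_fraction=d["wire_fraction"],
            planted_helix_offsets=d["planted_helix_offsets"],
            planted_contacts=[
                ContactSchedule(tuple(c["acidic"]), tuple(c["basic"]),
                                list(c["on_frames"]))
                for c in d["planted_contacts"]],
            pore_radius_by_z={float(k): v
                              for k, v in d["pore_radius_by_z"].items()},
            gate_drift=None if d["gate_drift"] is None else
            (tuple(d["gate_drift"][0]), d["gate_drift"][1]),
            coords_checksum=d.get("coords_checksum", ""),
        )


# ---------------------------------------------------------------------------
# scaffold
# ---------------------------------------------------------------------------

_HELIX_ORDER = ["S1", "S2", "S3", "S4"]
_QUADRANT_DEG = {"S1": 45.0, "S2": 135.0, "S3": 225.0, "S4": 315.0}


def _scaffold_arrays(spec: SyntheticSpec, channel: ChannelDefinition):
    """Topology arrays + base coordinates of the four-helix scaffold."""
    heavy_names = ["CA", "CB", "CG", "CD", "CE", "CZ"]
    if spec.atoms_per_ring > len(heavy_names):
        raise ValueError("atoms_per_ring too large for the name table")
    for label, (lo, hi) in channel.helix_ranges.items():
        if spec.n_rings > hi - lo + 1:
            raise ValueError(
                f"n_rings={spec.n_rings} exceeds helix {label} residue range")
    z_levels = np.linspace(-spec.scaffold_length / 2,
                           spec.scaffold_length / 2, spec.n_rings)
    # a residue is one ring position of one helix; gate residues get their
    # proper name and contribute only their CA to the wall (their remaining
    # heavy atoms come from the planted sidechain, avoiding name clashes)
    gate_names = {num: name for num, name in channel.gate_residues}
    names, resnames, resnums, segments, positions = [], [], [], [], []
    for label in _HELIX_ORDER:
        lo, _ = channel.helix_ranges[label]
        quad0 = _QUADRANT_DEG[label] - 45.0
        for k, z in enumerate(z_levels):
            resnum = lo + k
            n_wall = 1 if resnum in gate_names else spec.atoms_per_ring
            for j in range(n_wall):
                phi = np.radians(
                    quad0 + (j + 0.5) * 90.0 / spec.atoms_per_ring)
                names.append(heavy_names[j])
                resnames.append(gate_names.get(resnum, "ALA"))
                resnums.append(resnum)
                segments.append(label)
                positions.append([spec.scaffold_radius * np.cos(phi),
                                  spec.scaffold_radius * np.sin(phi), z])
    return (names, resnames, resnums, segments,
            np.asarray(positions, dtype=np.float64), z_levels)


def _helix_of_residue(channel: ChannelDefinition, resnum: int) -> str:
    for label, (lo, hi) in channel.helix_ranges.items():
        if lo <= resnum <= hi:
            return label
    raise ValueError(f"residue {resnum} is not inside any helix range")


def _gate_base_positions(spec: SyntheticSpec, channel: ChannelDefinition,
                         resnum: int, resname: str,
                         z_levels: np.ndarray) -> dict[str, np.ndarray]:
    """Idealized inward-pointing sidechain for one gate residue."""
    label = _helix_of_residue(channel, resnum)
    lo, _ = channel.helix_ranges[label]
    ring = resnum - lo
    if not 0 <= ring < spec.n_rings:
        raise ValueError(f"gate residue {resnum} outside scaffold rings")
    z = z_levels[ring]
    phi = np.radians(_QUADRANT_DEG[label])
    u = np.array([np.cos(phi), np.sin(phi), 0.0])   # outward radial
    t = np.array([-np.sin(phi), np.cos(phi), 0.0])  # tangential
    r_wall = spec.scaffold_radius
    pos: dict[str, np.ndarray] = {}
    if resname == "ASP":
        pos["CB"] = u * (r_wall - 1.4) + [0, 0, z]
        pos["CG"] = u * (r_wall - 2.6) + [0, 0, z]
        pos["OD1"] = u * (r_wall - 3.4) + [0, 0, z + 1.1]
        pos["OD2"] = u * (r_wall - 3.4) + [0, 0, z - 1.1]
    elif resname == "ARG":
        # chain folded along the wall; guanidinium gets repositioned by the
        # contact schedule, these are the "off" coordinates
        for i, nm in enumerate(GATE_SIDECHAINS["ARG"]):
            pos[nm] = u * (r_wall - 1.2) + t * (0.8 + 0.45 * i) + [0, 0, z]
    else:  # PHE / LEU four-atom hydrophobic blob
        pos["CB"] = u * (r_wall - 1.4) + [0, 0, z]
        pos["CG"] = u * (r_wall - 2.6) + [0, 0, z]
        pos["CD1"] = u * (r_wall - 3.3) + t * 0.7 + [0, 0, z + 0.4]
        pos["CD2"] = u * (r_wall - 3.3) - t * 0.7 + [0, 0, z - 0.4]
    return pos


def generate_scaffold(spec: SyntheticSpec,
                      channel: ChannelDefinition | None = None) -> Frame:
    """Static scaffold frame: four pseudo-helix walls plus gate sidechains."""
    channel = channel or spec.channel()
    names, resnames, resnums, segments, positions, z_levels = \
        _scaffold_arrays(spec, channel)
    names, resnames = list(names), list(resnames)
    resnums, segments = list(resnums), list(segments)
    positions = list(positions)
    for num, resname in channel.gate_residues:
        label = _helix_of_residue(channel, num)
        for nm, xyz in _gate_base_positions(spec, channel, num, resname,
                                            z_levels).items():
            names.append(nm)
            resnames.append(resname)
            resnums.append(num)
            segments.append(label)
            positions.append(np.asarray(xyz))
    top = Topology(names, resnames, resnums, segments)
    coords = np.round(np.asarray(positions, dtype=np.float64), 3)
    return Frame(top, coords, time=0.0)


def generate_cylinder_frame(center_radius: float = 2.85,
                            vdw_element: str = "C",
                            ring_spacing: float = 1.0,
                            n_per_ring: int = 24,
                            length: float = 30.0) -> Frame:
    """Dense ideal cylinder for analytic pore-radius checks.

    Atom centers sit exactly at ``center_radius`` from the z-axis, so the
    exact pore radius at every ring slice is ``center_radius − vdw``
    (1.15 Å at the defaults).  Residue numbers cycle through the default
    four-helix ranges so the default pore selection picks every atom.
    """
    if center_radius <= 0:
        raise ValueError("degenerate cylinder: radius must be positive")
    channel = ChannelDefinition()
    n_rings = int(round(length / ring_spacing)) + 1
    z_levels = -length / 2 + np.arange(n_rings) * ring_spacing
    names, resnames, resnums, segments, positions = [], [], [], [], []
    labels = list(channel.helix_ranges)
    for k, z in enumerate(z_levels):
        label = labels[k % 4]
        lo, hi = channel.helix_ranges[label]
        resnum = lo + (k // 4)
        if resnum > hi:
            raise ValueError("cylinder too long for the residue ranges")
        for j in range(n_per_ring):
            phi = 2 * np.pi * j / n_per_ring
            names.append("CA")
            resnames.append("ALA")
            resnums.append(resnum)
            segments.append(label)
            positions.append([center_radius * np.cos(phi),
                              center_radius * np.sin(phi), z])
    top = Topology(names, resnames, resnums, segments,
                   elements=[vdw_element] * len(names))
    return Frame(top, np.round(np.asarray(positions), 3))


# ---------------------------------------------------------------------------
# trajectory
# ---------------------------------------------------------------------------

def _water_chain(spec: SyntheticSpec) -> np.ndarray:
    """z-positions of the axial water chain (membrane-spanning, in-band)."""
    z_lo, z_hi = spec.membrane_z
    m = spec.boundary_margin
    b = z_lo - m + 0.1
    t = z_hi + m - 0.1
    n = int(np.ceil((t - b) / spec.wire_spacing)) + 1
    return np.linspace(b, t, n)


def generate_trajectory(spec: SyntheticSpec,
                        channel: ChannelDefinition | None = None
                        ) -> tuple[Trajectory, GroundTruthManifest]:
    """Emit the trajectory and the manifest of its planted ground truth.

    Wire frames are drawn by seeded sampling without replacement (exactly
    ``round(wire_fraction * n_frames)`` of them); non-wire frames get one
    ``gap_size`` break at a seeded interior chain position.  Helix
    offsets, contacts and gate drift are applied as scheduled.
    Deterministic: same spec and seed give a bitwise-identical result.
    """
    channel = channel or spec.channel()
    scaffold = generate_scaffold(spec, channel)
    top = scaffold.topology
    base = scaffold.positions

    rng = np.random.default_rng(spec.seed)
    wire_frames = sorted(
        int(i) for i in rng.choice(spec.n_frames, size=spec.n_wire_frames,
                                   replace=False))
    wire_set = set(wire_frames)

    chain_z = _water_chain(spec)
    z_lo, z_hi = spec.membrane_z
    mid = 0.5 * (chain_z[:-1] + chain_z[1:])
    interior_pairs = np.flatnonzero((mid > z_lo + 1.0) & (mid < z_hi - 1.0))
    if interior_pairs.size == 0:
        raise ValueError("water chain has no interior pair for the gap")
    gap_choice = {f: int(rng.choice(interior_pairs))
                  for f in range(spec.n_frames) if f not in wire_set}
    spacing = float(chain_z[1] - chain_z[0])
    gap_shift = spec.gap_size - spacing

    decoy_xy = None
    if spec.decoy_waters:
        r = channel.water_cylinder_radius + 2.0 \
            + rng.uniform(0.0, 4.0, size=spec.decoy_waters)
        phi = rng.uniform(0.0, 2 * np.pi, size=spec.decoy_waters)
        decoy_z = rng.uniform(z_lo, z_hi, size=spec.decoy_waters)
        decoy_xy = np.column_stack([r * np.cos(phi), r * np.sin(phi), decoy_z])

    # extend topology with waters
    n_chain = chain_z.size
    w_names = ["OH2"] * (n_chain + spec.decoy_waters)
    w_resnames = ["TIP3"] * (n_chain + spec.decoy_waters)
    w_resnums = list(range(1000, 1000 + n_chain + spec.decoy_waters))
    w_segments = ["WAT"] * (n_chain + spec.decoy_waters)
    full_top = Topology(
        list(top.names) + w_names, list(top.resnames) + w_resnames,
        list(top.resnums) + w_resnums, list(top.segments) + w_segments)

    helix_atoms = {label: np.flatnonzero(full_top.segments == label)
                   for label in channel.helix_ranges}
    offsets = {label: spec.helix_schedules.get(
        label, np.zeros(spec.n_frames)) for label in channel.helix_ranges}

    contact_atoms = []
    for sched in spec.contact_schedule:
        contact_atoms.append((sched, set(sched.on_frames)))

    drift_atoms = None
    if spec.gate_drift is not None:
        (res_num, res_name), total = spec.gate_drift
        mask = (full_top.resnums == res_num) \
            & np.isin(full_top.names, GATE_SIDECHAINS[res_name])
        drift_atoms = np.flatnonzero(mask)
        if drift_atoms.size == 0:
            raise ValueError(f"gate drift residue {res_num} not in scaffold")

    n_atoms = full_top.n_atoms
    coords = np.empty((spec.n_frames, n_atoms, 3))
    n_prot = top.n_atoms
    for f in range(spec.n_frames):
        pos = np.zeros((n_atoms, 3))
        pos[:n_prot] = base
        for label, idx in helix_atoms.items():
            dz = offsets[label][f]
            if dz:
                pos[idx, 2] += dz
        if drift_atoms is not None:
            (res_num, res_name), total = spec.gate_drift
            frac = f / (spec.n_frames - 1) if spec.n_frames > 1 else 0.0
            pos[drift_atoms, 2] += total * frac
        for sched, on in contact_atoms:
            _apply_contact(full_top, pos, sched, f in on)
        # waters
        wz = chain_z.copy()
        if f not in wire_set:
            g = gap_choice[f]
            wz[g + 1:] += gap_shift
        pos[n_prot:n_prot + n_chain, 2] = wz
        if decoy_xy is not None:
            pos[n_prot + n_chain:] = decoy_xy
        coords[f] = np.round(pos, 3)

    times = np.arange(spec.n_frames) * 0.1
    traj = Trajectory(full_top, coords, times)
    manifest = GroundTruthManifest(
        n_frames=spec.n_frames, seed=spec.seed, wire_frames=wire_frames,
        wire_fraction=spec.wire_fraction,
        planted_helix_offsets={k: list(map(float, v))
                               for k, v in offsets.items()},
        planted_contacts=list(spec.contact_schedule),
        pore_radius_by_z=_clean_pore_slices(spec, channel),
        gate_drift=spec.gate_drift,
        coords_checksum=_coords_checksum(coords),
    )
    return traj, manifest


def _coords_checksum(coords: np.ndarray) -> str:
    import hashlib
    return hashlib.sha1(np.ascontiguousarray(coords).tobytes()).hexdigest()


def _clean_pore_slices(spec: SyntheticSpec,
                       channel: ChannelDefinition) -> dict[float, float]:
    """Analytic wall radius at ring slices far from any gate sidechain."""
    z_levels = np.linspace(-spec.scaffold_length / 2,
                           spec.scaffold_length / 2, spec.n_rings)
    gate_z = []
    for num, _ in channel.gate_residues:
        label = _helix_of_residue(channel, num)
        lo, _ = channel.helix_ranges[label]
        gate_z.append(z_levels[num - lo])
    wall = spec.scaffold_radius - 1.70  # carbon wall atoms
    # a gate sidechain tip at radius ~(R - 3.4) shadows the axial clearance
    # of slices up to sqrt(R^2 - tip^2) away in z; stay clear of that
    tip = max(spec.scaffold_radius - 3.4, 0.0)
    margin = float(np.sqrt(spec.scaffold_radius ** 2 - tip ** 2)) + 0.5
    out = {}
    for z in z_levels:
        if all(abs(z - gz) > margin for gz in gate_z):
            out[float(np.round(z, 3))] = float(wall)
    return out


def _apply_contact(top: Topology, pos: np.ndarray, sched: ContactSchedule,
                   on: bool) -> None:
    """Place the basic residue's guanidinium against the acidic residue's
    carboxylate (ideal bidentate geometry) or park it away from it."""
    a_num, a_name = sched.acidic
    b_num, b_name = sched.basic
    if a_name != "ASP" or b_name != "ARG":
        raise ValueError("contact schedules support ASP acceptors and "
                         "ARG donors")

    def atom(num, nm):
        i = np.flatnonzero((top.resnums == num) & (top.names == nm))
        if i.size != 1:
            raise ValueError(f"atom {nm} of residue {num} not unique")
        return int(i[0])

    od1, od2 = pos[atom(a_num, "OD1")], pos[atom(a_num, "OD2")]
    center = 0.5 * (od1 + od2)
    # approach direction: horizontal, pointing away from the acid toward
    # the pore-tangent side (unit vector perpendicular to the radial)
    radial = center[:2] / np.linalg.norm(center[:2])
    t = np.array([-radial[1], radial[0], 0.0])
    shift = 0.0 if on else 6.0  # parked 6 Å further out when off
    nh1 = od1 + t * (2.9 + shift)
    nh2 = od2 + t * (2.9 + shift)
    placements = {
        "NH1": nh1, "HH11": od1 + t * (1.9 + shift), "HH12": nh1 + t * 1.0,
        "NH2": nh2, "HH21": od2 + t * (1.9 + shift), "HH22": nh2 + t * 1.0,
        "CZ": 0.5 * (nh1 + nh2) + t * 1.2,
        "NE": 0.5 * (nh1 + nh2) + t * 2.4,
        "HE": 0.5 * (nh1 + nh2) + t * 3.2,
        "CD": 0.5 * (nh1 + nh2) + t * 3.6,
        "CG": 0.5 * (nh1 + nh2) + t * 5.0,
        "CB": 0.5 * (nh1 + nh2) + t * 6.4,
    }
    for nm, xyz in placements.items():
        pos[atom(b_num, nm)] = xyz


# ---------------------------------------------------------------------------
# self-check
# ---------------------------------------------------------------------------

def verify_manifest(traj: Trajectory, manifest: GroundTruthManifest,
                    channel: ChannelDefinition | None = None,
                    wire_criteria=None, hbond_criteria=None,
                    check_pore: bool = True) -> dict:
    """Re-run every analysis stage and diff against the planted manifest.

    Returns ``{"disagreements": [...], "checks": {...}}``; an untouched
    trajectory/manifest pair yields an empty disagreement list.
    """
    from .hydration import WaterWireCriteria, occupancy_series
    from .interactions import HBondCriteria, hbond_count_series
    from .kinematics import helix_z_series
    from .pore import pore_profile

    channel = channel or ChannelDefinition()
    wire_criteria = wire_criteria or WaterWireCriteria()
    hbond_criteria = hbond_criteria or HBondCriteria()
    problems: list[str] = []
    checks: dict[str, bool] = {}

    # water wire
    res = occupancy_series(traj, channel, wire_criteria)
    measured = [int(i) for i in res.frame_indices[res.per_frame]]
    if measured != manifest.wire_frames:
        extra = sorted(set(measured) - set(manifest.wire_frames))
        missing = sorted(set(manifest.wire_frames) - set(measured))
        problems.append(
            f"wire frames differ: unexpected {extra}, missed {missing}")
    checks["wire_frames"] = measured == manifest.wire_frames

    # helix offsets (relative, re-zeroed — the observable form)
    series = helix_z_series(traj, channel, rezero=True)
    planted = {k: np.asarray(v)
               for k, v in manifest.planted_helix_offsets.items()}
    pooled = np.mean([planted[k] for k in series], axis=0)
    ok = True
    for label, s in series.items():
        expected = (planted[label] - pooled)
        expected = expected - expected[0]
        if np.max(np.abs(s.z_values - expected)) > 2e-3:
            ok = False
            problems.append(f"helix {label} offsets deviate from schedule")
    checks["helix_offsets"] = ok

    # contacts
    ok = True
    for sched in manifest.planted_contacts:
        cs = hbond_count_series(traj, sched.acidic, sched.basic,
                                hbond_criteria)
        on = np.isin(cs.frame_indices, sched.on_frames)
        bad_on = cs.frame_indices[on & (cs.counts < 1)]
        bad_off = cs.frame_indices[~on & (cs.counts > 0)]
        if bad_on.size or bad_off.size:
            ok = False
            problems.append(
                f"contact {sched.acidic}-{sched.basic}: missing on frames "
                f"{bad_on.tolist()}, spurious on frames {bad_off.tolist()}")
    checks["contacts"] = ok

    # pore wall at clean slices (frame 0)
    if check_pore and manifest.pore_radius_by_z:
        prof = pore_profile(traj.frame(0), channel)
        ok = True
        for z, expected in manifest.pore_radius_by_z.items():
            k = int(np.argmin(np.abs(prof.z_grid - z)))
            if abs(prof.z_grid[k] - z) < 1e-6 and \
                    abs(prof.radii[k] - expected) > 0.02:
                ok = False
                problems.append(
                    f"pore radius at z={z}: {prof.radii[k]:.3f} vs "
                    f"planted {expected:.3f}")
        checks["pore"] = ok

    return {"disagreements": problems, "checks": checks}


# ---------------------------------------------------------------------------
# YAML spec + emission
# ---------------------------------------------------------------------------

def load_synthetic_spec(source: str | Path | Mapping) -> SyntheticSpec:
    """Build a :class:`SyntheticSpec` from YAML (file path or mapping).

    Helix schedules may be literal per-frame lists, ``{linear: dz}``
    ramps, or ``{step: {at: frame, dz: v}}``.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            source = yaml.safe_load(fh)
    d = dict(source)
    n = int(d.get("n_frames", 200))
    schedules = {}
    for label, sched in (d.pop("helix_schedules", None) or {}).items():
        if isinstance(sched, Mapping):
            if "linear" in sched:
                schedules[label] = np.linspace(0.0, float(sched["linear"]), n)
            elif "step" in sched:
                arr = np.zeros(n)
                arr[int(sched["step"]["at"]):] = float(sched["step"]["dz"])
                schedules[label] = arr
            else:
                raise ValueError(f"unknown schedule form for {label}")
        else:
            schedules[label] = np.asarray(sched, dtype=np.float64)
    contacts = []
    for c in d.pop("contact_schedule", None) or []:
        on = []
        for span in c["on_frames"]:
            if isinstance(span, Sequence) and not isinstance(span, str):
                on.extend(range(int(span[0]), int(span[1]) + 1))
            else:
                on.append(int(span))
        contacts.append(ContactSchedule(
            acidic=(int(c["acidic"][0]), str(c["acidic"][1])),
            basic=(int(c["basic"][0]), str(c["basic"][1])),
            on_frames=sorted(set(on))))
    gate = d.pop("gate_drift", None)
    if gate is not None:
        gate = ((int(gate["residue"][0]), str(gate["residue"][1])),
                float(gate["dz"]))
    known = {f.name for f in SyntheticSpec.__dataclass_fields__.values()}
    kwargs = {k: v for k, v in d.items() if k in known}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown synthetic spec keys: {sorted(unknown)}")
    if "membrane_z" in kwargs:
        kwargs["membrane_z"] = tuple(float(v) for v in kwargs["membrane_z"])
    return SyntheticSpec(helix_schedules=schedules,
                         contact_schedule=contacts, gate_drift=gate,
                         **kwargs)


def emit(spec: SyntheticSpec, outdir: str | Path) -> tuple[Path, Path]:
    """Generate and write ``trajectory.pdb`` + ``manifest.json``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    traj, manifest = generate_trajectory(spec)
    pdb = outdir / "trajectory.pdb"
    mjs = outdir / "manifest.json"
    write_trajectory(traj, pdb)
    manifest.to_json(mjs)
    return pdb, mjs
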