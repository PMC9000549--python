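"""Domain types, trajectory I/O, configuration and small physics helpers.

The in-memory model is a :class:`Trajectory`: a static :class:`Topology`
(atom names, residues, segments, van der Waals radii) shared by all frames,
plus a ``(n_frames, n_atoms, 3)`` coordinate array in Å and per-frame time
stamps in ns.  Two on-disk dialects are supported:

``pdb_multimodel``
    Standard multi-model PDB (``MODEL``/``ENDMDL`` with fixed-column
    ``ATOM``/``HETATM`` records, CHARMM-style segment ids in columns 73-76).
    Reading is delegated to MDAnalysis; writing uses a fixed-width formatter
    so output is byte-reproducible.

``frame_csv``
    A plain-text per-frame coordinate table with header
    ``frame,index,name,resname,resnum,segment,x,y,z``.

Coordinates are Å throughout and *z* increases toward the extracellular
side.  PDB coordinates carry three decimals, so all readers round to
3 decimals: a write/read round-trip is then bitwise exact.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "Topology",
    "Frame",
    "Trajectory",
    "ChannelDefinition",
    "FieldSpec",
    "ParseError",
    "TopologyError",
    "read_trajectory",
    "write_trajectory",
    "field_magnitude",
    "detect_equilibration",
    "vdw_radius_for_element",
    "infer_element",
    "select_atoms",
    "water_oxygen_indices",
    "resolve_residue",
    "load_channel_definition",
]

# Bondi-type van der Waals radii (Å).  Unknown elements fall back to
# carbon's 1.70 Å with a logged warning.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "NA": 2.27, "K": 2.75, "MG": 1.73, "CA": 2.31, "ZN": 1.39,
}
DEFAULT_VDW = 1.70

WATER_RESNAMES = {"TIP3", "TIP3P", "HOH", "WAT", "SOL", "SPC"}

# Backbone atom names (CHARMM/PDB conventions) excluded from sidechain
# selections.  OT1/OT2 are C-terminal carboxylate oxygens.
BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT", "OT1", "OT2", "HN", "HA", "H"}

_TWO_LETTER_ELEMENTS = {"CL", "BR", "NA", "MG", "ZN", "FE", "MN", "CU"}

_warned_elements: set[str] = set()


class ParseError(ValueError):
    """A trajectory file record could not be parsed."""


class TopologyError(ValueError):
    """Frames of one trajectory disagree on atom count or identity."""


# ---------------------------------------------------------------------------
# element / radius helpers
# ---------------------------------------------------------------------------

def infer_element(atom_name: str) -> str:
    """Guess the element symbol from a PDB-style atom name.

    Digits and primes are stripped; a leading two-letter match against
    known two-letter elements (Cl, Na, ...) wins, otherwise the first
    alphabetic character is used.  Water oxygens named ``OH2``/``OW`` and
    hydrogens named ``HH11`` etc. resolve correctly under this rule.
    """
    stripped = "".join(c for c in atom_name if c.isalpha()).upper()
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    if stripped[:2] in _TWO_LETTER_ELEMENTS:
        return stripped[:2].capitalize()
    return stripped[0]


def vdw_radius_for_element(element: str) -> float:
    """Bondi-type vdW radius in Å; unknown elements default to 1.70 Å."""
    key = element.upper()
    if key in VDW_RADII:
        return VDW_RADII[key]
    if key not in _warned_elements:
        logger.warning("unknown element %r: using default vdW radius %.2f Å",
                       element, DEFAULT_VDW)
        _warned_elements.add(key)
    return DEFAULT_VDW


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomRecord:
    """One atom of one frame (coordinates in Å)."""

    index: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    segment: str
    position: np.ndarray
    vdw_radius: float

    def __post_init__(self) -> None:
        if self.vdw_radius <= 0:
            raise ValueError("vdw_radius must be positive")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("position must be finite")


class Topology:
    """Static per-atom metadata shared by every frame of a trajectory."""

    def __init__(self, names, resnames, resnums, segments, elements=None,
                 vdw=None):
        self.names = np.asarray(names, dtype=object)
        self.resnames = np.asarray(resnames, dtype=object)
        self.resnums = np.asarray(resnums, dtype=np.int64)
        self.segments = np.asarray(segments, dtype=object)
        n = len(self.names)
        if not (len(self.resnames) == len(self.resnums)
                == len(self.segments) == n):
            raise TopologyError("topology arrays must have equal length")
        if elements is None:
            elements = [infer_element(nm) for nm in self.names]
        self.elements = np.asarray(elements, dtype=object)
        if vdw is None:
            vdw = [vdw_radius_for_element(e) for e in self.elements]
        self.vdw = np.asarray(vdw, dtype=np.float64)

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def checksum(self) -> str:
        h = hashlib.sha1()
        for arr in (self.names, self.resnames, self.resnums.astype(str),
                    self.segments, self.elements):
            h.update("\x1f".join(map(str, arr)).encode())
            h.update(b"\x1e")
        return h.hexdigest()

    def __eq__(self, other) -> bool:
        return isinstance(other, Topology) and self.checksum() == other.checksum()


class Frame:
    """A single trajectory frame: topology view + ``(n_atoms, 3)`` coordinates."""

    def __init__(self, topology: Topology, positions: np.ndarray,
                 time: float = 0.0, box: np.ndarray | None = None):
        positions = np.asarray(positions, dtype=np.float64)
        if positions.shape != (topology.n_atoms, 3):
            raise TopologyError(
                f"positions shape {positions.shape} does not match "
                f"{topology.n_atoms} topology atoms")
        self.topology = topology
        self.positions = positions
        self.time = float(time)
        self.box = None if box is None else np.asarray(box, dtype=np.float64)

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    @property
    def atoms(self) -> list[AtomRecord]:
        t = self.topology
        return [AtomRecord(i, t.names[i], t.elements[i], t.resnames[i],
                           int(t.resnums[i]), t.segments[i],
                           self.positions[i], float(t.vdw[i]))
                for i in range(t.n_atoms)]


class Trajectory:
    """An ordered sequence of frames over one topology."""

    def __init__(self, topology: Topology, coords: np.ndarray,
                 times: Sequence[float] | None = None):
        coords = np.asarray(coords, dtype=np.float64)
        if coords.ndim != 3 or coords.shape[1:] != (topology.n_atoms, 3):
            raise TopologyError(
                f"coords shape {coords.shape} incompatible with "
                f"{topology.n_atoms}-atom topology")
        self.topology = topology
        self.coords = coords
        if times is None:
            times = np.arange(len(coords), dtype=np.float64) * 0.1
        self.times = np.asarray(times, dtype=np.float64)
        if len(self.times) != len(coords):
            raise TopologyError("one time stamp per frame required")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    def __len__(self) -> int:
        return self.n_frames

    def frame(self, i: int) -> Frame:
        return Frame(self.topology, self.coords[i], self.times[i])

    @property
    def frames(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    @property
    def topology_checksum(self) -> str:
        return self.topology.checksum()

    @classmethod
    def from_frames(cls, frames: Sequence[Frame]) -> "Trajectory":
        if not frames:
            raise ValueError("cannot build a trajectory from zero frames")
        top = frames[0].topology
        for k, f in enumerate(frames[1:], start=2):
            if f.topology != top:
                raise TopologyError(f"frame {k} disagrees with frame 1 topology")
        coords = np.stack([f.positions for f in frames])
        times = [f.time for f in frames]
        return cls(top, coords, times)


@dataclass
class ChannelDefinition:
    """Geometry of the four-helix channel used by every analysis stage.

    ``membrane_z`` is the membrane slab (z_lo, z_hi) in Å; waters are
    selected inside a cylinder of ``water_cylinder_radius`` about the pore
    axis, extended by ``boundary_margin`` beyond the slab.
    """

    helix_ranges: dict[str, tuple[int, int]] = field(default_factory=lambda: {
        "S1": (97, 120), "S2": (133, 157), "S3": (166, 188), "S4": (193, 214),
    })
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    membrane_z: tuple[float, float] = (-18.0, 18.0)
    water_cylinder_radius: float = 8.0
    boundary_margin: float = 2.0
    gate_residues: list[tuple[int, str]] = field(default_factory=lambda: [
        (108, "ASP"), (143, "LEU"), (146, "PHE"), (178, "PHE"), (204, "ARG"),
    ])

    def __post_init__(self) -> None:
        z_lo, z_hi = self.membrane_z
        if not z_lo < z_hi:
            raise ValueError("membrane_z must satisfy z_lo < z_hi")
        if self.water_cylinder_radius <= 0:
            raise ValueError("water_cylinder_radius must be positive")
        spans = sorted(self.helix_ranges.values())
        for (a, b), (c, d) in zip(spans, spans[1:]):
            if c <= b:
                raise ValueError("helix residue ranges must not overlap")

    def helix_atom_indices(self, topology: Topology,
                           mode: str | None = "all_heavy"
                           ) -> dict[str, np.ndarray]:
        """Atom indices per helix under the given selection mode.

        Water residues are excluded even when their residue numbers fall
        inside a helix range.
        """
        water = np.isin(topology.resnames, list(WATER_RESNAMES))
        out = {}
        for label, (lo, hi) in self.helix_ranges.items():
            idx = select_atoms(topology, resnum_range=(lo, hi), mode=mode)
            idx = idx[~water[idx]]
            if idx.size == 0:
                raise ValueError(f"helix {label} (residues {lo}-{hi}) "
                                 f"selects no atoms under mode {mode!r}")
            out[label] = idx
        return out


@dataclass(frozen=True)
class FieldSpec:
    """A uniform transmembrane electric field E = V / z."""

    potential_mV: float
    thickness_A: float = 36.0
    magnitude_mV_per_A: float = field(init=False)

    def __post_init__(self) -> None:
        if self.thickness_A <= 0:
            raise ValueError("membrane thickness must be positive")
        object.__setattr__(self, "magnitude_mV_per_A",
                           self.potential_mV / self.thickness_A)


def field_magnitude(potential_mV: float, thickness_A: float = 36.0) -> FieldSpec:
    """Field magnitude E = V/z in mV/Å for a membrane of given thickness."""
    return FieldSpec(potential_mV=potential_mV, thickness_A=thickness_A)


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

def select_atoms(topology: Topology, *, resnum: int | None = None,
                 resnum_range: tuple[int, int] | None = None,
                 resname: str | None = None, segment: str | None = None,
                 names: Sequence[str] | None = None,
                 mode: str | None = None) -> np.ndarray:
    """Return sorted atom indices matching all given filters.

    ``mode`` is one of ``alpha_carbon`` (name CA), ``sidechain_heavy``
    (non-hydrogen, non-backbone) or ``all_heavy`` (non-hydrogen).
    """
    mask = np.ones(topology.n_atoms, dtype=bool)
    if resnum is not None:
        mask &= topology.resnums == resnum
    if resnum_range is not None:
        lo, hi = resnum_range
        mask &= (topology.resnums >= lo) & (topology.resnums <= hi)
    if resname is not None:
        mask &= topology.resnames == resname
    if segment is not None:
        mask &= topology.segments == segment
    if names is not None:
        mask &= np.isin(topology.names, list(names))
    if mode is not None:
        if mode == "alpha_carbon":
            mask &= topology.names == "CA"
        elif mode == "sidechain_heavy":
            mask &= topology.elements != "H"
            mask &= ~np.isin(topology.names, list(BACKBONE_NAMES))
        elif mode == "all_heavy":
            mask &= topology.elements != "H"
        else:
            raise ValueError(f"unknown selection mode {mode!r}")
    return np.flatnonzero(mask)


def water_oxygen_indices(topology: Topology) -> np.ndarray:
    """Indices of water oxygen atoms (residues TIP3/TIP3P/HOH/WAT...)."""
    mask = np.isin(topology.resnames, list(WATER_RESNAMES))
    mask &= topology.elements == "O"
    return np.flatnonzero(mask)


def resolve_residue(topology: Topology,
                    residue: int | tuple[int, str]) -> np.ndarray:
    """Atom indices of a residue given as number or (number, name)."""
    if isinstance(residue, tuple):
        num, name = residue
        idx = select_atoms(topology, resnum=int(num))
        if idx.size and not np.all(topology.resnames[idx] == name):
            found = sorted(set(topology.resnames[idx]))
            raise ValueError(
                f"residue {num} has name(s) {found}, expected {name!r}")
    else:
        num = int(residue)
        idx = select_atoms(topology, resnum=num)
    if idx.size == 0:
        raise ValueError(f"residue {residue!r} selects no atoms")
    return idx


# ---------------------------------------------------------------------------
# trajectory I/O
# ---------------------------------------------------------------------------

CSV_COLUMNS = ["frame", "index", "name", "resname", "resnum", "segment",
               "x", "y", "z"]


def _prescan_pdb(path: Path) -> list[int]:
    """Validate ATOM/HETATM records and return per-model atom counts.

    Raises :class:`ParseError` naming the offending line, and
    :class:`TopologyError` if models disagree in atom count.
    """
    counts: list[int] = []
    current = 0
    in_model = False
    saw_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                if in_model:
                    counts.append(current)
                in_model, saw_model, current = True, True, 0
            elif rec == "ENDMDL":
                counts.append(current)
                in_model, current = False, 0
            elif rec in ("ATOM  ", "HETATM"):
                if len(line.rstrip("\n")) < 54:
                    raise ParseError(
                        f"{path}:{lineno}: truncated atom record")
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: unparseable coordinates") from exc
                current += 1
    if in_model or (not saw_model and current):
        counts.append(current)
    if not counts or sum(counts) == 0:
        raise ParseError(f"{path}: no atom records found")
    if len(set(counts)) > 1:
        raise TopologyError(
            f"{path}: models have inconsistent atom counts {sorted(set(counts))}")
    return counts


def _read_pdb(path: Path, dt_ns: float) -> Trajectory:
    import MDAnalysis as mda

    _prescan_pdb(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        names = [str(n) for n in u.atoms.names]
        resnames = [str(r) for r in u.atoms.resnames]
        resnums = [int(r) for r in u.atoms.resids]
        try:
            segments = [str(s) for s in u.atoms.segids]
        except mda.exceptions.NoDataError:  # pragma: no cover
            segments = [""] * len(names)
        try:
            elements = [str(e).capitalize() for e in u.atoms.elements]
            if any(not e for e in elements):
                raise ValueError
        except (mda.exceptions.NoDataError, ValueError):
            elements = [infer_element(n) for n in names]
        top = Topology(names, resnames, resnums, segments, elements)
        coords = np.stack([
            np.round(ts.positions.astype(np.float64), 3)
            for ts in u.trajectory
        ])
    times = np.arange(len(coords)) * dt_ns
    return Trajectory(top, coords, times)


def _read_frame_csv(path: Path, dt_ns: float) -> Trajectory:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    frames = sorted(df["frame"].unique())
    groups = [df[df["frame"] == f].sort_values("index") for f in frames]
    ref = groups[0]
    top = Topology(ref["name"].astype(str).tolist(),
                   ref["resname"].astype(str).tolist(),
                   ref["resnum"].astype(int).tolist(),
                   ref["segment"].astype(str).tolist())
    coords = []
    for f, g in zip(frames, groups):
        if len(g) != len(ref) or not np.array_equal(
                g["index"].to_numpy(), ref["index"].to_numpy()):
            raise TopologyError(f"{path}: frame {f} atom set differs from frame 0")
        coords.append(np.round(g[["x", "y", "z"]].to_numpy(np.float64), 3))
    return Trajectory(top, np.stack(coords), np.arange(len(coords)) * dt_ns)


def read_trajectory(path: str | Path, format: str = "pdb_multimodel",
                    dt_ns: float = 0.1) -> Trajectory:
    """Read a trajectory in the ``pdb_multimodel`` or ``frame_csv`` dialect.

    Neither dialect carries time stamps, so frame times are assigned as
    ``frame_index * dt_ns``.  Coordinates are rounded to 3 decimals (PDB
    precision) so write/read round-trips are exact.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "pdb_multimodel":
        return _read_pdb(path, dt_ns)
    if format == "frame_csv":
        return _read_frame_csv(path, dt_ns)
    raise ValueError(f"unknown trajectory format {format!r}")


def _pdb_atom_line(serial: int, name: str, resname: str, resnum: int,
                   xyz: np.ndarray, segment: str, element: str) -> str:
    nm = name if len(name) >= 4 else " " + name
    chain = (segment[:1] or "A") if segment else "A"
    return (f"ATOM  {serial % 100000:>5d} {nm:<4s} {resname:<4s}{chain:1s}"
            f"{resnum % 10000:>4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"      {segment:<4s}{element.upper():>2s}")


def write_trajectory(traj: Trajectory, path: str | Path,
                     format: str = "pdb_multimodel") -> None:
    """Write a trajectory; inverse of :func:`read_trajectory` to PDB precision."""
    if traj.n_frames == 0:
        raise ValueError("cannot write an empty trajectory")
    path = Path(path)
    if format == "pdb_multimodel":
        top = traj.topology
        with open(path, "w") as fh:
            for fidx in range(traj.n_frames):
                fh.write(f"MODEL     {fidx + 1:>4d}\n")
                pos = traj.coords[fidx]
                for i in range(top.n_atoms):
                    fh.write(_pdb_atom_line(
                        i + 1, top.names[i], top.resnames[i],
                        int(top.resnums[i]), pos[i], top.segments[i],
                        top.elements[i]) + "\n")
                fh.write("ENDMDL\n")
            fh.write("END\n")
    elif format == "frame_csv":
        top = traj.topology
        rows = []
        for fidx in range(traj.n_frames):
            pos = traj.coords[fidx]
            for i in range(top.n_atoms):
                rows.append((fidx, i, top.names[i], top.resnames[i],
                             int(top.resnums[i]), top.segments[i],
                             f"{pos[i, 0]:.3f}", f"{pos[i, 1]:.3f}",
                             f"{pos[i, 2]:.3f}"))
        pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown trajectory format {format!r}")


# ---------------------------------------------------------------------------
# RMSD-plateau equilibration detection
# ---------------------------------------------------------------------------

def detect_equilibration(rmsd_series: Sequence[float], window: int = 10,
                         slope_tol: float = 1e-3) -> int:
    """First frame index at which the RMSD series has plateaued.

    Slides a length-``window`` least-squares line along the series and
    returns the start index of the first window whose fitted |slope| is
    below ``slope_tol`` (Å/frame).  A constant series yields 0.  If no
    window qualifies the latest window start is returned with a warning.
    """
    y = np.asarray(rmsd_series, dtype=np.float64)
    if window < 2:
        raise ValueError("window must be at least 2")
    if y.size < 2 * window:
        raise ValueError(
            f"series of length {y.size} too short for window {window} "
            f"(need at least {2 * window})")
    x = np.arange(window, dtype=np.float64)
    x = x - x.mean()
    denom = float(x @ x)
    for start in range(y.size - window + 1):
        seg = y[start:start + window]
        slope = float(x @ (seg - seg.mean())) / denom
        if abs(slope) < slope_tol:
            return start
    warnings.warn("no RMSD plateau found; returning latest window start")
    return y.size - window


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def load_channel_definition(source: str | Path | Mapping) -> ChannelDefinition:
    """Build a :class:`ChannelDefinition` from a YAML/JSON file or mapping."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            source = yaml.safe_load(fh)
    if source is None:
        return ChannelDefinition()
    kwargs: dict = {}
    if "helix_ranges" in source:
        kwargs["helix_ranges"] = {
            str(k): (int(v[0]), int(v[1]))
            for k, v in source["helix_ranges"].items()}
    for key in ("axis", "membrane_z"):
        if key in source:
            kwargs[key] = tuple(float(v) for v in source[key])
    for key in ("water_cylinder_radius", "boundary_margin"):
        if key in source:
            kwargs[key] = float(source[key])
    if "gate_residues" in source:
        kwargs["gate_residues"] = [
            (int(num), str(name)) for num, name in source["gate_residues"]]
    return ChannelDefinition(**kwargs)


def channel_definition_to_dict(channel: ChannelDefinition) -> dict:
    """Inverse of :func:`load_channel_definition` (for YAML round-trips)."""
    return {
        "helix_ranges": {k: list(v) for k, v in channel.helix_ranges.items()},
        "axis": list(channel.axis),
        "membrane_z": list(channel.membrane_z),
        "water_cylinder_radius": channel.water_cylinder_radius,
        "boundary_margin": channel.boundary_margin,
        "gate_residues": [list(g) for g in channel.gate_residues],
    }
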