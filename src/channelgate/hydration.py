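"""Continuous water-wire detection and occupancy statistics.

A frame carries a *continuous water-wire* when the water oxygens inside
the channel form a chain connecting the extracellular and intracellular
sides with every adjacent O–O distance strictly below the cutoff
(default 3.4 Å).  Such a wire is the structural prerequisite for Grotthuss
proton relay across the membrane; the fraction of frames carrying one
(the occupancy) is the headline readout of voltage gating.

Geometry conventions: "in the channel" means inside a cylinder of
``water_cylinder_radius`` about the pore axis through the four-helix
centroid, with z inside the membrane slab extended by ``boundary_margin``;
a component spans the membrane when it holds at least one oxygen with
z ≥ z_hi and one with z ≤ z_lo.  Only water oxygens participate —
hydrogens and protein atoms never bridge a wire.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .model_io import (ChannelDefinition, Frame, Trajectory,
                       water_oxygen_indices)

__all__ = [
    "WaterWireCriteria",
    "WaterWireResult",
    "select_channel_waters",
    "water_adjacency",
    "classify_frame",
    "occupancy_series",
]


@dataclass(frozen=True)
class WaterWireCriteria:
    """Adjacency cutoff for the wire graph (strict O–O < ``oo_cutoff`` Å)."""

    oo_cutoff: float = 3.4

    def __post_init__(self) -> None:
        if self.oo_cutoff <= 0:
            raise ValueError("oo_cutoff must be positive")


@dataclass
class WaterWireResult:
    """Per-frame wire classification plus summary statistics.

    ``occupancy`` is the mean of ``per_frame``; ``run_lengths`` are the
    lengths of maximal runs of consecutive continuous frames (wire
    lifetimes in frames).
    """

    per_frame: np.ndarray
    spanning_paths: list[list[int]]
    occupancy: float
    run_lengths: list[int]
    frame_indices: np.ndarray = field(default=None)
    times: np.ndarray = field(default=None)


def _pore_axis_center(frame: Frame, channel: ChannelDefinition) -> np.ndarray:
    """In-plane (x, y) point the pore axis passes through: the centroid of
    all heavy atoms of the four helix ranges."""
    helix = channel.helix_atom_indices(frame.topology, mode="all_heavy")
    idx = np.concatenate(list(helix.values()))
    return frame.positions[idx].mean(axis=0)


def select_channel_waters(frame: Frame,
                          channel: ChannelDefinition) -> np.ndarray:
    """Water oxygens inside the channel cylinder (sorted atom indices).

    The cylinder has radius ``channel.water_cylinder_radius`` about the
    z-axis through the four-helix centroid; its z-extent is the membrane
    slab widened by ``boundary_margin`` on each side.  Returns an empty
    array when the frame has no waters in the volume.
    """
    ox = water_oxygen_indices(frame.topology)
    if ox.size == 0:
        return ox
    center = _pore_axis_center(frame, channel)
    pos = frame.positions[ox]
    r2 = (pos[:, 0] - center[0]) ** 2 + (pos[:, 1] - center[1]) ** 2
    z_lo, z_hi = channel.membrane_z
    m = channel.boundary_margin
    keep = (r2 <= channel.water_cylinder_radius ** 2) \
        & (pos[:, 2] >= z_lo - m) & (pos[:, 2] <= z_hi + m)
    return ox[keep]


def water_adjacency(oxygens: np.ndarray, frame: Frame,
                    criteria: WaterWireCriteria = WaterWireCriteria()
                    ) -> set[tuple[int, int]]:
    """Undirected wire-graph edges: O–O pairs strictly closer than cutoff.

    The inequality is strict, so a pair at exactly the cutoff distance is
    *not* adjacent.
    """
    oxygens = np.asarray(sorted(oxygens), dtype=np.int64)
    if oxygens.size < 2:
        return set()
    pos = frame.positions[oxygens]
    tree = cKDTree(pos)
    pairs = tree.query_pairs(r=criteria.oo_cutoff, output_type="ndarray")
    edges = set()
    for i, j in pairs:
        # query_pairs is inclusive at r; enforce the strict "<"
        if np.linalg.norm(pos[i] - pos[j]) < criteria.oo_cutoff:
            a, b = int(oxygens[i]), int(oxygens[j])
            edges.add((min(a, b), max(a, b)))
    return edges


def _lexicographic_shortest_path(graph: nx.Graph, sources: set[int],
                                 targets: set[int]) -> list[int]:
    """Fewest-hop path from a source to a target; ties broken toward the
    smallest atom-index sequence."""
    # hop distance from every node to the nearest target
    dist = {}
    frontier = sorted(targets)
    for t in frontier:
        dist[t] = 0
    d = 0
    while frontier:
        nxt = []
        for node in frontier:
            for nb in graph.neighbors(node):
                if nb not in dist:
                    dist[nb] = d + 1
                    nxt.append(nb)
        frontier = sorted(nxt)
        d += 1
    reach = [s for s in sources if s in dist]
    if not reach:
        return []
    best = min(dist[s] for s in reach)
    start = min(s for s in reach if dist[s] == best)
    path = [start]
    node = start
    while dist[node] > 0:
        node = min(nb for nb in graph.neighbors(node)
                   if nb in dist and dist[nb] == dist[node] - 1)
        path.append(node)
    return path


def classify_frame(frame: Frame, channel: ChannelDefinition,
                   criteria: WaterWireCriteria = WaterWireCriteria()
                   ) -> tuple[bool, list[int]]:
    """Classify one frame as continuous/discontinuous and report the wire.

    Continuous iff the adjacency graph over channel waters has a connected
    component containing both an oxygen with z ≥ z_hi (extracellular) and
    one with z ≤ z_lo (intracellular).  The returned path is the
    fewest-hop chain between such boundary waters (ties broken toward the
    smallest atom-index sequence); it is empty when discontinuous.
    """
    ox = select_channel_waters(frame, channel)
    if ox.size == 0:
        return False, []
    z = frame.positions[ox][:, 2]
    z_lo, z_hi = channel.membrane_z
    top = {int(i) for i, zi in zip(ox, z) if zi >= z_hi}
    bottom = {int(i) for i, zi in zip(ox, z) if zi <= z_lo}
    if not top or not bottom:
        return False, []
    g = nx.Graph()
    g.add_nodes_from(int(i) for i in ox)
    g.add_edges_from(water_adjacency(ox, frame, criteria))
    for comp in nx.connected_components(g):
        if comp & top and comp & bottom:
            path = _lexicographic_shortest_path(g.subgraph(comp),
                                                bottom & comp, top & comp)
            return True, path
    return False, []


def _run_lengths(flags: np.ndarray) -> list[int]:
    runs, current = [], 0
    for f in flags:
        if f:
            current += 1
        elif current:
            runs.append(current)
            current = 0
    if current:
        runs.append(current)
    return runs


def occupancy_series(traj: Trajectory, channel: ChannelDefinition,
                     criteria: WaterWireCriteria = WaterWireCriteria(),
                     equil_start: int = 0) -> WaterWireResult:
    """Water-wire classification for every frame at or after ``equil_start``.

    ``occupancy`` is the fraction of analyzed frames carrying a continuous
    wire; ``run_lengths`` collect wire lifetimes in frames.
    """
    if not 0 <= equil_start < traj.n_frames:
        raise ValueError(
            f"equil_start {equil_start} outside 0..{traj.n_frames - 1}")
    frame_indices = np.arange(equil_start, traj.n_frames)
    flags = np.zeros(frame_indices.size, dtype=bool)
    paths: list[list[int]] = []
    for k, fidx in enumerate(frame_indices):
        cont, path = classify_frame(traj.frame(fidx), channel, criteria)
        flags[k] = cont
        paths.append(path)
    return WaterWireResult(
        per_frame=flags,
        spanning_paths=paths,
        occupancy=float(flags.mean()),
        run_lengths=_run_lengths(flags),
        frame_indices=frame_indices,
        times=traj.times[frame_indices],
    )
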