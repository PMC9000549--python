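"""Helix and sidechain z-displacement series — the gating kinematics.

Voltage gating of the proton channel shows up as opposed axial motions:
the S4 helix (carrying the gating-charge arginines) translates toward the
extracellular side while S2 moves down relative to it.  Helix motion is
measured as the z of each helix's Cα centroid relative to the pooled
four-helix Cα centroid, which cancels whole-channel drift.  Sidechain
tracks (Arg201/204/207, the Phe146/Leu143 gate) are measured after
rigidly superposing each frame onto a reference frame using an anchor
residue, Asp108 by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import superpose
from .model_io import ChannelDefinition, Topology, Trajectory, \
    resolve_residue, select_atoms

__all__ = [
    "DisplacementSeries",
    "helix_z_series",
    "sidechain_z_series",
    "gate_z_gap",
]


@dataclass
class DisplacementSeries:
    """One z-track in Å: a helix or residue against a stated reference."""

    label: str
    z_values: np.ndarray
    reference: str  # "four_helix_center" or "residue_superposition"
    frame_indices: np.ndarray = None
    times: np.ndarray = None

    def final_mean(self, fraction: float = 0.2) -> float:
        """Mean over the final ``fraction`` of frames (net-motion verdict)."""
        n = max(1, int(round(fraction * self.z_values.size)))
        return float(self.z_values[-n:].mean())


def _sidechain_indices(topology: Topology, residue) -> np.ndarray:
    idx = resolve_residue(topology, residue)
    side = [i for i in idx
            if topology.elements[i] != "H"
            and str(topology.names[i]) not in
            ("N", "CA", "C", "O", "OXT", "OT1", "OT2")]
    if not side:
        raise ValueError(
            f"residue {residue!r} has no sidechain heavy atoms "
            "(glycine has no sidechain)")
    return np.asarray(side, dtype=np.int64)


def helix_z_series(traj: Trajectory, channel: ChannelDefinition,
                   equil_start: int = 0, rezero: bool = True
                   ) -> dict[str, DisplacementSeries]:
    """Per-helix z-displacement relative to the four-helix center.

    For every frame, the z of each helix's Cα centroid minus the z of the
    pooled Cα centroid over the union of the four helix ranges (so the
    atom-count-weighted sum of the four series is identically zero).
    With ``rezero`` the series are shifted to start at 0 at the first
    analyzed frame, turning them into displacements.
    """
    helix_idx = channel.helix_atom_indices(traj.topology, mode="alpha_carbon")
    pooled = np.concatenate(list(helix_idx.values()))
    frame_indices = np.arange(equil_start, traj.n_frames)
    if frame_indices.size == 0:
        raise ValueError("no frames at or after equil_start")
    out = {}
    z_pool = traj.coords[frame_indices][:, pooled, 2].mean(axis=1)
    for label, idx in helix_idx.items():
        z_helix = traj.coords[frame_indices][:, idx, 2].mean(axis=1)
        series = z_helix - z_pool
        if rezero:
            series = series - series[0]
        out[label] = DisplacementSeries(
            label=label, z_values=series, reference="four_helix_center",
            frame_indices=frame_indices, times=traj.times[frame_indices])
    return out


def sidechain_z_series(traj: Trajectory, residue, superpose_on=None,
                       fit_selection: np.ndarray | None = None,
                       equil_start: int = 0,
                       rezero: bool = False) -> DisplacementSeries:
    """z-track of a residue's sidechain-heavy centroid, in Å.

    When ``superpose_on`` names an anchor residue, each frame is first
    rigidly superposed onto the first analyzed frame using the anchor's
    heavy atoms (or an explicit ``fit_selection`` of atom indices), so
    the track reads relative to that anchor's frame of reference.
    """
    top = traj.topology
    side = _sidechain_indices(top, residue)
    frame_indices = np.arange(equil_start, traj.n_frames)
    if frame_indices.size == 0:
        raise ValueError("no frames at or after equil_start")
    if superpose_on is not None and fit_selection is None:
        anchor = resolve_residue(top, superpose_on)
        fit_selection = anchor[top.elements[anchor] != "H"]
    z = np.empty(frame_indices.size)
    ref = traj.coords[frame_indices[0]]
    for k, fidx in enumerate(frame_indices):
        pos = traj.coords[fidx]
        if fit_selection is not None:
            transform, _ = superpose(pos[fit_selection], ref[fit_selection])
            z[k] = transform.apply(pos[side]).mean(axis=0)[2]
        else:
            z[k] = pos[side].mean(axis=0)[2]
    if rezero:
        z = z - z[0]
    return DisplacementSeries(
        label=_label(residue), z_values=z,
        reference="residue_superposition" if fit_selection is not None
        else "absolute",
        frame_indices=frame_indices, times=traj.times[frame_indices])


def gate_z_gap(traj: Trajectory, gate_residue, anchor=(108, "ASP"),
               equil_start: int = 0) -> DisplacementSeries:
    """Signed z-gap gate − anchor between sidechain centroids, in Å.

    Each frame is superposed on the anchor residue's heavy atoms first,
    so the gap tracks the gate's motion in the anchor's frame — e.g. the
    Phe146 (or Leu143) hydrophobic-gate residue against Asp108.
    """
    top = traj.topology
    gate_side = _sidechain_indices(top, gate_residue)
    anchor_side = _sidechain_indices(top, anchor)
    anchor_idx = resolve_residue(top, anchor)
    fit = anchor_idx[top.elements[anchor_idx] != "H"]
    frame_indices = np.arange(equil_start, traj.n_frames)
    if frame_indices.size == 0:
        raise ValueError("no frames at or after equil_start")
    ref = traj.coords[frame_indices[0]]
    gap = np.empty(frame_indices.size)
    for k, fidx in enumerate(frame_indices):
        pos = traj.coords[fidx]
        transform, _ = superpose(pos[fit], ref[fit])
        moved = transform.apply(pos)
        gap[k] = moved[gate_side].mean(axis=0)[2] \
            - moved[anchor_side].mean(axis=0)[2]
    return DisplacementSeries(
        label=f"{_label(gate_residue)}-{_label(anchor)}", z_values=gap,
        reference="residue_superposition",
        frame_indices=frame_indices, times=traj.times[frame_indices])


def _label(residue) -> str:
    if isinstance(residue, tuple):
        return f"{residue[0]}:{residue[1]}"
    return str(residue)
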