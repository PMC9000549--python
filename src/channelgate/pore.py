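"""Pore-radius profiling along the channel axis (HOLE-style, deterministic).

For each z-slice the pore radius is the radius of the largest sphere,
centered in the slice plane, that touches no atom: with the sphere center
``c`` confined to the plane,

    radius(z) = max_c  min_i ( |c - x_i| - vdw_i ),

clamped to [0, r_max], with ``c`` confined to the structure's radial
extent about the pore axis (so the search cannot wander past the helix
wall into open solvent).  The atom set is restricted to the four
transmembrane helix residue ranges.  The inner objective is 1-Lipschitz
in ``c``, which lets a coarse candidate grid be refined by deterministic
branch-and-bound with a provable error bound (≤ 0.005 Å at the default
settings) — in contrast to HOLE's stochastic Monte-Carlo walk, repeated
runs are bitwise identical.

A pore is *passable* for water when its minimum radius reaches the
1.15 Å threshold, the accepted minimum for a water molecule to pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model_io import (WATER_RESNAMES, ChannelDefinition, Frame,
                       select_atoms)

logger = logging.getLogger(__name__)

__all__ = ["PoreProfile", "pore_profile", "min_radius_and_passability",
           "WATER_PASSAGE_RADIUS"]

WATER_PASSAGE_RADIUS = 1.15  # Å, minimum radius for single-file water passage


@dataclass
class PoreProfile:
    """Radius-vs-z curve: ``radii[k]`` is the pore radius at ``z_grid[k]``."""

    z_grid: np.ndarray
    radii: np.ndarray
    centers: np.ndarray  # (n_slices, 2) in-plane sphere centers
    min_radius: float
    min_z: float

    def __post_init__(self) -> None:
        if len(self.z_grid) != len(self.radii):
            raise ValueError("z_grid and radii must have equal length")


def _clearance(centers_xy: np.ndarray, z0: float, atom_xyz: np.ndarray,
               atom_vdw: np.ndarray) -> np.ndarray:
    """min over atoms of (3D distance from (cx, cy, z0) to atom − vdw)."""
    dx = centers_xy[:, 0:1] - atom_xyz[:, 0][None, :]
    dy = centers_xy[:, 1:2] - atom_xyz[:, 1][None, :]
    dz = z0 - atom_xyz[:, 2][None, :]
    d = np.sqrt(dx * dx + dy * dy + dz * dz) - atom_vdw[None, :]
    return d.min(axis=1)


def _maximize_slice(z0: float, axis_xy: np.ndarray, atom_xyz: np.ndarray,
                    atom_vdw: np.ndarray, r_domain: float, r_max: float,
                    grid_res: float,
                    refine_to: float = 0.005) -> tuple[float, np.ndarray]:
    """Branch-and-bound maximization of the clearance over the slice disc.

    Starts from a square grid of spacing ``grid_res`` clipped to the disc
    of radius ``r_domain`` about the axis; repeatedly halves the spacing,
    keeping only candidates whose Lipschitz upper bound can still beat
    the incumbent.  Terminates when the spacing guarantees the optimum is
    within ``refine_to`` of the incumbent.
    """
    def clip_to_disc(rel: np.ndarray) -> np.ndarray:
        """Project candidates outside the search disc onto its boundary
        (discarding them would lose coverage of boundary maxima)."""
        r = np.hypot(rel[:, 0], rel[:, 1])
        out = r > r_domain
        if out.any():
            rel = rel.copy()
            rel[out] *= (r_domain / r[out])[:, None]
        return rel

    n = int(np.ceil(r_domain / grid_res))
    offs = np.arange(-n, n + 1) * grid_res
    gx, gy = np.meshgrid(offs, offs)
    rel = np.column_stack([gx.ravel(), gy.ravel()])
    rel = rel[np.hypot(rel[:, 0], rel[:, 1]) <= r_domain + grid_res]
    pts = clip_to_disc(rel) + axis_xy
    step = grid_res
    vals = _clearance(pts, z0, atom_xyz, atom_vdw)
    child = np.array([[dx, dy] for dx in (-0.25, 0.25) for dy in (-0.25, 0.25)])
    while True:
        best = vals.max()
        if best >= r_max:  # radius will be clamped; no need to refine
            k = int(vals.argmax())
            return float(best), pts[k]
        bound = step * np.sqrt(2) / 2  # half cell diagonal, Lipschitz const 1
        if bound <= refine_to:
            k = int(vals.argmax())
            return float(best), pts[k]
        keep = vals >= best - bound
        parents = pts[keep]
        children = (parents[:, None, :]
                    + child[None, :, :] * step).reshape(-1, 2)
        children = clip_to_disc(children - axis_xy) + axis_xy
        pts = np.concatenate([parents, children])
        step *= 0.5
        vals = _clearance(pts, z0, atom_xyz, atom_vdw)


def pore_profile(frame: Frame, channel: ChannelDefinition,
                 z_step: float = 0.5, r_max: float = 10.0,
                 grid_res: float = 0.25,
                 atom_indices: np.ndarray | None = None) -> PoreProfile:
    """Pore radius profile over the membrane slab of one frame.

    Uses all atoms of the four helix residue ranges unless an explicit
    ``atom_indices`` selection is given.  Slices with no atom within
    ``r_max`` (plus the largest vdW radius) report ``r_max`` with a
    logged warning.  Fully deterministic for fixed parameters.
    """
    if atom_indices is None:
        top = frame.topology
        water = np.isin(top.resnames, list(WATER_RESNAMES))
        parts = [select_atoms(top, resnum_range=rng)
                 for rng in channel.helix_ranges.values()]
        atom_indices = np.concatenate(parts)
        atom_indices = atom_indices[~water[atom_indices]]
        if atom_indices.size == 0:
            raise ValueError("helix residue ranges select no atoms")
    xyz = frame.positions[atom_indices]
    vdw = frame.topology.vdw[atom_indices]
    axis_xy = xyz[:, :2].mean(axis=0)
    # candidate centers stay within the structure's radial extent so the
    # search cannot escape past the wall into open solvent
    r_domain = min(r_max, float(
        np.hypot(xyz[:, 0] - axis_xy[0], xyz[:, 1] - axis_xy[1]).max()))
    z_lo, z_hi = channel.membrane_z
    z_grid = np.arange(z_lo, z_hi + 1e-9, z_step)
    radii = np.empty(z_grid.size)
    centers = np.empty((z_grid.size, 2))
    reach = r_max + vdw.max()
    for k, z0 in enumerate(z_grid):
        near = np.abs(xyz[:, 2] - z0) <= reach
        if not near.any():
            logger.warning("no atoms within %.1f Å of slice z=%.2f; "
                           "reporting r_max", reach, z0)
            radii[k] = r_max
            centers[k] = axis_xy
            continue
        val, center = _maximize_slice(z0, axis_xy, xyz[near], vdw[near],
                                      r_domain, r_max, grid_res)
        radii[k] = min(max(val, 0.0), r_max)
        centers[k] = center
    kmin = int(radii.argmin())
    return PoreProfile(z_grid=z_grid, radii=radii, centers=centers,
                       min_radius=float(radii[kmin]),
                       min_z=float(z_grid[kmin]))


def min_radius_and_passability(profile: PoreProfile,
                               water_threshold: float = WATER_PASSAGE_RADIUS
                               ) -> tuple[float, float, bool]:
    """(min_radius, min_z, passable): passable iff min radius ≥ threshold."""
    if len(profile.radii) == 0:
        raise ValueError("empty pore profile")
    return (profile.min_radius, profile.min_z,
            bool(profile.min_radius >= water_threshold))
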