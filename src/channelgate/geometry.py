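"""Centroids, least-squares rigid superposition (Kabsch) and RMSD series.

These are the reference-frame primitives behind every kinematic analysis:
helix displacements are measured against the four-helix center, and
sidechain z-tracks are measured after superposing each frame onto a
reference frame using an anchor residue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .model_io import Frame, Topology, Trajectory, select_atoms

__all__ = ["RigidTransform", "centroid", "superpose", "rmsd", "rmsd_series"]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body transform ``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=np.float64)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if abs(np.linalg.det(R) - 1.0) > 1e-8:
            raise ValueError("rotation must be proper (det +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def centroid(frame: Frame, *, resnum_range: tuple[int, int] | None = None,
             resnum: int | None = None, mode: str = "all_heavy") -> np.ndarray:
    """Unweighted geometric center of a selection, in Å.

    ``mode`` follows :func:`channelgate.model_io.select_atoms`:
    ``alpha_carbon``, ``sidechain_heavy`` or ``all_heavy``.
    """
    idx = select_atoms(frame.topology, resnum_range=resnum_range,
                       resnum=resnum, mode=mode)
    if idx.size == 0:
        raise ValueError(
            f"empty selection (resnum={resnum}, range={resnum_range}, "
            f"mode={mode!r})")
    return frame.positions[idx].mean(axis=0)


def _check_not_collinear(coords: np.ndarray) -> None:
    centered = coords - coords.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[0] == 0 or s[1] / s[0] < 1e-8:
        raise ValueError("degenerate (collinear) coordinate set: "
                         "superposition rotation is not unique")


def superpose(mobile: np.ndarray,
              reference: np.ndarray) -> tuple[RigidTransform, float]:
    """Optimal rigid superposition of paired coordinate sets (Kabsch).

    Returns the proper rigid transform mapping ``mobile`` onto
    ``reference`` in the least-squares sense, and the post-fit RMSD in Å.
    Reflections are never returned: the underlying solver flips the
    smallest singular vector when the raw optimum is improper.
    """
    mobile = np.asarray(mobile, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if mobile.shape != reference.shape:
        raise ValueError(
            f"paired sets required: {mobile.shape} vs {reference.shape}")
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("need at least 3 points of dimension 3")
    _check_not_collinear(reference)
    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    rot, rssd = Rotation.align_vectors(reference - ref_c, mobile - mob_c)
    R = rot.as_matrix()
    transform = RigidTransform(R, ref_c - R @ mob_c)
    return transform, float(rssd) / np.sqrt(mobile.shape[0])


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (no-fit) RMSD between paired coordinate sets, in Å."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired sets required")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rmsd_series(traj: Trajectory, reference_frame: int = 0, *,
                resnum_range: tuple[int, int] | None = None,
                mode: str = "all_heavy") -> np.ndarray:
    """Per-frame best-fit RMSD (Å) to a reference frame over a selection.

    Each frame is rigidly superposed onto the reference on the stated
    selection before the deviation is measured, so whole-body drift and
    tumbling do not register.
    """
    if not -traj.n_frames <= reference_frame < traj.n_frames:
        raise IndexError(f"reference frame {reference_frame} out of range")
    idx = select_atoms(traj.topology, resnum_range=resnum_range, mode=mode)
    if idx.size == 0:
        raise ValueError("selection matches no atoms")
    ref = traj.coords[reference_frame][idx]
    out = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        _, out[i] = superpose(traj.coords[i][idx], ref)
    return out
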