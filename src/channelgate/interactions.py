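"""Hydrogen-bond and salt-bridge time series between residue pairs.

A hydrogen bond D–H···A passes when the donor-heavy to acceptor-heavy
distance is within the cutoff (default 3.4 Å, inclusive) and the D–H···A
arrangement deviates from linearity by at most the angle cutoff
(default 30°).  The distance may alternatively be measured H···A
(``distance_mode="hydrogen"``); heavy–heavy is the default so the number
matches the water-wire O–O criterion.

A salt bridge is the subset of hydrogen bonds whose donor is an Arg/Lys
sidechain nitrogen and whose acceptor is an Asp/Glu carboxylate oxygen;
partner-switching of the S4 arginines between Asp108 and Asp181 is the
signature rearrangement accompanying channel opening.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_io import AtomRecord, Frame, Topology, Trajectory, resolve_residue

__all__ = [
    "HBondCriteria",
    "ContactSeries",
    "is_hbond",
    "hbond_count_series",
    "partner_occupancy_table",
]

MAX_DH_BOND = 1.2  # Å, covalent D–H association cutoff

# sidechain atoms defining salt-bridge termini
BASIC_SIDECHAIN_N = {"ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"}}
ACIDIC_SIDECHAIN_O = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criterion (distance Å, angle degrees)."""

    distance_cutoff: float = 3.4
    angle_cutoff: float = 30.0
    distance_mode: str = "heavy"  # "heavy" (D···A) or "hydrogen" (H···A)

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0 or self.angle_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if self.distance_mode not in ("heavy", "hydrogen"):
            raise ValueError("distance_mode must be 'heavy' or 'hydrogen'")


@dataclass
class ContactSeries:
    """Per-frame H-bond counts for one residue pair."""

    pair: tuple
    counts: np.ndarray
    frame_indices: np.ndarray = None
    times: np.ndarray = None

    @property
    def occupancy(self) -> float:
        """Fraction of frames with at least one bond."""
        return float((self.counts >= 1).mean())


def _deviation_from_linear(d: np.ndarray, h: np.ndarray,
                           a: np.ndarray) -> float:
    """Deviation of D–H···A from 180°, in degrees."""
    v1 = np.asarray(d, float) - np.asarray(h, float)
    v2 = np.asarray(a, float) - np.asarray(h, float)
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return 180.0 - angle


def is_hbond(donor_heavy: AtomRecord, hydrogen: AtomRecord,
             acceptor: AtomRecord,
             criteria: HBondCriteria = HBondCriteria()) -> bool:
    """Geometric hydrogen-bond test for one D–H···A triple.

    Raises if the hydrogen is not covalently associated with the donor
    (same residue, within 1.2 Å).
    """
    if hydrogen.residue_number != donor_heavy.residue_number or \
            np.linalg.norm(np.asarray(hydrogen.position)
                           - np.asarray(donor_heavy.position)) > MAX_DH_BOND:
        raise ValueError(
            f"hydrogen {hydrogen.name} is not bonded to donor "
            f"{donor_heavy.name} (same residue within {MAX_DH_BOND} Å required)")
    if criteria.distance_mode == "heavy":
        dist = np.linalg.norm(np.asarray(donor_heavy.position)
                              - np.asarray(acceptor.position))
    else:
        dist = np.linalg.norm(np.asarray(hydrogen.position)
                              - np.asarray(acceptor.position))
    if dist > criteria.distance_cutoff:
        return False
    dev = _deviation_from_linear(donor_heavy.position, hydrogen.position,
                                 acceptor.position)
    return dev <= criteria.angle_cutoff


def _donor_triples(topology: Topology, positions: np.ndarray,
                   idx: np.ndarray) -> list[tuple[int, int]]:
    """(donor_heavy, hydrogen) index pairs within one residue selection."""
    heavies = [i for i in idx if topology.elements[i] in ("N", "O")]
    hydrogens = [i for i in idx if topology.elements[i] == "H"]
    out = []
    for h in hydrogens:
        best, best_d = None, MAX_DH_BOND
        for d in heavies:
            dd = np.linalg.norm(positions[h] - positions[d])
            if dd <= best_d:
                best, best_d = d, dd
        if best is not None:
            out.append((best, h))
    return out


def _acceptors(topology: Topology, idx: np.ndarray) -> list[int]:
    return [i for i in idx if topology.elements[i] in ("N", "O")]


def _count_frame(topology: Topology, positions: np.ndarray,
                 idx_a: np.ndarray, idx_b: np.ndarray,
                 criteria: HBondCriteria,
                 donor_filter=None, acceptor_filter=None) -> int:
    count = 0
    for don_idx, acc_idx in ((idx_a, idx_b), (idx_b, idx_a)):
        triples = _donor_triples(topology, positions, don_idx)
        accs = _acceptors(topology, acc_idx)
        for d, h in triples:
            if donor_filter and not donor_filter(d):
                continue
            for a in accs:
                if acceptor_filter and not acceptor_filter(a):
                    continue
                key = positions[d] if criteria.distance_mode == "heavy" \
                    else positions[h]
                if np.linalg.norm(key - positions[a]) > criteria.distance_cutoff:
                    continue
                if _deviation_from_linear(positions[d], positions[h],
                                          positions[a]) <= criteria.angle_cutoff:
                    count += 1
    return count


def hbond_count_series(traj: Trajectory, residue_a, residue_b,
                       criteria: HBondCriteria = HBondCriteria(),
                       equil_start: int = 0,
                       hydrogen_free: bool = False) -> ContactSeries:
    """Per-frame count of hydrogen bonds between two residues.

    Donor–hydrogen pairs are identified per residue as hydrogens within
    1.2 Å of an N/O heavy atom; both donor directions are counted.  With
    ``hydrogen_free=True`` the angle term is skipped and N/O–N/O pairs
    within the distance cutoff are counted instead (for topologies
    without explicit hydrogens).
    """
    top = traj.topology
    idx_a = resolve_residue(top, residue_a)
    idx_b = resolve_residue(top, residue_b)
    if not hydrogen_free:
        has_h = any(top.elements[i] == "H" for i in np.concatenate([idx_a, idx_b]))
        if not has_h:
            raise ValueError(
                "neither residue carries hydrogens; pass hydrogen_free=True "
                "for the distance-only criterion")
    frame_indices = np.arange(equil_start, traj.n_frames)
    counts = np.zeros(frame_indices.size, dtype=np.int64)
    for k, fidx in enumerate(frame_indices):
        pos = traj.coords[fidx]
        if hydrogen_free:
            n = 0
            for i in _acceptors(top, idx_a):
                for j in _acceptors(top, idx_b):
                    if np.linalg.norm(pos[i] - pos[j]) <= criteria.distance_cutoff:
                        n += 1
            counts[k] = n
        else:
            counts[k] = _count_frame(top, pos, idx_a, idx_b, criteria)
    return ContactSeries(pair=(residue_a, residue_b), counts=counts,
                         frame_indices=frame_indices,
                         times=traj.times[frame_indices])


def _salt_bridge_filters(topology: Topology):
    def is_basic_n(i: int) -> bool:
        allowed = BASIC_SIDECHAIN_N.get(str(topology.resnames[i]), set())
        return str(topology.names[i]) in allowed

    def is_acidic_o(i: int) -> bool:
        allowed = ACIDIC_SIDECHAIN_O.get(str(topology.resnames[i]), set())
        return str(topology.names[i]) in allowed

    return is_basic_n, is_acidic_o


def partner_occupancy_table(traj: Trajectory, basic_residues: list,
                            acidic_residues: list,
                            criteria: HBondCriteria = HBondCriteria(),
                            equil_start: int = 0) -> pd.DataFrame:
    """Salt-bridge occupancy for every (basic, acidic) residue pair.

    Occupancy is the fraction of analyzed frames with at least one
    salt-bridge hydrogen bond (Arg/Lys sidechain N donating to an Asp/Glu
    carboxylate O).  The ``dominant`` column repeats, per acidic residue,
    the basic partner with the highest occupancy ("none" when all zero).
    """
    if not basic_residues or not acidic_residues:
        raise ValueError("residue lists must be non-empty")
    top = traj.topology
    is_basic_n, is_acidic_o = _salt_bridge_filters(top)
    frame_indices = np.arange(equil_start, traj.n_frames)
    rows = []
    for acid in acidic_residues:
        idx_acid = resolve_residue(top, acid)
        for base in basic_residues:
            idx_base = resolve_residue(top, base)
            hits = 0
            for fidx in frame_indices:
                n = _count_frame(top, traj.coords[fidx], idx_base, idx_acid,
                                 criteria, donor_filter=is_basic_n,
                                 acceptor_filter=is_acidic_o)
                hits += n >= 1
            rows.append({"acidic": _label(acid), "basic": _label(base),
                         "occupancy": hits / frame_indices.size})
    table = pd.DataFrame(rows)
    dominant = {}
    for acid, group in table.groupby("acidic"):
        best = group.loc[group["occupancy"].idxmax()]
        dominant[acid] = best["basic"] if best["occupancy"] > 0 else "none"
    table["dominant"] = table["acidic"].map(dominant)
    return table


def _label(residue) -> str:
    if isinstance(residue, tuple):
        return f"{residue[0]}:{residue[1]}"
    return str(residue)
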