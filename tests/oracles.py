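"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is deliberately naive (exhaustive enumeration, dense grids)
and shares no code with the library paths it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def brute_force_adjacency(indices, positions, cutoff) -> set[tuple[int, int]]:
    """O(n²) strict-inequality O–O edge enumeration."""
    idx = list(indices)
    edges = set()
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            if np.linalg.norm(positions[idx[a]] - positions[idx[b]]) < cutoff:
                edges.add((min(idx[a], idx[b]), max(idx[a], idx[b])))
    return edges


def brute_force_spanning(indices, positions, cutoff, z_lo, z_hi) -> bool:
    """Union-find connected components; True iff one component touches
    both z-boundaries."""
    idx = list(indices)
    parent = {i: i for i in idx}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in brute_force_adjacency(idx, positions, cutoff):
        parent[find(a)] = find(b)
    comps = {}
    for i in idx:
        comps.setdefault(find(i), []).append(i)
    for members in comps.values():
        zs = [positions[i][2] for i in members]
        if max(zs) >= z_hi and min(zs) <= z_lo:
            return True
    return False


def euler_grid_min_rmsd(mobile, reference, coarse_deg=12.0, levels=4):
    """Rotation-grid search for the minimum superposition RMSD.

    Scans proper rotations on an Euler-angle (ZYZ) grid, then refines the
    grid around the best rotation; translation is optimal by centering.
    Independent of the SVD/Kabsch route.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    A = mobile - mobile.mean(axis=0)
    B = reference - reference.mean(axis=0)
    n = len(A)

    def scan(alphas, betas, gammas):
        best = (np.inf, None)
        for a in alphas:
            for b in betas:
                for g in gammas:
                    R = Rotation.from_euler("ZYZ", [a, b, g],
                                            degrees=True).as_matrix()
                    val = np.sqrt(np.sum((A @ R.T - B) ** 2) / n)
                    if val < best[0]:
                        best = (val, (a, b, g))
        return best

    step = coarse_deg
    best_val, best_ang = scan(np.arange(0, 360, step),
                              np.arange(0, 180 + step, step),
                              np.arange(0, 360, step))
    for _ in range(levels):
        fine = step / 3.0
        a0, b0, g0 = best_ang
        rng = np.arange(-1.5, 1.51, 0.5)
        val, ang = scan(a0 + rng * step, b0 + rng * step, g0 + rng * step)
        if val < best_val:
            best_val, best_ang = val, ang
        step = fine
    return best_val


def fine_grid_pore_radius(xyz, vdw, z0, r_max=10.0, grid=0.005):
    """Exhaustive dense-grid maximization of the slice clearance.

    Same domain rule as the profiler: centers within the structure's
    radial extent about the mean-xy axis (capped at r_max).
    """
    xyz = np.asarray(xyz, float)
    vdw = np.asarray(vdw, float)
    axis = xyz[:, :2].mean(axis=0)
    r_dom = min(r_max, np.hypot(xyz[:, 0] - axis[0],
                                xyz[:, 1] - axis[1]).max())
    n = int(np.floor(r_dom / grid))
    offs = np.arange(-n, n + 1) * grid
    best = -np.inf
    for ox in offs:  # row-wise to bound memory
        cy = offs[np.hypot(ox, offs) <= r_dom]
        if cy.size == 0:
            continue
        cx = np.full_like(cy, ox)
        d = np.sqrt((cx[:, None] + axis[0] - xyz[:, 0]) ** 2
                    + (cy[:, None] + axis[1] - xyz[:, 1]) ** 2
                    + (z0 - xyz[:, 2]) ** 2) - vdw
        best = max(best, d.min(axis=1).max())
    return min(max(best, 0.0), r_max)


def grid_scan_pi(charge_fn, step=0.001):
    """pH grid scan: the pH in [0, 14] whose |charge| is smallest."""
    phs = np.arange(0.0, 14.0 + step, step)
    charges = np.array([charge_fn(p) for p in phs])
    return float(phs[np.abs(charges).argmin()])
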