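"""Pairwise steric interaction between fiber interaction points.

The interaction points are the fiber vertices themselves (spaced 0.2 µm).
The force law is piecewise linear: repulsive below the effective diameter
d0, attractive between d0 and the maximal range dm, zero beyond.  The jump
of magnitude K_pull·(dm - d0) at dm is a documented property of the law,
not an artifact to be smoothed.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .params import StericParams

#: points closer than this many segments in arc length on the same fiber
#: never interact (prevents self-collapse of the discretization).
SELF_EXCLUSION_SEGMENTS = 3


def pair_force(d, params: StericParams):
    """Signed scalar force at separation d (pN); negative = repulsive.

    Returns K_push·(d-d0) for d < d0, K_pull·(d-d0) for d0 <= d <= dm and
    0 for d > dm.  Accepts scalars or arrays.
    """
    d = np.asarray(d, dtype=float)
    out = np.where(d < params.d0,
                   params.K_push * (d - params.d0),
                   np.where(d <= params.dm, params.K_pull * (d - params.d0), 0.0))
    return float(out) if out.ndim == 0 else out


def _min_image(delta: np.ndarray, domain) -> np.ndarray:
    if domain is not None:
        L = np.asarray(domain, dtype=float)
        delta = delta - L * np.round(delta / L)
    return delta


def neighbor_pairs(points: np.ndarray, dm: float,
                   fiber_ids: Optional[np.ndarray] = None,
                   arc_index: Optional[np.ndarray] = None,
                   domain=None,
                   exclusion: int = SELF_EXCLUSION_SEGMENTS
                   ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All point pairs within distance dm (broad phase + exact filter).

    Parameters
    ----------
    points : (n, 2) array of interaction-point positions.
    dm : maximal interaction distance (> 0).
    fiber_ids, arc_index : optional (n,) arrays; pairs on the same fiber
        whose arc-index difference is < ``exclusion`` are excluded.
    domain : optional (Lx, Ly) periodic box (minimum-image distances).

    Returns
    -------
    (i, j, d): index arrays with i < j, duplicate-free, and their distances.
    """
    if dm <= 0:
        raise ValueError("dm must be positive")
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        z = np.zeros(0, dtype=int)
        return z, z, np.zeros(0)
    if domain is not None:
        L = np.asarray(domain, dtype=float)
        wrapped = np.remainder(pts, L)
        # guard against points landing exactly on the upper boundary
        wrapped[wrapped >= L] = 0.0
        tree = cKDTree(wrapped, boxsize=L)
    else:
        tree = cKDTree(pts)
    pairs = tree.query_pairs(dm, output_type="ndarray")
    if len(pairs) == 0:
        z = np.zeros(0, dtype=int)
        return z, z, np.zeros(0)
    i, j = pairs[:, 0], pairs[:, 1]
    if fiber_ids is not None:
        same = np.asarray(fiber_ids)[i] == np.asarray(fiber_ids)[j]
        if arc_index is not None:
            close = np.abs(np.asarray(arc_index)[i] - np.asarray(arc_index)[j]) < exclusion
            drop = same & close
        else:
            drop = same
        i, j = i[~drop], j[~drop]
    delta = _min_image(pts[j] - pts[i], domain)
    d = np.linalg.norm(delta, axis=1)
    keep = d <= dm
    return i[keep], j[keep], d[keep]


def steric_forces(points: np.ndarray, params: StericParams,
                  fiber_ids: Optional[np.ndarray] = None,
                  arc_index: Optional[np.ndarray] = None,
                  domain=None,
                  rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Total steric force on every interaction point (action = -reaction).

    For each interacting pair, equal and opposite forces act along the
    separation axis; the system-wide sum is zero.  Coincident points (d = 0)
    are pushed apart along a deterministically seeded random direction.
    """
    pts = np.asarray(points, dtype=float)
    f = np.zeros_like(pts)
    i, j, d = neighbor_pairs(pts, params.dm, fiber_ids, arc_index, domain)
    if len(i) == 0:
        return f
    delta = _min_image(pts[j] - pts[i], domain)
    zero = d < 1e-12
    if np.any(zero):
        rng = rng or np.random.default_rng(12345)
        phi = rng.uniform(0, 2 * np.pi, int(zero.sum()))
        delta[zero] = np.column_stack([np.cos(phi), np.sin(phi)]) * 1e-12
        d = np.where(zero, 1e-12, d)
    mag = pair_force(d, params)          # >0 attractive (toward each other)
    fij = (mag / d)[:, None] * delta     # force on i, along i->j
    np.add.at(f, i, fij)
    np.add.at(f, j, -fij)
    return f


def pair_spring_stiffness(d: np.ndarray, params: StericParams) -> np.ndarray:
    """Local spring constant of each pair (pN/µm), for implicit damping."""
    d = np.asarray(d, dtype=float)
    return np.where(d < params.d0, params.K_push,
                    np.where(d <= params.dm, params.K_pull, 0.0))
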