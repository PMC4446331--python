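"""Semiflexible-fiber mechanics: bending forces, force-dependent growth,
worm-like-chain sampling and persistence-length estimation.

A fiber is an ordered (n, 2) array of vertex positions; index 0 is the
pointed (minus) end and index n-1 the growing barbed (plus) end.  The
discrete worm-like-chain bending energy over interior joints is

    E = (K / 2l) * sum_i theta_i**2

with l the segment length, theta_i the turning angle at joint i, and
K = kBT * Lp the bending stiffness.  In two dimensions this energy makes
equilibrium joint angles Gaussian with variance l/Lp, so tangent
correlations decay as <cos dtheta(s)> = exp(-s / 2 Lp).
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence, Tuple

import numpy as np

from .params import MechParams


def bending_forces(vertices: np.ndarray, K: float,
                   segment_length: Optional[float] = None) -> np.ndarray:
    """Per-vertex bending forces (pN): negative gradient of the WLC energy.

    Parameters
    ----------
    vertices : (n, 2) array
        Fiber vertex positions, µm.
    K : float
        Bending stiffness, pN·µm².
    segment_length : float, optional
        Segment length l entering E = (K/2l)·Σθ².  Defaults to the mean of
        the actual segment lengths.

    Returns
    -------
    (n, 2) array of forces.  Fibers with fewer than 3 vertices have no
    curvature and get zero forces.  The returned forces sum to zero and
    exert no net torque (the energy depends only on the fiber's shape).
    """
    x = np.asarray(vertices, dtype=float)
    n = len(x)
    f = np.zeros_like(x)
    if n < 3:
        return f
    seg = np.diff(x, axis=0)                       # (n-1, 2)
    if segment_length is None:
        segment_length = float(np.mean(np.linalg.norm(seg, axis=1)))
    a, b = seg[:-1], seg[1:]                       # joint i between a_i, b_i
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    dot = np.einsum("ij,ij->i", a, b)
    theta = np.arctan2(cross, dot)                 # turning angle per joint
    coef = K * theta / segment_length              # dE/dtheta
    a2 = np.einsum("ij,ij->i", a, a)
    b2 = np.einsum("ij,ij->i", b, b)
    aperp = np.column_stack([-a[:, 1], a[:, 0]]) / a2[:, None]
    bperp = np.column_stack([-b[:, 1], b[:, 0]]) / b2[:, None]
    # dtheta/dx_{i-1} = +aperp, dtheta/dx_{i+1} = +bperp,
    # dtheta/dx_i = -(aperp + bperp); force = -coef * dtheta/dx
    ga = coef[:, None] * aperp
    gb = coef[:, None] * bperp
    np.add.at(f, np.arange(n - 2), -ga)
    np.add.at(f, np.arange(1, n - 1), ga + gb)
    np.add.at(f, np.arange(2, n), -gb)
    return f


def bending_energy(vertices: np.ndarray, K: float,
                   segment_length: Optional[float] = None) -> float:
    """Discrete WLC bending energy E = (K/2l)·Σθ² (pN·µm)."""
    x = np.asarray(vertices, dtype=float)
    if len(x) < 3:
        return 0.0
    seg = np.diff(x, axis=0)
    if segment_length is None:
        segment_length = float(np.mean(np.linalg.norm(seg, axis=1)))
    a, b = seg[:-1], seg[1:]
    theta = np.arctan2(a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0],
                       np.einsum("ij,ij->i", a, b))
    return float(K / (2.0 * segment_length) * np.sum(theta**2))


def tip_growth_speed(tip_force: np.ndarray, tip_tangent: np.ndarray,
                     params: MechParams) -> float:
    """Barbed-end elongation speed under load, µm/s.

    Growth at speed v0 is reduced exponentially by any antagonistic force:
    v = v0·exp(f·t / fs) when the projection f·t of the tip force on the
    barbed-end tangent is negative, and v = v0 otherwise.
    """
    ft = float(np.dot(tip_force, tip_tangent))
    if ft < 0.0:
        return params.v0 * float(np.exp(ft / params.fs))
    return params.v0


def sample_wlc_fiber(n_segments: int, Lp: float, rng: np.random.Generator,
                     segment_length: float = 0.2,
                     origin=(0.0, 0.0), phi0: Optional[float] = None) -> np.ndarray:
    """Draw one fiber from the exact 2D worm-like-chain equilibrium.

    Joint angles are independent Gaussians with variance l/Lp (the Boltzmann
    weight of E = (K/2l)Σθ² at K = kBT·Lp), so the sample has
    <cos dtheta(k·l)> = exp(-k·l / 2Lp) exactly in expectation.
    """
    if phi0 is None:
        phi0 = rng.uniform(0.0, 2.0 * np.pi)
    dphi = rng.normal(0.0, np.sqrt(segment_length / Lp), n_segments - 1)
    phi = phi0 + np.concatenate([[0.0], np.cumsum(dphi)])
    steps = segment_length * np.column_stack([np.cos(phi), np.sin(phi)])
    return np.concatenate([[origin], origin + np.cumsum(steps, axis=0)])


def tangent_correlation(fibers: Sequence[np.ndarray],
                        max_lag: Optional[int] = None
                        ) -> Tuple[np.ndarray, np.ndarray]:
    """Mean tangent-angle correlation <cos dtheta(s)> versus arc separation.

    Returns (s, corr) where s = k·<l> for lags k = 1..max_lag, averaging
    over all vertex pairs of all fibers.
    """
    nseg = min(len(f) - 1 for f in fibers)
    if max_lag is None:
        max_lag = max(1, nseg - 1)
    max_lag = min(max_lag, nseg - 1)
    sums = np.zeros(max_lag)
    counts = np.zeros(max_lag)
    seglen = []
    for f in fibers:
        seg = np.diff(np.asarray(f, dtype=float), axis=0)
        ln = np.linalg.norm(seg, axis=1)
        seglen.append(ln.mean())
        phi = np.arctan2(seg[:, 1], seg[:, 0])
        phi = np.unwrap(phi)
        for k in range(1, max_lag + 1):
            d = phi[k:] - phi[:-k]
            sums[k - 1] += np.cos(d).sum()
            counts[k - 1] += d.size
    s = np.arange(1, max_lag + 1) * float(np.mean(seglen))
    return s, sums / counts


def estimate_persistence_length(fibers: Sequence[np.ndarray],
                                max_lag: Optional[int] = None,
                                n_bootstrap: int = 200,
                                rng: Optional[np.random.Generator] = None,
                                min_fibers: int = 50,
                                min_segments: int = 10
                                ) -> Tuple[float, float]:
    """Fit <cos dtheta(s)> = exp(-s / 2 Lp) on a thermal fiber ensemble.

    Parameters
    ----------
    fibers : sequence of (n, 2) arrays
        At least ``min_fibers`` fibers of at least ``min_segments`` segments,
        sampled at thermal equilibrium with no external forces.

    Returns
    -------
    (Lp, se) : persistence length (µm) and its bootstrap standard error.
    Perfectly straight ensembles (correlation identically 1) return
    ``(inf, 0.0)``.

    Notes
    -----
    The decay is fitted by least squares on log <cos dtheta> over lags where
    the correlation stays above 0.2, weighting each lag by its pair count
    implicitly through the ensemble average.
    """
    fibers = [np.asarray(f, dtype=float) for f in fibers]
    if len(fibers) < min_fibers or any(len(f) - 1 < min_segments for f in fibers):
        raise ValueError(
            f"need >= {min_fibers} fibers with >= {min_segments} segments "
            f"(got {len(fibers)} fibers)")

    def _fit(sub: Sequence[np.ndarray]) -> float:
        s, corr = tangent_correlation(sub, max_lag=max_lag)
        good = corr > 0.2
        if corr[good].min(initial=1.0) > 1.0 - 1e-12:
            return np.inf
        s, corr = s[good], np.clip(corr[good], 1e-12, None)
        # slope of log corr vs s through the origin = -1/(2 Lp)
        slope = np.sum(s * np.log(corr)) / np.sum(s * s)
        if slope >= 0.0:
            return np.inf
        return -1.0 / (2.0 * slope)

    est = _fit(fibers)
    if not np.isfinite(est):
        return np.inf, 0.0
    rng = rng or np.random.default_rng(0)
    idx = np.arange(len(fibers))
    boots = []
    for _ in range(n_bootstrap):
        pick = rng.choice(idx, size=len(idx), replace=True)
        b = _fit([fibers[i] for i in pick])
        if np.isfinite(b):
            boots.append(b)
    se = float(np.std(boots)) if boots else np.nan
    return float(est), se
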