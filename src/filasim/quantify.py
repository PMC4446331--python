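"""Rendering of fiber configurations and organization metrics.

Implements the image statistics used to compare simulated networks with
experiments: the corner-intensity ratio I_c (bundling along the pattern
axis depletes the corners, I_c < 1), the intensity deviation I_d along an
ellipse around the pattern (high for discrete bundles), orientation
fractions of segments crossing a V-shape's bisecting line, the meeting
angle between fibers from opposing bars, and the outer-intensity statistic
rho_ext of the primer-effect experiment, plus the standard distribution
tests (two-sample Kolmogorov-Smirnov, one-sample Wilcoxon signed-rank
against zero, Spearman rank correlation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage, stats

from .patterns import PatternGeometry, Rect
from .world import World


@dataclass
class DensityImage:
    """2D actin-density image rendered from a fiber configuration."""

    pixel_size: float              # µm per pixel
    values: np.ndarray             # (ny, nx) non-negative intensities
    origin: Tuple[float, float]    # world coordinate of pixel (0, 0) center

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def world_to_pixel(self, pts: np.ndarray) -> np.ndarray:
        """Continuous pixel coordinates (col, row) of world points."""
        pts = np.atleast_2d(pts)
        return (pts - np.asarray(self.origin)) / self.pixel_size

    def sample_bilinear(self, pts: np.ndarray) -> np.ndarray:
        """Bilinear interpolation of the image at world points."""
        pix = self.world_to_pixel(pts)
        # map_coordinates expects (row, col)
        return ndimage.map_coordinates(self.values, [pix[:, 1], pix[:, 0]],
                                       order=1, mode="constant")


def _segments_of(world_or_frames) -> Tuple[np.ndarray, np.ndarray]:
    """All fiber segments as (starts (n,2), ends (n,2))."""
    if isinstance(world_or_frames, World):
        X = world_or_frames.X
        valid = world_or_frames._seg_valid
        if len(X) < 2:
            return np.zeros((0, 2)), np.zeros((0, 2))
        return X[:-1][valid], X[1:][valid]
    starts, ends = [], []
    for rec in world_or_frames:
        v = rec["vertices"] if isinstance(rec, dict) else np.asarray(rec)
        starts.append(v[:-1])
        ends.append(v[1:])
    if not starts:
        return np.zeros((0, 2)), np.zeros((0, 2))
    return np.vstack(starts), np.vstack(ends)


def render_density(world, pixel_size: float = 0.1, blur_sigma: float = 0.0,
                   extent: Optional[Tuple[float, float, float, float]] = None,
                   pad: float = 2.0) -> DensityImage:
    """Render fiber density: each segment deposits intensity equal to its
    length (µm) by sub-pixel line sampling, then an optional Gaussian blur
    of width ``blur_sigma`` (µm) emulates the optical point-spread.

    ``extent = (xmin, xmax, ymin, ymax)`` fixes the field of view; by
    default it hugs the fibers with ``pad`` µm of margin.  Deterministic.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    a, b = _segments_of(world)
    domain = world.geometry.periodic_domain if isinstance(world, World) else None
    if extent is None:
        if domain is not None:
            extent = (-domain[0] / 2, domain[0] / 2, -domain[1] / 2, domain[1] / 2)
        elif len(a):
            lo = np.minimum(a.min(axis=0), b.min(axis=0)) - pad
            hi = np.maximum(a.max(axis=0), b.max(axis=0)) + pad
            extent = (lo[0], hi[0], lo[1], hi[1])
        else:
            extent = (-5.0, 5.0, -5.0, 5.0)
    xmin, xmax, ymin, ymax = extent
    nx = max(1, int(round((xmax - xmin) / pixel_size)))
    ny = max(1, int(round((ymax - ymin) / pixel_size)))
    img = np.zeros((ny, nx))
    if len(a):
        seglen = np.linalg.norm(b - a, axis=1)
        # sub-pixel sampling: ~4 samples per pixel crossed
        nsamp = np.maximum(2, np.ceil(4 * seglen / pixel_size).astype(int))
        for k in range(len(a)):
            t = (np.arange(nsamp[k]) + 0.5) / nsamp[k]
            pts = a[k] + t[:, None] * (b[k] - a[k])
            if domain is not None:
                L = np.asarray(domain)
                pts = (pts + L / 2) % L - L / 2
            ix = np.floor((pts[:, 0] - xmin) / pixel_size).astype(int)
            iy = np.floor((pts[:, 1] - ymin) / pixel_size).astype(int)
            ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
            np.add.at(img, (iy[ok], ix[ok]), seglen[k] / nsamp[k])
    if blur_sigma > 0:
        img = ndimage.gaussian_filter(img, blur_sigma / pixel_size,
                                      mode="wrap" if domain is not None else "constant")
    origin = (xmin + pixel_size / 2, ymin + pixel_size / 2)
    return DensityImage(pixel_size=pixel_size, values=img, origin=origin)


# ---------------------------------------------------------------------------
# image metrics
# ---------------------------------------------------------------------------

def corner_intensity_ratio(image: DensityImage, geometry, corner_box: float = 2.0
                           ) -> float:
    """I_c: mean corner-box intensity over mean image intensity.

    The four boxes are squares of side ``corner_box`` placed diagonally
    adjacent to the four corners of the (single) rectangular bar; both the
    box and whole-image intensities are normalized per unit area, so a
    spatially uniform image gives exactly 1.
    """
    if isinstance(geometry, PatternGeometry):
        rects = [r for r in geometry.regions if isinstance(r, Rect)]
        if len(rects) != 1:
            raise ValueError("I_c needs a single-bar geometry")
        bar = rects[0]
    else:
        bar = geometry
    tot = image.values.sum()
    if tot <= 0:
        raise ValueError("zero total intensity")
    mean_all = image.values.mean()
    c, s = math.cos(bar.angle), math.sin(bar.angle)
    hl, hw = bar.length / 2, bar.width / 2
    means = []
    for su in (-1, 1):
        for sv in (-1, 1):
            # box center sits diagonally off the corner
            u = su * (hl + corner_box / 2)
            v = sv * (hw + corner_box / 2)
            cx = bar.center[0] + c * u - s * v
            cy = bar.center[1] + s * u + c * v
            pix = image.world_to_pixel(np.array([[cx, cy]]))[0]
            half = corner_box / (2 * image.pixel_size)
            x0, x1 = int(round(pix[0] - half)), int(round(pix[0] + half))
            y0, y1 = int(round(pix[1] - half)), int(round(pix[1] + half))
            x0, y0 = max(x0, 0), max(y0, 0)
            x1 = min(x1, image.values.shape[1])
            y1 = min(y1, image.values.shape[0])
            if x1 <= x0 or y1 <= y0:
                raise ValueError("corner box falls outside the image")
            means.append(image.values[y0:y1, x0:x1].mean())
    return float(np.mean(means) / mean_all)


def ellipse_intensity_deviation(image: DensityImage,
                                center: Tuple[float, float],
                                semi_axes: Tuple[float, float],
                                n_samples: int = 720) -> float:
    """I_d: normalized standard deviation of intensity along an ellipse.

    Intensity is sampled (bilinear) at ``n_samples`` points uniformly
    spaced in arc length along the ellipse perimeter, divided by the mean
    sample, and the standard deviation of the normalized samples returned.
    """
    a, b = semi_axes
    if a <= 0 or b <= 0:
        raise ValueError("degenerate ellipse")
    # uniform-in-arc-length parametrization via dense resampling
    t = np.linspace(0, 2 * np.pi, 20 * n_samples, endpoint=False)
    xy = np.column_stack([center[0] + a * np.cos(t), center[1] + b * np.sin(t)])
    d = np.linalg.norm(np.diff(np.vstack([xy, xy[:1]]), axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(d)])
    total = arc[-1]
    want = np.arange(n_samples) * total / n_samples
    idx = np.searchsorted(arc, want, side="right") - 1
    pts = xy[np.clip(idx, 0, len(xy) - 1)]
    vals = image.sample_bilinear(pts)
    m = vals.mean()
    if m <= 0:
        raise ValueError("zero mean intensity along the ellipse")
    return float(np.std(vals / m))


def default_ellipse(bar: Rect, margin: float = 3.0) -> Tuple[Tuple[float, float],
                                                             Tuple[float, float]]:
    """Ellipse used for I_d: centered on the bar, semi-axes
    (half-length + margin, margin) in the bar frame (bar assumed axis-aligned)."""
    return tuple(bar.center), (bar.length / 2 + margin, margin)


# ---------------------------------------------------------------------------
# line-crossing metrics (V-shape analyses)
# ---------------------------------------------------------------------------

def _crossing_segments(world: World, axis: str = "y"):
    """Segments crossing the bisecting line (the y-axis), with tangents."""
    X = world.X
    if len(X) < 2:
        return np.zeros(0, dtype=int), np.zeros((0, 2))
    valid = world._seg_valid
    a, b = X[:-1], X[1:]
    cross = (np.sign(a[:, 0]) != np.sign(b[:, 0])) & valid
    idx = np.nonzero(cross)[0]
    tan = b[idx] - a[idx]
    tan /= np.linalg.norm(tan, axis=1, keepdims=True)
    return idx, tan


def median_line_fractions(world: World, angle_window: float = 20.0
                          ) -> Dict[str, float]:
    """Fractions of bisector crossings classified by orientation.

    Every fiber segment crossing the bisecting line (the y-axis of a
    V-shape geometry) is classified by the unsigned acute angle of its
    tangent to the x-axis: within [90-w, 90] degrees -> "parallel" (aligned
    with the bisector), within [0, w] -> "antiparallel", else "other"
    (w = ``angle_window``).  Fractions are crossing-weighted; if nothing
    crosses, all fractions are 0 and ``n`` flags the empty result.
    """
    idx, tan = _crossing_segments(world)
    n = len(idx)
    if n == 0:
        return {"parallel": 0.0, "antiparallel": 0.0, "other": 0.0, "n": 0}
    ang = np.degrees(np.arctan2(np.abs(tan[:, 1]), np.abs(tan[:, 0])))  # acute, [0, 90]
    par = np.count_nonzero(ang >= 90.0 - angle_window)
    anti = np.count_nonzero(ang <= angle_window)
    return {"parallel": par / n, "antiparallel": anti / n,
            "other": (n - par - anti) / n, "n": n}


def meeting_angles(world: World, contact_radius: Optional[float] = None,
                   line_halfwidth: float = 1.0,
                   line_interval: Optional[Tuple[float, float]] = None
                   ) -> np.ndarray:
    """Meeting angles (deg) between fibers from opposing bars on the
    middle line between the patterns.

    For every pair of vertices from fibers of different origin tags that
    are in steric contact (within ``contact_radius`` of each other,
    default: the steric range dm) inside the bisector band
    |x| <= ``line_halfwidth``, the unsigned angle in [0, 180] between the
    two local tangents (oriented pointed-to-barbed) is recorded: 180 deg is
    a head-on antiparallel encounter, 0 deg co-aligned parallel growth.

    The band is wider than the contact radius because zipped bundles
    running along the bisector have a finite width of several effective
    fiber diameters.  ``line_interval`` optionally restricts the bisector
    coordinate (y) to the stretch that lies *between* the patterns — the
    gap corridor for collinear bars, the wedge interior above the vertex
    for an opened V; the experiment drivers supply it from the pattern
    construction.  Outside that stretch the two networks' fan edges merge
    in open space regardless of the pattern angle, which is not the
    structure this statistic classifies.

    Contact points lying inside a nucleation region are excluded: where
    the two patterns meet or overlap (the shared vertex of a V), fibers of
    both origins co-nucleate, and their in-pattern contacts reflect the
    overlapping nucleation zones rather than networks meeting on the line.
    """
    from scipy.spatial import cKDTree

    r = world.steric.dm if contact_radius is None else contact_radius
    X = world.X
    if len(X) == 0:
        return np.zeros(0)
    near_line = np.abs(X[:, 0]) <= max(line_halfwidth, r)
    if line_interval is not None:
        near_line &= (X[:, 1] >= line_interval[0]) \
            & (X[:, 1] <= line_interval[1])
    if world.geometry.regions:
        near_line &= ~world.geometry.contains(X)
    idx = np.nonzero(near_line)[0]
    if len(idx) < 2:
        return np.zeros(0)
    tags = world.origin[world.fiber_of[idx]]
    tree = cKDTree(X[idx])
    pairs = tree.query_pairs(r, output_type="ndarray")
    if len(pairs) == 0:
        return np.zeros(0)
    i, j = idx[pairs[:, 0]], idx[pairs[:, 1]]
    diff = tags[pairs[:, 0]] != tags[pairs[:, 1]]
    i, j = i[diff], j[diff]
    if len(i) == 0:
        return np.zeros(0)
    tan = world.vertex_tangents()
    dot = np.clip(np.einsum("ij,ij->i", tan[i], tan[j]), -1.0, 1.0)
    return np.degrees(np.arccos(dot))


# ---------------------------------------------------------------------------
# primer-effect statistic
# ---------------------------------------------------------------------------

def rho_ext(I_d_ti: float, I_d_tf: float, I_inf_ti: float, I_inf_tf: float
            ) -> float:
    """Outer-intensity fold-change difference
    rho_ext = I(d, tf)/I(d, ti) - I(d_inf, tf)/I(d_inf, ti).

    Positive values indicate extra outer-side assembly caused by the
    neighboring bar (primer-effect nucleation)."""
    if I_d_ti <= 0 or I_inf_ti <= 0:
        raise ValueError("initial-time intensities must be positive")
    return I_d_tf / I_d_ti - I_inf_tf / I_inf_ti


def outer_strip_intensity(frame, bar: Rect, strip_distance: float = 7.0,
                          strip_width: float = 1.0, side: int = -1) -> float:
    """Fiber length inside a strip parallel to a horizontal bar.

    The strip spans the bar's x-extent (plus its own width on both sides)
    and lies at ``strip_distance`` from the bar center on the outer side
    (``side`` = -1: below, +1: above).  Intensity = total fiber length in
    the strip, measured by midpoint sampling of each segment at 10 nm
    resolution.
    """
    a, b = _segments_of(frame)
    if len(a) == 0:
        return 0.0
    y0 = bar.center[1] + side * strip_distance
    ylo, yhi = y0 - strip_width / 2, y0 + strip_width / 2
    xlo = bar.center[0] - bar.length / 2 - strip_width
    xhi = bar.center[0] + bar.length / 2 + strip_width
    seglen = np.linalg.norm(b - a, axis=1)
    total = 0.0
    for k in range(len(a)):
        ns = max(2, int(math.ceil(seglen[k] / 0.01)))
        t = (np.arange(ns) + 0.5) / ns
        pts = a[k] + t[:, None] * (b[k] - a[k])
        ok = ((pts[:, 1] >= ylo) & (pts[:, 1] <= yhi)
              & (pts[:, 0] >= xlo) & (pts[:, 0] <= xhi))
        total += seglen[k] * ok.mean()
    return float(total)


# ---------------------------------------------------------------------------
# distribution tests
# ---------------------------------------------------------------------------

def ks_test(samples_a: Sequence[float], samples_b: Sequence[float]):
    """Two-sample Kolmogorov-Smirnov test (exact sup-distance of the ECDFs,
    asymptotic p-value).  Returns (D, p)."""
    a, b = np.asarray(samples_a), np.asarray(samples_b)
    if len(a) < 5 or len(b) < 5:
        raise ValueError("need at least 5 samples per group")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def wilcoxon_vs_zero(samples: Sequence[float]):
    """One-sample Wilcoxon signed-rank test of median = 0.  Returns (W, p)."""
    x = np.asarray(samples, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 samples")
    res = stats.wilcoxon(x, zero_method="wilcox")
    return float(res.statistic), float(res.pvalue)


def spearman_trend(x: Sequence[float], y: Sequence[float]):
    """Spearman rank correlation (mid-ranks for ties) with its trend
    p-value.  Returns (rho, p); constant input raises."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 samples")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for constant input")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# summary record
# ---------------------------------------------------------------------------

@dataclass
class MetricRecord:
    """One row of a metrics table, with full provenance."""

    run_id: str = ""
    seed: int = 0
    time: float = 0.0
    params: Dict[str, float] = field(default_factory=dict)
    I_c: Optional[float] = None
    I_d: Optional[float] = None
    fractions: Optional[Dict[str, float]] = None
    meeting_angle_median: Optional[float] = None
    rho_ext: Optional[float] = None

    def to_row(self) -> Dict[str, object]:
        row = {"run_id": self.run_id, "seed": self.seed, "time": self.time}
        row.update(self.params)
        for key in ("I_c", "I_d", "meeting_angle_median", "rho_ext"):
            v = getattr(self, key)
            if v is not None:
                row[key] = v
        if self.fractions:
            for k, v in self.fractions.items():
                row[f"frac_{k}"] = v
        return row
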