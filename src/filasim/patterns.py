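"""Micropattern geometries: where nucleation entities live.

A pattern is a union of oriented rectangles and discs.  Presets reproduce
the geometries used in the experiments: a single nucleating bar, a V-shape
of two bars at an opening angle θ, an eight-fold star, two parallel bars at
an edge-to-edge distance d, and periodic dot lattices (square/triangular).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np


@dataclass(frozen=True)
class Rect:
    """Oriented rectangle: center, full length (along axis), width, angle (rad)."""

    center: Tuple[float, float]
    length: float
    width: float
    angle: float = 0.0
    tag: int = 0

    def __post_init__(self):
        if self.length <= 0 or self.width <= 0:
            raise ValueError("rectangle dimensions must be positive")

    @property
    def area(self) -> float:
        return self.length * self.width

    def contains(self, pts: np.ndarray) -> np.ndarray:
        """Exact point-in-rectangle test for an (n, 2) array."""
        pts = np.atleast_2d(pts)
        c, s = math.cos(self.angle), math.sin(self.angle)
        dx = pts[:, 0] - self.center[0]
        dy = pts[:, 1] - self.center[1]
        u = c * dx + s * dy
        v = -s * dx + c * dy
        return (np.abs(u) <= self.length / 2) & (np.abs(v) <= self.width / 2)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        u = rng.uniform(-self.length / 2, self.length / 2, n)
        v = rng.uniform(-self.width / 2, self.width / 2, n)
        c, s = math.cos(self.angle), math.sin(self.angle)
        return np.column_stack([self.center[0] + c * u - s * v,
                                self.center[1] + s * u + c * v])


@dataclass(frozen=True)
class Disc:
    center: Tuple[float, float]
    radius: float
    tag: int = 0

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("disc radius must be positive")

    @property
    def area(self) -> float:
        return math.pi * self.radius**2

    def contains(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        d2 = (pts[:, 0] - self.center[0]) ** 2 + (pts[:, 1] - self.center[1]) ** 2
        return d2 <= self.radius**2

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        r = self.radius * np.sqrt(rng.uniform(0, 1, n))
        phi = rng.uniform(0, 2 * math.pi, n)
        return np.column_stack([self.center[0] + r * np.cos(phi),
                                self.center[1] + r * np.sin(phi)])


@dataclass
class PatternGeometry:
    """Union of nucleating regions, optionally on a periodic domain.

    ``periodic_domain`` is ``(Lx, Ly)``: positions are identified modulo the
    box (minimum-image convention for interactions), with the box spanning
    ``[-Lx/2, Lx/2) x [-Ly/2, Ly/2)``.
    """

    regions: List[object] = field(default_factory=list)
    periodic_domain: Optional[Tuple[float, float]] = None
    name: str = "custom"

    @property
    def area(self) -> float:
        return float(sum(r.area for r in self.regions))

    @property
    def tags(self) -> List[int]:
        return sorted({r.tag for r in self.regions})

    def regions_with_tag(self, tag: int) -> List[object]:
        return [r for r in self.regions if r.tag == tag]

    def wrap(self, pts: np.ndarray) -> np.ndarray:
        """Map positions into the periodic box (identity if not periodic)."""
        if self.periodic_domain is None:
            return pts
        L = np.asarray(self.periodic_domain)
        return (pts + L / 2) % L - L / 2

    def contains(self, pts: np.ndarray) -> np.ndarray:
        pts = self.wrap(np.atleast_2d(np.asarray(pts, dtype=float)))
        inside = np.zeros(len(pts), dtype=bool)
        for r in self.regions:
            inside |= r.contains(pts)
        return inside

    def region_of(self, pts: np.ndarray) -> np.ndarray:
        """Tag of the containing region per point (-1 if outside all)."""
        pts = self.wrap(np.atleast_2d(np.asarray(pts, dtype=float)))
        out = np.full(len(pts), -1, dtype=int)
        for r in self.regions:
            m = r.contains(pts) & (out == -1)
            out[m] = r.tag
        return out

    def sample(self, n: int, rng: np.random.Generator,
               tag: Optional[int] = None) -> Tuple[np.ndarray, np.ndarray]:
        """Draw n points uniformly over the pattern area (area-weighted).

        Returns (positions (n,2), region tags (n,)).
        """
        regions = self.regions if tag is None else self.regions_with_tag(tag)
        if not regions:
            raise ValueError("pattern has no regions (zero area)")
        areas = np.array([r.area for r in regions])
        which = rng.choice(len(regions), size=n, p=areas / areas.sum())
        pts = np.empty((n, 2))
        tags = np.empty(n, dtype=int)
        for i, r in enumerate(regions):
            m = which == i
            k = int(m.sum())
            if k:
                pts[m] = r.sample(k, rng)
                tags[m] = r.tag
        return pts, tags


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def bar(length: float = 8.0, width: float = 1.0, center=(0.0, 0.0),
        angle: float = 0.0) -> PatternGeometry:
    """Single nucleating bar (the calibration pattern)."""
    return PatternGeometry([Rect(tuple(center), length, width, angle, tag=0)],
                           name="bar")


def vshape(theta_deg: float, length: float = 8.0, width: float = 1.0,
           inner_gap: Optional[float] = None) -> PatternGeometry:
    """Two bars forming a V with opening angle θ between them.

    The bisecting line is the y-axis.  Each bar is tilted by θ/2 away from
    the x-axis, mirror-symmetric about the bisector.  ``inner_gap`` is
    twice the distance of each bar's inner end from the vertex; by default
    the bars share the vertex (as the rays of the eight-fold star share
    its center), except in the near-collinear regime (θ < 5°) where a
    shared vertex would merge the bars into one — there the default is a
    4 µm separation (half a bar length), giving two distinct collinear
    bars whose networks meet in the open corridor between them.
    """
    if not (0.0 <= theta_deg <= 120.0):
        raise ValueError("vshape angle must lie in [0, 120] degrees")
    if inner_gap is None:
        inner_gap = 4.0 if theta_deg < 5.0 else 0.0
    half = math.radians(theta_deg) / 2.0
    r_in = inner_gap / 2.0
    regs = []
    for side, tag in ((+1, 0), (-1, 1)):
        ang = half if side > 0 else math.pi - half
        dx, dy = math.cos(ang), math.sin(ang)
        c = ((r_in + length / 2.0) * dx, (r_in + length / 2.0) * dy)
        regs.append(Rect(c, length, width, ang, tag=tag))
    return PatternGeometry(regs, name=f"vshape{theta_deg:g}")


def star8(length: float = 8.0, width: float = 1.0,
          inner_radius: float = 1.0) -> PatternGeometry:
    """Eight bars at 45° increments radiating from a common center."""
    regs = []
    for k in range(8):
        ang = k * math.pi / 4.0
        c = ((inner_radius + length / 2.0) * math.cos(ang),
             (inner_radius + length / 2.0) * math.sin(ang))
        regs.append(Rect(c, length, width, ang, tag=k))
    return PatternGeometry(regs, name="star8")


def parallel_bars(distance: float, length: float = 5.0, width: float = 3.0
                  ) -> PatternGeometry:
    """Two parallel horizontal bars, edge-to-edge gap = ``distance``.

    Bar 0 (the focal/measured bar) is below, bar 1 above; both have their
    long axis along x.  Centers are ``width + distance`` apart in y.
    """
    if distance < 0:
        raise ValueError("bar distance must be non-negative")
    dy = (width + distance) / 2.0
    return PatternGeometry(
        [Rect((0.0, -dy), length, width, 0.0, tag=0),
         Rect((0.0, +dy), length, width, 0.0, tag=1)],
        name=f"parallel_bars_d{distance:g}")


def lattice(kind: str = "square", spacing: float = 6.0, points: int = 8,
            repeats: int = 9, dot_radius: float = 0.4) -> PatternGeometry:
    """Periodic dot lattice: a unit of ``points`` discs tiled periodically.

    ``repeats`` must be a perfect square (tiles arranged r×r); the default
    prediction geometry uses 8 dots 6 µm apart repeated 9 times.  The unit is two
    rows of points//2 dots; the triangular variant offsets alternate rows by
    half a spacing with row distance spacing·√3/2.
    """
    if kind not in ("square", "triangular"):
        raise ValueError(f"unknown lattice kind {kind!r}")
    if points % 2 or points <= 0:
        raise ValueError("lattice unit needs an even positive dot count")
    r = int(round(math.sqrt(repeats)))
    if r * r != repeats:
        raise ValueError("repeats must be a perfect square (r x r tiling)")
    ncol = points // 2
    if kind == "square":
        row_dy, row_off = spacing, 0.0
    else:
        row_dy, row_off = spacing * math.sqrt(3) / 2.0, spacing / 2.0
    ux, uy = ncol * spacing, 2 * row_dy  # unit cell
    Lx, Ly = r * ux, r * uy
    regs = []
    tag = 0
    for ty in range(r):
        for tx in range(r):
            for row in range(2):
                for col in range(ncol):
                    x = tx * ux + col * spacing + row * row_off
                    y = ty * uy + row * row_dy
                    # map into centered box
                    x = (x + Lx / 2) % Lx - Lx / 2
                    y = (y + Ly / 2) % Ly - Ly / 2
                    regs.append(Disc((x, y), dot_radius, tag=tag))
                    tag += 1
    return PatternGeometry(regs, periodic_domain=(Lx, Ly), name=f"lattice_{kind}")


_PRESETS = {
    "bar": bar,
    "vshape": vshape,
    "star8": star8,
    "parallel_bars": parallel_bars,
    "lattice": lattice,
}


def build_geometry(spec: dict) -> PatternGeometry:
    """Build a pattern from a config block ``{"preset": name, **params}``.

    An explicit region list is also accepted:
    ``{"rects": [[cx, cy, length, width, angle_deg, tag], ...]}``.
    """
    spec = dict(spec)
    if "rects" in spec:
        regs = [Rect((r[0], r[1]), r[2], r[3], math.radians(r[4]) if len(r) > 4 else 0.0,
                     tag=int(r[5]) if len(r) > 5 else i)
                for i, r in enumerate(spec["rects"])]
        dom = spec.get("periodic_domain")
        return PatternGeometry(regs, periodic_domain=tuple(dom) if dom else None)
    name = spec.pop("preset", None)
    if name not in _PRESETS:
        raise ValueError(f"unknown geometry preset {name!r}; "
                         f"choose from {sorted(_PRESETS)}")
    if name == "vshape" and "theta_deg" not in spec:
        raise ValueError("vshape requires theta_deg")
    return _PRESETS[name](**spec)
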