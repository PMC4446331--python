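"""Simulation state and overdamped Brownian-dynamics engine.

All fibers live in flat arrays: ``X`` holds every vertex of every fiber
(vertex order: fiber 0's vertices, then fiber 1's, ...), with per-fiber
offsets.  One step of the dynamics solves

    M dx = F_explicit(x) + (gamma/dt) * xi,      M = (gamma/dt) I + A/2 + D

per coordinate axis, where ``A`` is the linearized (curvature) bending
operator, ``F_explicit`` the full nonlinear force (worm-like-chain bending,
steric pairs, entity springs), ``D`` a diagonal damping holding the local
stiffness of every engaged pair spring, and ``xi`` the thermal displacement
with per-coordinate variance 2 kBT dt / gamma.  Treating the bending
operator with a Crank-Nicolson half-step makes the scheme stable for stiff
fibers and gives exact equilibrium statistics for the linearized bending
modes at any dt; pair springs are stabilized through ``D`` (their force is
explicit, their damping implicit), which is unconditionally stable.  After
each step, segment lengths are restored to their targets by a
direction-preserving, centroid-preserving projection, growing tips are
extended at the force-dependent speed, and the terminal segment is
subdivided when it exceeds the 0.2 µm target spacing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.linalg import solve_banded
from scipy.spatial import cKDTree

from . import steric as steric_mod
from .params import SimConfig, MechParams, StericParams, EntityParams, RunParams
from .patterns import PatternGeometry, build_geometry
from .steric import pair_force, pair_spring_stiffness, SELF_EXCLUSION_SEGMENTS

LINEAGE_PRIMER = 0
LINEAGE_BRANCH = 1
LINEAGE_PRIMER_EFFECT = 2
LINEAGE_NAMES = {0: "primer", 1: "branch", 2: "primer_effect"}

#: Verlet skin added to the steric cutoff when caching neighbor pairs, µm.
#: Sized so the cache survives a few thermal steps of the fastest vertex
#: (the cached list is refreshed whenever any vertex has moved by skin/2);
#: the grid rebuild is cheap, so a tight skin that keeps the candidate
#: list small wins over a long-lived cache.
PAIR_SKIN = 0.2


class SimulationError(RuntimeError):
    """Numerical failure during integration; carries a frame snapshot."""

    def __init__(self, message: str, snapshot=None):
        super().__init__(message)
        self.snapshot = snapshot


@dataclass
class Entities:
    """State of all pattern-bound entities (anchors are fixed positions)."""

    # Arp2/3-like complexes: free until they branch, then a mother-daughter link
    arp_anchor: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    arp_tag: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    arp_spent: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    # fixed binders
    binder_anchor: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    binder_fiber: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))  # -1 unbound
    binder_vertex: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    # primer-effect entities (capper / nucleator mixture)
    primer_anchor: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    primer_tag: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    primer_is_nucleator: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    primer_used: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    # nucleator positions (used once at seeding; kept for bookkeeping)
    nucleator_anchor: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    # branch links: (mother fiber, mother vertex, daughter fiber, signed rest angle)
    link_mother: List[int] = field(default_factory=list)
    link_mvertex: List[int] = field(default_factory=list)
    link_daughter: List[int] = field(default_factory=list)
    link_angle: List[float] = field(default_factory=list)


class FiberView:
    """Read-only view of one fiber backed by the world arrays."""

    __slots__ = ("_world", "id")

    def __init__(self, world: "World", fid: int):
        self._world = world
        self.id = fid

    @property
    def vertices(self) -> np.ndarray:
        w = self._world
        s = w.offsets[self.id]
        return w.X[s:s + w.nv[self.id]].copy()

    @property
    def n_vertices(self) -> int:
        return int(self._world.nv[self.id])

    @property
    def growth_state(self) -> str:
        return "growing" if self._world.growing[self.id] else "capped"

    @property
    def lineage(self) -> str:
        return LINEAGE_NAMES[int(self._world.lineage[self.id])]

    @property
    def origin_tag(self) -> int:
        return int(self._world.origin[self.id])

    @property
    def length(self) -> float:
        w = self._world
        return (w.nv[self.id] - 2) * w.mech.segment_length + w.term_len[self.id]

    def tangents(self) -> np.ndarray:
        """Unit tangents (pointed-to-barbed) at each vertex (central diff)."""
        x = self.vertices
        t = np.empty_like(x)
        t[1:-1] = x[2:] - x[:-2]
        t[0] = x[1] - x[0]
        t[-1] = x[-1] - x[-2]
        return t / np.linalg.norm(t, axis=1, keepdims=True)


class World:
    """Complete simulation state; advanced in place by :meth:`step`/:meth:`run`."""

    def __init__(self, config: SimConfig, seed: Optional[int] = None,
                 geometry: Optional[PatternGeometry] = None):
        self.config = config
        self.mech: MechParams = config.mech
        self.steric: StericParams = config.steric
        self.entities_cfg: EntityParams = config.entities
        self.runp: RunParams = config.run
        self.geometry = geometry if geometry is not None else build_geometry(config.geometry)
        self.domain = self.geometry.periodic_domain
        self.dt = config.resolve_dt()
        self.time = 0.0
        self.seed = int(config.run.seed if seed is None else seed)
        self.rng = np.random.default_rng(self.seed)

        l0 = self.mech.segment_length
        self.l0 = l0
        self.gamma = self.mech.gamma_v
        self.K = self.mech.K

        # flat per-vertex arrays
        self.X = np.zeros((0, 2))
        # per-fiber arrays
        self.nv = np.zeros(0, dtype=int)
        self.term_len = np.zeros(0)
        self.growing = np.zeros(0, dtype=bool)
        self.lineage = np.zeros(0, dtype=int)
        self.origin = np.zeros(0, dtype=int)
        self.total_length = 0.0

        self.ent = Entities()
        self._branch_angles: List[float] = []   # realized angle at each event
        self._capture_count = 0
        self._primer_effect_count = 0
        self._pending: List[Tuple] = []   # fibers created during an event sweep

        #: use the compiled (numba) inner loop in :meth:`run`; the pure
        #: numpy :meth:`step` remains the reference implementation.
        self.use_kernel = True
        self._rebuild_topology()
        self._pairs = (np.zeros(0, dtype=np.intp), np.zeros(0, dtype=np.intp))
        self._pair_dirty = True
        self._binder_tree: Optional[cKDTree] = None
        self._seed_entities()

    # ------------------------------------------------------------------
    # construction helpers
    # ------------------------------------------------------------------
    @classmethod
    def from_fibers(cls, fibers, config: Optional[SimConfig] = None,
                    origins=None, geometry: Optional[PatternGeometry] = None,
                    growing=True) -> "World":
        """Build a world holding hand-specified fibers (no entities, no RNG
        use).  ``fibers`` is a sequence of (n, 2) vertex arrays; ``origins``
        optional per-fiber region tags."""
        if config is None:
            config = SimConfig(geometry={"rects": []},
                               entities=EntityParams(nucleators_per_region=0,
                                                     arp_per_region=0,
                                                     binder_density=0.0))
        w = cls(config, geometry=geometry)
        for k, verts in enumerate(fibers):
            verts = np.asarray(verts, dtype=float)
            if verts.ndim != 2 or len(verts) < 2:
                raise ValueError("each fiber needs at least 2 vertices")
            w.X = np.vstack([w.X, verts])
            w.nv = np.append(w.nv, len(verts))
            w.term_len = np.append(w.term_len,
                                   float(np.linalg.norm(verts[-1] - verts[-2])))
            w.growing = np.append(w.growing, bool(growing))
            w.lineage = np.append(w.lineage, LINEAGE_PRIMER)
            w.origin = np.append(w.origin,
                                 int(origins[k]) if origins is not None else 0)
        w.total_length = float(sum(
            np.linalg.norm(np.diff(np.asarray(f, dtype=float), axis=0), axis=1).sum()
            for f in fibers))
        w._rebuild_topology()
        return w

    @property
    def n_fibers(self) -> int:
        return len(self.nv)

    @property
    def n_vertices(self) -> int:
        return len(self.X)

    @property
    def fibers(self) -> List[FiberView]:
        return [FiberView(self, i) for i in range(self.n_fibers)]

    def _seed_entities(self) -> None:
        cfg = self.entities_cfg
        geo = self.geometry
        if not geo.regions:
            if cfg.nucleators_per_region or (cfg.arp_enabled and cfg.arp_per_region):
                raise ValueError("zero pattern area but nonzero entity counts")
            return
        rng = self.rng
        tags = geo.tags
        # nucleators: fixed points, one primer fiber each (uniform per region tag)
        n_nuc = cfg.nucleators_per_region
        if n_nuc:
            for tag in tags:
                pts, _ = geo.sample(n_nuc, rng, tag=tag)
                self.ent.nucleator_anchor = np.vstack([self.ent.nucleator_anchor, pts])
                for p in pts:
                    if self.n_fibers >= self.runp.fiber_budget:
                        break
                    phi = rng.uniform(0, 2 * math.pi)
                    self._append_fiber_from(p, phi, tag, LINEAGE_PRIMER,
                                            n_segments=2)
        if cfg.arp_enabled and cfg.arp_per_region:
            for tag in tags:
                pts, _ = geo.sample(cfg.arp_per_region, rng, tag=tag)
                self.ent.arp_anchor = np.vstack([self.ent.arp_anchor, pts])
                self.ent.arp_tag = np.concatenate([self.ent.arp_tag,
                                                   np.full(len(pts), tag)])
            self.ent.arp_spent = np.zeros(len(self.ent.arp_anchor), dtype=bool)
        if cfg.binders_enabled and cfg.binder_density > 0:
            n_b = max(1, int(round(cfg.binder_density * geo.area)))
            pts, _ = geo.sample(n_b, rng)
            self.ent.binder_anchor = pts
            self.ent.binder_fiber = np.full(n_b, -1, dtype=int)
            self.ent.binder_vertex = np.zeros(n_b, dtype=int)
        if cfg.primer_enabled and cfg.primer_density > 0:
            n_p = max(1, int(round(cfg.primer_density * geo.area)))
            pts, ptags = geo.sample(n_p, rng)
            self.ent.primer_anchor = pts
            self.ent.primer_tag = ptags
            self.ent.primer_is_nucleator = rng.random(n_p) < cfg.nucleation_efficiency
            self.ent.primer_used = np.zeros(n_p, dtype=bool)
        self._rebuild_topology()

    def _append_fiber_from(self, origin_pt, phi: float, tag: int, lineage: int,
                           n_segments: int = 2, first_len: Optional[float] = None,
                           growing: bool = True) -> int:
        """Append a new short fiber; caller must rebuild topology afterwards."""
        d = np.array([math.cos(phi), math.sin(phi)])
        l0 = self.l0
        if n_segments >= 2:
            verts = origin_pt + np.outer(np.arange(n_segments + 1) * l0, d)
            term = l0
        else:
            fl = first_len if first_len is not None else 0.5 * l0
            verts = np.vstack([origin_pt, origin_pt + fl * d])
            term = fl
        self.X = np.vstack([self.X, verts])
        self.nv = np.append(self.nv, len(verts))
        self.term_len = np.append(self.term_len, term)
        self.growing = np.append(self.growing, growing)
        self.lineage = np.append(self.lineage, lineage)
        self.origin = np.append(self.origin, tag)
        self.total_length += (len(verts) - 2) * l0 + term
        return self.n_fibers - 1

    def _rebuild_topology(self) -> None:
        """Recompute all index arrays derived from fiber vertex counts."""
        nv = self.nv
        N = int(nv.sum())
        self.offsets = np.concatenate([[0], np.cumsum(nv)]).astype(int)
        self.fiber_of = np.repeat(np.arange(self.n_fibers), nv)
        self.vstart = np.repeat(self.offsets[:-1], nv)      # fiber start per vertex
        self.arc_index = np.arange(N) - self.vstart         # index within fiber
        self.tips = self.offsets[1:] - 1                    # barbed-end vertex per fiber
        # interior joints (vertex with both neighbors on the same fiber)
        joint_mask = (self.arc_index >= 1) & (self.arc_index <= nv[self.fiber_of] - 2)
        self.joints = np.nonzero(joint_mask)[0]
        # linearized bending operator A = (K/l^3) D^T D (pentadiagonal,
        # isotropic); the anisotropic stretching-spring Hessian k_s t t^T
        # is assembled per step from the current segment directions.
        c = joint_mask.astype(float)
        main = 4.0 * c
        main[1:] += c[:-1]
        main[:-1] += c[1:]
        off1 = np.zeros(N)
        if N > 1:
            off1[:-1] = -2.0 * (c[:-1] + c[1:])
        off2 = np.zeros(N)
        if N > 2:
            off2[:-2] = c[1:-1]
        scale = self.K / self.l0**3
        # per-segment rest lengths (segment i connects vertex i, i+1)
        tgt = np.full(max(N - 1, 0), self.l0)
        valid = np.zeros(max(N - 1, 0), dtype=bool)
        if N > 1:
            valid = self.fiber_of[1:] == self.fiber_of[:-1]
            tgt[~valid] = 0.0
            tgt[self.tips - 1] = self.term_len
        self._seg_target = tgt
        self._seg_valid = valid
        self._A_main = scale * main
        self._A_off1 = scale * off1
        self._A_off2 = scale * off2
        self._acc = np.zeros((N, 2))
        self._pair_dirty = True

    # ------------------------------------------------------------------
    # forces
    # ------------------------------------------------------------------
    def _min_image(self, delta: np.ndarray) -> np.ndarray:
        if self.domain is not None:
            L = np.asarray(self.domain)
            delta = delta - L * np.round(delta / L)
        return delta

    def _bending_force(self, F: np.ndarray) -> None:
        """Accumulate the angle-gradient WLC bending force.

        The lever arm of each joint is clamped below at 0.7 l0 so that a
        freshly subdivided short terminal segment cannot produce a force
        spike beyond what the implicit bending operator can damp; interior
        segments sit at the rest length and are unaffected.
        """
        J = self.joints
        if len(J) == 0:
            return
        X = self.X
        a = X[J] - X[J - 1]
        b = X[J + 1] - X[J]
        cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
        dot = np.einsum("ij,ij->i", a, b)
        theta = np.arctan2(cross, dot)
        coef = self.K * theta / self.l0
        lmin2 = (0.7 * self.l0) ** 2
        a2 = np.maximum(np.einsum("ij,ij->i", a, a), lmin2)
        b2 = np.maximum(np.einsum("ij,ij->i", b, b), lmin2)
        ga = coef[:, None] * np.column_stack([-a[:, 1], a[:, 0]]) / a2[:, None]
        gb = coef[:, None] * np.column_stack([-b[:, 1], b[:, 0]]) / b2[:, None]
        N = self.n_vertices
        for idx, w in ((J - 1, -ga), (J, ga + gb), (J + 1, -gb)):
            F[:, 0] += np.bincount(idx, weights=w[:, 0], minlength=N)
            F[:, 1] += np.bincount(idx, weights=w[:, 1], minlength=N)

    def _stretch_force(self, F: np.ndarray) -> None:
        """Stretching springs holding segments at their rest lengths."""
        X = self.X
        if len(X) < 2:
            return
        seg = X[1:] - X[:-1]
        ln = np.hypot(seg[:, 0], seg[:, 1])
        np.maximum(ln, 1e-12, out=ln)
        mag = self.mech.stretch_stiffness * (ln - self._seg_target)
        mag[~self._seg_valid] = 0.0
        fvec = (mag / ln)[:, None] * seg
        F[:-1] += fvec
        F[1:] -= fvec

    def _refresh_pairs(self) -> None:
        """Rebuild the cached (interaction point, fiber segment) candidates.

        The engine's steric force acts between the discretization points of
        one fiber and the nearest point of nearby *segments* of another (a
        continuous obstacle, so a growing tip cannot slip between two
        interaction points).  Candidates come from a KD-tree point broad
        phase whose cutoff covers the worst point-to-segment geometry plus
        the Verlet skin."""
        empty = (np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64))
        if not self.steric.enabled or self.n_vertices < 2:
            self._pairs = empty
            self._pair_dirty = False
            self._acc[:] = 0.0
            return
        from ._kernels import build_candidates

        N = self.n_vertices
        reach = self.steric.dm + PAIR_SKIN
        periodic = self.domain is not None
        Lx, Ly = (float(self.domain[0]), float(self.domain[1])) if periodic \
            else (1.0, 1.0)
        if periodic and min(Lx, Ly) < 3 * (reach + 1.5 * self.l0):
            raise ValueError("periodic domain too small for the neighbor grid")
        if getattr(self, "_cand_buf", None) is None or \
                len(self._cand_buf[0]) < 96 * N:
            cap = max(4096, 96 * N)
            self._cand_buf = (np.empty(cap, dtype=np.int64),
                              np.empty(cap, dtype=np.int64))
        while True:
            out_p, out_s = self._cand_buf
            m = build_candidates(self.X, self.fiber_of, self.arc_index,
                                 self._seg_valid, reach, 1.5 * self.l0,
                                 SELF_EXCLUSION_SEGMENTS, periodic, Lx, Ly,
                                 out_p, out_s)
            if m >= 0:
                break
            cap = 2 * len(out_p)
            self._cand_buf = (np.empty(cap, dtype=np.int64),
                              np.empty(cap, dtype=np.int64))
        self._pairs = (out_p[:m], out_s[:m])
        self._pair_dirty = False
        self._acc[:] = 0.0

    def _steric_force(self, F: np.ndarray, D: np.ndarray) -> None:
        """Point-to-segment steric forces from the cached candidate list.

        Each interaction connects a fiber point P to its orthogonal
        projection Q on a nearby segment; the piecewise-linear pair force
        acts along P-Q, with the reaction distributed barycentrically to
        the segment endpoints (Newton's third law holds exactly)."""
        p, s = self._pairs
        if len(p) == 0:
            return
        X = self.X
        AB = self._min_image(X[s + 1] - X[s])
        AP = self._min_image(X[p] - X[s])
        ab2 = np.maximum(np.einsum("ij,ij->i", AB, AB), 1e-24)
        t = np.clip(np.einsum("ij,ij->i", AP, AB) / ab2, 0.0, 1.0)
        delta = AP - t[:, None] * AB          # P - Q
        d = np.hypot(delta[:, 0], delta[:, 1])
        np.maximum(d, 1e-12, out=d)
        mag = pair_force(d, self.steric)      # > 0 attractive
        fP = (-mag / d)[:, None] * delta      # force on P, toward Q if > 0
        w0 = (1.0 - t)[:, None] * fP
        w1 = t[:, None] * fP
        N = self.n_vertices
        for idx, w in ((p, fP), (s, -w0), (s + 1, -w1)):
            F[:, 0] += np.bincount(idx, weights=w[:, 0], minlength=N)
            F[:, 1] += np.bincount(idx, weights=w[:, 1], minlength=N)
        k = pair_spring_stiffness(d, self.steric)
        D += np.bincount(p, weights=k, minlength=N)
        D += np.bincount(s, weights=k * (1 - t), minlength=N)
        D += np.bincount(s + 1, weights=k * t, minlength=N)

    def _entity_forces(self, F: np.ndarray, D: np.ndarray) -> None:
        ent = self.ent
        cfg = self.entities_cfg
        # binder springs: anchored, force on the fiber only (anchor = substrate)
        bound = np.nonzero(ent.binder_fiber >= 0)[0]
        if len(bound):
            gv = self.offsets[ent.binder_fiber[bound]] + ent.binder_vertex[bound]
            delta = self._min_image(ent.binder_anchor[bound] - self.X[gv])
            np.add.at(F, gv, cfg.binder_stiffness * delta)
            np.add.at(D, gv, cfg.binder_stiffness)
        # branch links: Hookean + angular spring between mother and daughter
        if ent.link_mother:
            mf = np.asarray(ent.link_mother)
            mvx = np.asarray(ent.link_mvertex)
            df = np.asarray(ent.link_daughter)
            phi0 = np.asarray(ent.link_angle)
            gm = self.offsets[mf] + mvx
            gd = self.offsets[df]          # daughter pointed end
            delta = self._min_image(self.X[gm] - self.X[gd])
            k = cfg.arp_link_stiffness
            np.add.at(F, gd, k * delta)
            np.add.at(F, gm, -k * delta)
            np.add.at(D, gd, k)
            np.add.at(D, gm, k)
            # angular spring on (mother local segment, daughter first segment)
            ma = gm.copy()
            mb = gm + 1
            at_end = mvx >= self.nv[mf] - 1
            ma[at_end] = gm[at_end] - 1
            mb[at_end] = gm[at_end]
            a = self.X[mb] - self.X[ma]
            b = self.X[gd + 1] - self.X[gd]
            cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
            dot = np.einsum("ij,ij->i", a, b)
            phi = np.arctan2(cross, dot)
            dphi = np.arctan2(np.sin(phi - phi0), np.cos(phi - phi0))
            coef = cfg.arp_angular_stiffness * dphi
            lmin2 = (0.7 * self.l0) ** 2
            a2 = np.maximum(np.einsum("ij,ij->i", a, a), lmin2)
            b2 = np.maximum(np.einsum("ij,ij->i", b, b), lmin2)
            ga = coef[:, None] * np.column_stack([-a[:, 1], a[:, 0]]) / a2[:, None]
            gb = coef[:, None] * np.column_stack([-b[:, 1], b[:, 0]]) / b2[:, None]
            # diagonal damping of the angular spring's local stiffness
            np.add.at(D, ma, cfg.arp_angular_stiffness / a2)
            np.add.at(D, mb, cfg.arp_angular_stiffness / a2)
            np.add.at(D, gd, cfg.arp_angular_stiffness / b2)
            np.add.at(D, gd + 1, cfg.arp_angular_stiffness / b2)
            # dphi/d(ma) = +aperp/|a|^2, dphi/d(mb) = -aperp/|a|^2,
            # dphi/d(gd) = +bperp/|b|^2 ... with force = -coef * dphi/dx
            np.add.at(F, ma, -ga)
            np.add.at(F, mb, ga)
            np.add.at(F, gd, gb)
            np.add.at(F, gd + 1, -gb)

    def _pairs_stale(self) -> bool:
        if self._pair_dirty:
            return True
        if len(self._acc) == 0:
            return False
        m = float(np.einsum("ij,ij->i", self._acc, self._acc).max())
        return m > (PAIR_SKIN / 2) ** 2

    def compute_forces(self) -> Tuple[np.ndarray, np.ndarray]:
        """Total explicit force and implicit pair-damping diagonal."""
        N = self.n_vertices
        F = np.zeros((N, 2))
        D = np.zeros(N)
        self._bending_force(F)
        self._stretch_force(F)
        if self.steric.enabled:
            if self._pairs_stale():
                self._refresh_pairs()
            self._steric_force(F, D)
        self._entity_forces(F, D)
        return F, D

    def _implicit_solve(self, rhs: np.ndarray, D: np.ndarray) -> np.ndarray:
        """Solve M dx = rhs with the 2x2-block pentadiagonal matrix
        M = (gamma/dt) I + A_bend/2 + H_stretch/2 + diag(D).

        A_bend is the isotropic linearized bending operator; H_stretch is
        the anisotropic stretching Hessian (k_s along each current segment
        direction), so transverse modes feel exactly the bending operator
        and longitudinal ones the springs — keeping the Crank-Nicolson
        half-step consistent with the true force Jacobian (an isotropic
        approximation was found to suppress transverse fluctuations).
        The interleaved (x0, y0, x1, y1, ...) system has scalar bandwidth
        4 and is solved with a banded LAPACK call.
        """
        N = len(rhs)
        gamma_dt = self.gamma / self.dt
        # per-segment unit tangents
        seg = self.X[1:] - self.X[:-1]
        ln = np.hypot(seg[:, 0], seg[:, 1])
        np.maximum(ln, 1e-12, out=ln)
        t = seg / ln[:, None]
        ks2 = 0.5 * self.mech.stretch_stiffness
        v = self._seg_valid.astype(float)
        txx = ks2 * v * t[:, 0] * t[:, 0]
        txy = ks2 * v * t[:, 0] * t[:, 1]
        tyy = ks2 * v * t[:, 1] * t[:, 1]
        # diagonal blocks
        d_xx = np.full(N, gamma_dt) + 0.5 * self._A_main + D
        d_yy = d_xx.copy()
        d_xy = np.zeros(N)
        if N > 1:
            d_xx[:-1] += txx
            d_xx[1:] += txx
            d_yy[:-1] += tyy
            d_yy[1:] += tyy
            d_xy[:-1] += txy
            d_xy[1:] += txy
        # first-neighbor blocks (i, i+1): symmetric 2x2
        c1_xx = 0.5 * self._A_off1[:-1] - txx if N > 1 else np.zeros(0)
        c1_yy = 0.5 * self._A_off1[:-1] - tyy if N > 1 else np.zeros(0)
        c1_xy = -txy if N > 1 else np.zeros(0)
        # second-neighbor scalar
        c2 = 0.5 * self._A_off2[:-2] if N > 2 else np.zeros(0)
        n2 = 2 * N
        ab = np.zeros((9, n2))
        # row u+i-j (u=4) of ab holds entry (i, j); fill upper diagonals and
        # mirror (matrix symmetric)
        main = ab[4]
        main[0::2] = d_xx
        main[1::2] = d_yy
        # offset 1: (2i, 2i+1) = d_xy[i]
        ab[3, 1::2] = d_xy
        # offset 1 odd rows: (2i+1, 2i+2) = c1_xy[i]
        if N > 1:
            ab[3, 2::2] = c1_xy
            # offset 2: (2i, 2i+2) = c1_xx ; (2i+1, 2i+3) = c1_yy
            ab[2, 2::2] = c1_xx
            ab[2, 3::2] = c1_yy
            # offset 3: (2i, 2i+3) = c1_xy
            ab[1, 3::2] = c1_xy
        if N > 2:
            # offset 4: (2i, 2i+4) and (2i+1, 2i+5) = c2
            ab[0, 4::2] = c2
            ab[0, 5::2] = c2
        # lower diagonals by symmetry: ab[4+k, j] = ab[4-k, j+k]
        for k in range(1, 5):
            ab[4 + k, :n2 - k] = ab[4 - k, k:]
        b = rhs.reshape(-1)
        dx = solve_banded((4, 4), ab, b, overwrite_ab=True,
                          overwrite_b=False, check_finite=False)
        return dx.reshape(N, 2)

    # ------------------------------------------------------------------
    # one time step
    # ------------------------------------------------------------------
    def step(self) -> None:
        N = self.n_vertices
        dt = self.dt
        if N == 0:
            self.time += dt
            return
        X_before = self.X.copy()
        F, D = self.compute_forces()
        gamma_dt = self.gamma / dt
        rhs = F
        if self.mech.kBT > 0:
            xi = self.rng.standard_normal((N, 2))
            rhs = rhs + math.sqrt(2.0 * self.mech.kBT * self.gamma / dt) * xi
        dx = self._implicit_solve(rhs, D)
        self.X += dx
        # force-dependent tip growth (using the pre-step explicit tip force)
        grow = np.nonzero(self.growing)[0]
        if len(grow):
            tips = self.tips[grow]
            tan = self.X[tips] - self.X[tips - 1]
            norm = np.linalg.norm(tan, axis=1)
            np.maximum(norm, 1e-12, out=norm)
            tan /= norm[:, None]
            ft = np.einsum("ij,ij->i", F[tips], tan)
            v = self.mech.v0 * np.exp(np.clip(ft, -50.0 * self.mech.fs, 0.0)
                                      / self.mech.fs)
            if self.runp.monomer_budget is not None:
                v = v * max(0.0, 1.0 - self.total_length / self.runp.monomer_budget)
            adv = v * dt
            self.X[tips] += adv[:, None] * tan
            self.term_len[grow] += adv
            self._seg_target[tips - 1] = self.term_len[grow]
            self.total_length += float(adv.sum())
        self._acc += self.X - X_before
        self.time += dt

    def _subdivide(self) -> None:
        """Split terminal segments once they exceed 1.5 rest lengths.

        The new terminal segment then starts at >= 0.5 l0, keeping joint
        lever arms well conditioned."""
        over = np.nonzero(self.term_len > 1.5 * self.l0)[0]
        if len(over) == 0:
            return
        ins_pos = []
        ins_val = []
        for f in over:
            tip = self.tips[f]
            unit = self.X[tip] - self.X[tip - 1]
            unit /= max(np.linalg.norm(unit), 1e-12)
            new_vtx = self.X[tip - 1] + self.l0 * unit
            ins_pos.append(tip)
            ins_val.append(new_vtx)
            self.term_len[f] -= self.l0
        self.X = np.insert(self.X, ins_pos, ins_val, axis=0)
        self.nv[over] += 1
        self._rebuild_topology()

    # ------------------------------------------------------------------
    # entity events (binding, branching, capture)
    # ------------------------------------------------------------------
    def _candidate_points(self, pad: float) -> np.ndarray:
        """Indices of vertices within ``pad`` of any region's bounding box."""
        geo = self.geometry
        W = geo.wrap(self.X)
        mask = np.zeros(len(W), dtype=bool)
        for r in geo.regions:
            if hasattr(r, "length"):
                c, s = math.cos(r.angle), math.sin(r.angle)
                dx = W[:, 0] - r.center[0]
                dy = W[:, 1] - r.center[1]
                u = c * dx + s * dy
                v = -s * dx + c * dy
                mask |= (np.abs(u) <= r.length / 2 + pad) & (np.abs(v) <= r.width / 2 + pad)
            else:
                d2 = (W[:, 0] - r.center[0]) ** 2 + (W[:, 1] - r.center[1]) ** 2
                mask |= d2 <= (r.radius + pad) ** 2
        return np.nonzero(mask)[0]

    def _event_context(self):
        """Candidate vertices near the pattern and a KD-tree over them."""
        cfg = self.entities_cfg
        pad = max(cfg.binder_range, cfg.arp_binding_range, cfg.primer_range)
        cand = self._candidate_points(pad)
        ptree = None
        if len(cand):
            Wc = self.geometry.wrap(self.X[cand])
            if self.domain is not None:
                L = np.asarray(self.domain, dtype=float)
                pts = np.remainder(Wc, L)
                pts[pts >= L] = 0.0
                ptree = cKDTree(pts, boxsize=L)
            else:
                ptree = cKDTree(Wc)
        return cand, ptree

    def _wrap_anchor(self, a):
        if self.domain is None:
            return a
        L = np.asarray(self.domain, dtype=float)
        out = np.remainder(a, L)
        out[out >= L] = 0.0
        return out

    def entity_events(self, dt_event: float) -> None:
        """One sweep of stochastic entity updates over ``dt_event`` seconds.

        Order is fixed for reproducibility: binder unbinding, binder binding,
        Arp2/3 branching, primer-effect capture.  New fibers are appended at
        the end of the sweep.
        """
        ctx = self._event_context()
        self.binder_step(dt_event, _ctx=ctx)
        self.branching_step(dt_event, _ctx=ctx)
        self.primer_step(dt_event)
        self._flush_pending()

    def binder_step(self, dt_event: float, _ctx=None) -> None:
        """Stochastic binder unbinding (rate k_off) and binding (rate k_on
        to the nearest fiber point within range); detached binders keep
        their anchor and may rebind."""
        cfg = self.entities_cfg
        ent = self.ent
        rng = self.rng
        cand, ptree = self._event_context() if _ctx is None else _ctx
        have_pts = ptree is not None
        if cfg.binders_enabled and len(ent.binder_anchor):
            bound = ent.binder_fiber >= 0
            if bound.any():
                p_off = 1.0 - math.exp(-cfg.binder_k_off * dt_event)
                rel = rng.random(int(bound.sum())) < p_off
                idx = np.nonzero(bound)[0][rel]
                ent.binder_fiber[idx] = -1
            free = np.nonzero(ent.binder_fiber < 0)[0]
            if len(free) and have_pts:
                p_on = 1.0 - math.exp(-cfg.binder_k_on * dt_event)
                anchors = self._wrap_anchor(ent.binder_anchor[free])
                hits = ptree.query_ball_point(anchors, cfg.binder_range)
                roll = rng.random(len(free))
                for k, b in enumerate(free):
                    if not hits[k] or roll[k] >= p_on:
                        continue
                    local = cand[hits[k]]
                    diff = self._min_image(self.X[local] - ent.binder_anchor[b])
                    g = local[int(np.argmin(np.einsum("ij,ij->i", diff, diff)))]
                    ent.binder_fiber[b] = self.fiber_of[g]
                    ent.binder_vertex[b] = self.arc_index[g]

    def branching_step(self, dt_event: float, _ctx=None) -> None:
        """Arp2/3-like branching: free complexes bind a fiber point within
        range at rate k_on and immediately nucleate a daughter at ±70° to
        the local mother tangent (fair-coin side), pointed end at the
        branch point; the complex then becomes a Hookean + angular-spring
        link riding the mother and never branches again."""
        cfg = self.entities_cfg
        ent = self.ent
        rng = self.rng
        cand, ptree = self._event_context() if _ctx is None else _ctx
        have_pts = ptree is not None
        if cfg.arp_enabled and len(ent.arp_anchor):
            free = np.nonzero(~ent.arp_spent)[0]
            if len(free) and have_pts:
                p_on = 1.0 - math.exp(-cfg.arp_k_on * dt_event)
                anchors = self._wrap_anchor(ent.arp_anchor[free])
                hits = ptree.query_ball_point(anchors, cfg.arp_binding_range)
                roll = rng.random(len(free))
                sides = rng.random(len(free))  # fair coin per potential event
                for k, a in enumerate(free):
                    if not hits[k] or roll[k] >= p_on:
                        continue
                    if self.n_fibers + len(self._pending) >= self.runp.fiber_budget:
                        break
                    local = cand[hits[k]]
                    diff = self.X[local] - ent.arp_anchor[a]
                    g = local[int(np.argmin(np.einsum("ij,ij->i", diff, diff)))]
                    mf = int(self.fiber_of[g])
                    mvx = int(self.arc_index[g])
                    # mother tangent, pointed-to-barbed, at the attachment
                    if mvx < self.nv[mf] - 1:
                        tvec = self.X[g + 1] - self.X[g]
                    else:
                        tvec = self.X[g] - self.X[g - 1]
                    mphi = math.atan2(tvec[1], tvec[0])
                    side = 1.0 if sides[k] < 0.5 else -1.0
                    phi0 = side * math.radians(cfg.branch_angle_deg)
                    self._pending.append(("branch", self.X[g].copy(),
                                          mphi + phi0, int(self.origin[mf]),
                                          mf, mvx, phi0))
                    ent.arp_spent[a] = True
        if _ctx is None:
            self._flush_pending()

    def primer_step(self, dt_event: float = 0.0) -> None:
        """Primer-effect capture of foreign growing barbed ends.

        Under the entanglement hypothesis H1 (nucleation efficiency 0) any
        growing barbed end whose origin differs from the region it enters
        is capped unconditionally ("filaments stop growing").  Under the
        nucleation hypothesis H2 capture is mediated by the discrete
        entities: the first unused entity within range caps the end, and
        nucleator-type entities (mixture fraction = efficiency)
        additionally create a primer_effect fiber at the capture site;
        ends that thread between entities keep growing and may cross the
        pattern.  Capture is immediate on contact (``dt_event`` unused)."""
        cfg = self.entities_cfg
        ent = self.ent
        rng = self.rng
        geo = self.geometry
        if cfg.primer_enabled and cfg.nucleation_efficiency == 0.0:
            grow = np.nonzero(self.growing)[0]
            if len(grow):
                tips = self.tips[grow]
                tip_tag = geo.region_of(self.X[tips])
                foreign = (tip_tag >= 0) & (tip_tag != self.origin[grow])
                caught = grow[foreign]
                self.growing[caught] = False
                self._capture_count += len(caught)
            return
        if cfg.primer_enabled and len(ent.primer_anchor):
            grow = np.nonzero(self.growing)[0]
            if len(grow):
                tips = self.tips[grow]
                tip_tag = geo.region_of(self.X[tips])
                foreign = (tip_tag >= 0) & (tip_tag != self.origin[grow])
                cand_f = np.nonzero(foreign)[0]
                if len(cand_f):
                    avail = ~ent.primer_used
                    etree = cKDTree(ent.primer_anchor[avail]) if avail.any() else None
                    eidx = np.nonzero(avail)[0]
                    for k in cand_f:
                        if etree is None:
                            break
                        f = grow[k]
                        tippos = geo.wrap(self.X[self.tips[f]][None, :])[0]
                        near = etree.query_ball_point(tippos, cfg.primer_range)
                        near = [n for n in near
                                if ent.primer_tag[eidx[n]] == tip_tag[k]
                                and not ent.primer_used[eidx[n]]]
                        if not near:
                            continue
                        d2 = [float(np.sum((ent.primer_anchor[eidx[n]] - tippos) ** 2))
                              for n in near]
                        e = eidx[near[int(np.argmin(d2))]]
                        ent.primer_used[e] = True
                        self.growing[f] = False
                        self._capture_count += 1
                        if (ent.primer_is_nucleator[e]
                                and self.n_fibers + len(self._pending) < self.runp.fiber_budget):
                            phi = rng.uniform(0, 2 * math.pi)
                            self._pending.append(
                                ("primer_effect", ent.primer_anchor[e].copy(),
                                 phi, int(ent.primer_tag[e]), -1, -1, 0.0))
                            self._primer_effect_count += 1
        self._flush_pending()

    def _flush_pending(self) -> None:
        if not self._pending:
            return
        for kind, pos, phi, tag, mf, mvx, phi0 in self._pending:
            if kind == "branch":
                fid = self._append_fiber_from(pos, phi, tag, LINEAGE_BRANCH,
                                              n_segments=1,
                                              first_len=0.5 * self.l0)
                self.ent.link_mother.append(mf)
                self.ent.link_mvertex.append(mvx)
                self.ent.link_daughter.append(fid)
                self.ent.link_angle.append(phi0)
                # measure the realized unsigned mother-daughter angle now
                gm = self.offsets[mf] + mvx
                if mvx < self.nv[mf] - 1:
                    a = self.X[gm + 1] - self.X[gm]
                else:
                    a = self.X[gm] - self.X[gm - 1]
                b = self.X[-1] - self.X[-2]   # daughter's first segment
                cosang = float(np.dot(a, b)
                               / (np.linalg.norm(a) * np.linalg.norm(b)))
                self._branch_angles.append(
                    math.degrees(math.acos(max(-1.0, min(1.0, cosang)))))
            else:
                self._append_fiber_from(pos, phi, tag, LINEAGE_PRIMER_EFFECT,
                                        n_segments=2)
        self._pending.clear()
        self._rebuild_topology()

    # ------------------------------------------------------------------
    # run loop
    # ------------------------------------------------------------------
    def _advance_block_kernel(self, k: int) -> None:
        """Advance k steps through the compiled inner loop."""
        from ._kernels import advance_block

        N = self.n_vertices
        dt = self.dt
        if N == 0:
            self.time += k * dt
            return
        if self.mech.kBT > 0:
            xi = self.rng.standard_normal((k, N, 2))
            coeff = math.sqrt(2.0 * self.mech.kBT * self.gamma / dt)
        else:
            xi = np.zeros((1, N, 2))
            coeff = 0.0
        ent = self.ent
        cfg = self.entities_cfg
        bound = np.nonzero(ent.binder_fiber >= 0)[0]
        b_gv = (self.offsets[ent.binder_fiber[bound]]
                + ent.binder_vertex[bound]).astype(np.intp)
        b_ax = np.ascontiguousarray(ent.binder_anchor[bound, 0]) if len(bound) \
            else np.zeros(0)
        b_ay = np.ascontiguousarray(ent.binder_anchor[bound, 1]) if len(bound) \
            else np.zeros(0)
        if ent.link_mother:
            mf = np.asarray(ent.link_mother)
            mvx = np.asarray(ent.link_mvertex)
            lk_gm = (self.offsets[mf] + mvx).astype(np.intp)
            lk_gd = self.offsets[np.asarray(ent.link_daughter)].astype(np.intp)
            at_end = mvx >= self.nv[mf] - 1
            lk_ma = np.where(at_end, lk_gm - 1, lk_gm).astype(np.intp)
            lk_mb = np.where(at_end, lk_gm, lk_gm + 1).astype(np.intp)
            lk_phi0 = np.asarray(ent.link_angle, dtype=float)
        else:
            lk_gm = lk_gd = lk_ma = lk_mb = np.zeros(0, dtype=np.intp)
            lk_phi0 = np.zeros(0)
        periodic = self.domain is not None
        Lx, Ly = (float(self.domain[0]), float(self.domain[1])) if periodic \
            else (0.0, 0.0)
        monomer_cap = float(self.runp.monomer_budget or 0.0)
        done = 0
        while done < k:
            if self.steric.enabled and self._pairs_stale():
                self._refresh_pairs()
            sd, tl = advance_block(
                self.X, self._acc, self.offsets[:-1], self.nv, self.term_len,
                self.growing, self.joints,
                0.5 * self._A_main, 0.5 * self._A_off1, 0.5 * self._A_off2,
                self.K, self.l0, self.mech.stretch_stiffness,
                self.gamma, dt, coeff,
                self._pairs[0], self._pairs[1], bool(self.steric.enabled),
                self.steric.K_push, self.steric.K_pull,
                self.steric.d0, self.steric.dm,
                periodic, Lx, Ly,
                b_gv, b_ax, b_ay, float(cfg.binder_stiffness),
                lk_gm, lk_gd, lk_ma, lk_mb,
                float(cfg.arp_link_stiffness), float(cfg.arp_angular_stiffness),
                lk_phi0,
                self.mech.v0, self.mech.fs, monomer_cap, self.total_length,
                xi[done:] if coeff > 0 else xi, k - done, PAIR_SKIN / 2)
            self.total_length = tl
            done += sd
            self.time += sd * dt
        # keep the terminal-segment targets in sync for metrics/reference path
        if len(self.tips):
            self._seg_target[self.tips - 1] = self.term_len

    def run(self, duration: Optional[float] = None,
            callback=None, callback_interval: Optional[float] = None) -> "World":
        """Advance the world by ``duration`` seconds (default: config value).

        ``callback(world)`` is invoked every ``callback_interval`` seconds of
        simulated time (and once at the end).
        """
        duration = self.runp.duration if duration is None else duration
        t_end = self.time + duration
        ev_dt = self.runp.event_interval
        steps_per_block = max(1, int(round(ev_dt / self.dt)))
        next_cb = self.time + (callback_interval or np.inf)
        if callback is not None and callback_interval is not None:
            callback(self)
        n_steps_total = int(round(duration / self.dt))
        done = 0
        while done < n_steps_total:
            k = min(steps_per_block, n_steps_total - done)
            if self.use_kernel:
                self._advance_block_kernel(k)
            else:
                for _ in range(k):
                    self.step()
            done += k
            if not np.isfinite(self.X).all():
                raise SimulationError(
                    f"non-finite vertex position at t={self.time:.4f}s "
                    f"(dt={self.dt}, {self.n_fibers} fibers)",
                    snapshot=self.snapshot())
            self._subdivide()
            self.entity_events(k * self.dt)
            if callback is not None and self.time >= next_cb - 1e-9:
                callback(self)
                next_cb += callback_interval
        if callback is not None and callback_interval is not None:
            callback(self)
        return self

    # ------------------------------------------------------------------
    # observables
    # ------------------------------------------------------------------
    def snapshot(self) -> List[dict]:
        """Plain-data frame: one record per fiber."""
        out = []
        for f in range(self.n_fibers):
            s = self.offsets[f]
            out.append({
                "id": f,
                "lineage": LINEAGE_NAMES[int(self.lineage[f])],
                "origin_tag": int(self.origin[f]),
                "growing": bool(self.growing[f]),
                "vertices": self.X[s:s + self.nv[f]].copy(),
            })
        return out

    def fiber_vertices(self, f: int) -> np.ndarray:
        s = self.offsets[f]
        return self.X[s:s + self.nv[f]]

    def vertex_tangents(self) -> np.ndarray:
        """Unit tangent (pointed-to-barbed) at every vertex, flat array."""
        X = self.X
        N = len(X)
        t = np.zeros((N, 2))
        arc = self.arc_index
        last = self.nv[self.fiber_of] - 1
        interior = (arc > 0) & (arc < last)
        t[interior] = X[np.nonzero(interior)[0] + 1] - X[np.nonzero(interior)[0] - 1]
        first = arc == 0
        t[first] = X[np.nonzero(first)[0] + 1] - X[np.nonzero(first)[0]]
        endm = arc == last
        t[endm] = X[np.nonzero(endm)[0]] - X[np.nonzero(endm)[0] - 1]
        n = np.linalg.norm(t, axis=1, keepdims=True)
        np.maximum(n, 1e-12, out=n)
        return t / n

    @property
    def branch_angles(self) -> np.ndarray:
        """Unsigned mother-daughter angles (deg) recorded at creation."""
        return np.asarray(self._branch_angles)

    def realized_branch_angles(self) -> np.ndarray:
        """Current unsigned mother-daughter angle (deg) at every branch link."""
        ent = self.ent
        if not ent.link_mother:
            return np.zeros(0)
        out = []
        for mf, mvx, df in zip(ent.link_mother, ent.link_mvertex, ent.link_daughter):
            gm = self.offsets[mf] + mvx
            if mvx < self.nv[mf] - 1:
                a = self.X[gm + 1] - self.X[gm]
            else:
                a = self.X[gm] - self.X[gm - 1]
            gd = self.offsets[df]
            b = self.X[gd + 1] - self.X[gd]
            cosang = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
            out.append(math.degrees(math.acos(np.clip(cosang, -1, 1))))
        return np.asarray(out)

    @property
    def capture_count(self) -> int:
        return self._capture_count

    @property
    def primer_effect_count(self) -> int:
        return self._primer_effect_count


def make_world(config: SimConfig, seed: Optional[int] = None) -> World:
    return World(config, seed=seed)
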