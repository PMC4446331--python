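"""Physical and numerical parameters of the fiber simulation.

Units throughout the package: lengths in micrometers (µm), forces in
piconewtons (pN), time in seconds (s).  Bending stiffness K is tied to the
persistence length through K = kBT · Lp (the 2D tangent-correlation
convention exp(-s / 2 Lp) follows from this, see :mod:`filasim.mechanics`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

#: Boltzmann constant times room temperature, pN·µm.
KBT_ROOM = 4.2e-3

#: Discretization spacing of fiber vertices / steric interaction points, µm.
SEGMENT_LENGTH = 0.2


@dataclass
class MechParams:
    """Mechanical parameters of semiflexible growing fibers.

    Attributes
    ----------
    kBT : float
        Thermal energy, pN·µm.  Set to 0 for athermal (noise-free) runs.
    drag_per_length : float
        Isotropic drag coefficient per unit fiber length, pN·s/µm².  The
        per-vertex drag is ``drag_per_length * segment_length``.
    dt : float or None
        Integration time step, s.  ``None`` selects a step automatically
        from the stiffest explicitly-treated interaction (see
        :meth:`resolve_dt`).
    Lp : float
        Persistence length, µm.  Bending stiffness is ``K = kBT * Lp``.
    v0 : float
        Unloaded barbed-end elongation speed, µm/s.
    fs : float
        Force sensitivity of growth, pN: an antagonistic tip force f·t < 0
        reduces the speed to ``v0 * exp(f·t / fs)``.
    segment_length : float
        Rest distance between consecutive vertices, µm.
    stretch_stiffness : float
        Spring constant holding segments at their rest length, pN/µm.  At
        100 pN/µm thermal length fluctuations are ~3% of the segment
        length; the stretching springs keep the chain (near-)inextensible
        while preserving the exact Boltzmann statistics of the joint
        angles (a hard length constraint imposed by post-step projection
        was found to distort the angular equilibrium).
    """

    kBT: float = KBT_ROOM
    drag_per_length: float = 1.0
    dt: Optional[float] = None
    Lp: float = 15.0
    v0: float = 0.033
    fs: float = 0.8
    segment_length: float = SEGMENT_LENGTH
    stretch_stiffness: float = 100.0

    def __post_init__(self) -> None:
        for name in ("drag_per_length", "Lp", "v0", "fs", "segment_length",
                     "stretch_stiffness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"MechParams.{name} must be strictly positive")
        if self.kBT < 0:
            raise ValueError("MechParams.kBT must be non-negative")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("MechParams.dt must be positive (or None for auto)")

    @property
    def K(self) -> float:
        """Bending stiffness K = kBT·Lp, pN·µm² (uses room kBT if athermal)."""
        kBT = self.kBT if self.kBT > 0 else KBT_ROOM
        return kBT * self.Lp

    @property
    def gamma_v(self) -> float:
        """Per-vertex drag coefficient, pN·s/µm."""
        return self.drag_per_length * self.segment_length

    def resolve_dt(self, max_pair_stiffness: float = 0.0) -> float:
        """Return the actual time step.

        Bending is integrated implicitly and does not constrain ``dt``; the
        explicitly-treated pair interactions (steric, springs handled on the
        right-hand side) require ``k * dt / gamma_v`` to stay below ~0.5 for
        accuracy.  A 10 ms default is used when nothing is stiffer.
        """
        if self.dt is not None:
            if max_pair_stiffness > 0 and self.dt > 2.0 * self.gamma_v / max_pair_stiffness:
                raise ValueError(  # explicit pair forces would be unstable
                    f"dt={self.dt} unstable for pair stiffness "
                    f"{max_pair_stiffness} pN/µm with per-vertex drag "
                    f"{self.gamma_v} pN·s/µm (need dt <= "
                    f"{2.0 * self.gamma_v / max_pair_stiffness:.3g} s)"
                )
            return self.dt
        dt = 1e-2
        if max_pair_stiffness > 0:
            dt = min(dt, 0.5 * self.gamma_v / max_pair_stiffness)
        return dt


@dataclass
class StericParams:
    """Piecewise-linear effective fiber–fiber interaction.

    The pair force between two interaction points at distance d is
    ``K_push (d - d0)`` for d < d0 (repulsive), ``K_pull (d - d0)`` for
    d0 <= d <= dm (attractive) and zero beyond dm.  The calibrated set is
    K_push = 7.5 pN/µm, K_pull = 0.5 pN/µm with an effective fiber diameter
    d0 = 0.1 µm and a maximal range dm = 0.2 µm (i.e. dr = 0.05 µm with
    dm = d0 + 2 dr).
    """

    K_push: float = 7.5
    K_pull: float = 0.5
    d0: float = 0.1
    dm: float = 0.2
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.K_push < 0 or self.K_pull < 0:
            raise ValueError("steric stiffnesses must be non-negative")
        if not (0 < self.d0 < self.dm):
            raise ValueError("require 0 < d0 < dm")

    @property
    def dr(self) -> float:
        """Half-width of the attractive shell: dm = d0 + 2·dr."""
        return (self.dm - self.d0) / 2.0

    @classmethod
    def from_dr(cls, dr: float, d0: float = 0.1, **kw) -> "StericParams":
        return cls(d0=d0, dm=d0 + 2.0 * dr, **kw)


@dataclass
class EntityParams:
    """Densities, rates and stiffnesses of the pattern-bound entities.

    The rates and spring constants are not measured quantities; they are
    effective values chosen so that binders confine the network to the
    pattern and branches stay attached, and they are surfaced here so any
    run records them.
    """

    # fixed nucleators: each creates one 2-segment primer fiber at t = 0
    nucleators_per_region: int = 10
    # Arp2/3-like complexes: bind a passing fiber, nucleate one daughter at 70 deg
    arp_per_region: int = 160
    arp_k_on: float = 10.0          # 1/s while a fiber point is in range
    arp_binding_range: float = 0.1  # µm
    arp_link_stiffness: float = 100.0   # pN/µm, mother-daughter Hookean link
    arp_angular_stiffness: float = 0.5  # pN·µm/rad, branch-angle spring
    branch_angle_deg: float = 70.0
    # fixed binders: transient anchored Hookean springs (pattern friction)
    binder_density: float = 25.0    # anchors per µm² of pattern area
    binder_k_on: float = 10.0       # 1/s while a fiber point is in range
    binder_k_off: float = 0.5       # 1/s
    binder_range: float = 0.1       # µm
    binder_stiffness: float = 100.0  # pN/µm
    # primer-effect entities (parallel-bars experiment).  Under H1
    # (efficiency 0) entanglement is absolute: any foreign barbed end
    # entering the region is capped.  Under H2 capture is entity-based, so
    # a minority of ends thread between entities and cross the pattern
    # ("cross and/or nucleate").
    primer_density: float = 20.0    # entities per µm² of pattern area
    primer_range: float = 0.1       # µm
    nucleation_efficiency: float = 0.0  # fraction of entities that re-nucleate
    primer_enabled: bool = False
    binders_enabled: bool = True
    arp_enabled: bool = True


@dataclass
class RunParams:
    """Duration, budget and bookkeeping intervals of a simulation run."""

    duration: float = 250.0       # s
    seed: int = 0
    fiber_budget: int = 170       # hard cap on the total number of fibers
    event_interval: float = 0.1   # s between entity binding/nucleation sweeps
    frame_interval: Optional[float] = None  # s between stored frames (None: end only)
    monomer_budget: Optional[float] = None  # total polymer length cap, µm (None: off)


@dataclass
class SimConfig:
    """Complete configuration of one simulation run."""

    geometry: dict = field(default_factory=lambda: {"preset": "bar", "length": 8.0, "width": 1.0})
    mech: MechParams = field(default_factory=MechParams)
    steric: StericParams = field(default_factory=StericParams)
    entities: EntityParams = field(default_factory=EntityParams)
    run: RunParams = field(default_factory=RunParams)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        kw = {}
        if "geometry" in d:
            kw["geometry"] = dict(d["geometry"])
        for key, typ in (("mech", MechParams), ("steric", StericParams),
                         ("entities", EntityParams), ("run", RunParams)):
            if key in d:
                val = d[key]
                kw[key] = val if isinstance(val, typ) else typ(**val)
        unknown = set(d) - {"geometry", "mech", "steric", "entities", "run"}
        if unknown:
            raise ValueError(f"unknown config blocks: {sorted(unknown)}")
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def resolve_dt(self) -> float:
        stiff = 0.0
        if self.steric.enabled:
            stiff = max(self.steric.K_push, self.steric.K_pull)
        return self.mech.resolve_dt(stiff)


def spawn_rng(seed: int, *keys: int) -> np.random.Generator:
    """Deterministically derive an independent RNG stream from a base seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, keys)]))
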