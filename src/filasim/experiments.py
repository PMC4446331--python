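"""Scripted in-silico experiments: calibration, V-shape sweeps, the
primer-effect assay, ablations and lattice predictions.

Every run's seed is derived deterministically from (base seed, cell,
replicate), so sweeps are idempotent: re-running a cell reproduces its rows
bit for bit.  Default problem sizes are "desk scale" (reduced fiber budgets
and replicate counts at unchanged physics); the ``scale`` argument
multiplies fiber budgets for larger runs.
"""

from __future__ import annotations

import itertools
import math
import zlib
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .params import SimConfig, MechParams, StericParams, EntityParams, RunParams, spawn_rng
from .patterns import PatternGeometry, Rect, bar, vshape, star8, parallel_bars, lattice
from .world import World, LINEAGE_PRIMER_EFFECT
from . import quantify as Q


# ---------------------------------------------------------------------------
# configuration builders
# ---------------------------------------------------------------------------

def bar_config(length: float = 8.0, width: float = 1.0, budget: int = 170,
               duration: float = 250.0, Lp: float = 15.0,
               K_push: float = 7.5, K_pull: float = 0.5,
               nucleators: int = 10, seed: int = 0, **mech_over) -> SimConfig:
    """Calibration-bar run (desk-scale default: 170 fibers, a third of the
    full 510-fiber budget)."""
    return SimConfig(
        geometry={"preset": "bar", "length": length, "width": width},
        mech=MechParams(Lp=Lp, **mech_over),
        steric=StericParams(K_push=K_push, K_pull=K_pull),
        entities=EntityParams(nucleators_per_region=nucleators,
                              arp_per_region=budget),
        run=RunParams(duration=duration, seed=seed, fiber_budget=budget),
    )


def vshape_config(theta_deg: float, Lp: float = 15.0, fibers_per_bar: int = 120,
                  bar_length: float = 8.0, bar_width: float = 1.0,
                  inner_gap: Optional[float] = None, duration: float = 250.0,
                  nucleators: int = 8, seed: int = 0) -> SimConfig:
    budget = 2 * fibers_per_bar
    return SimConfig(
        geometry={"preset": "vshape", "theta_deg": theta_deg,
                  "length": bar_length, "width": bar_width,
                  "inner_gap": inner_gap},
        mech=MechParams(Lp=Lp),
        steric=StericParams(),
        entities=EntityParams(nucleators_per_region=nucleators,
                              arp_per_region=fibers_per_bar),
        run=RunParams(duration=duration, seed=seed, fiber_budget=budget),
    )


def primer_config(distance: float, efficiency: float, fibers_per_bar: int = 45,
                  bar_length: float = 5.0, bar_width: float = 3.0,
                  duration: float = 500.0, nucleators: int = 6,
                  seed: int = 0) -> SimConfig:
    """Two parallel bars at edge-to-edge gap ``distance``; primer-effect
    entities with the given nucleation efficiency (H1 = cappers only,
    efficiency 0)."""
    budget = int(4 * fibers_per_bar)  # headroom for primer-effect fibers
    return SimConfig(
        geometry={"preset": "parallel_bars", "distance": distance,
                  "length": bar_length, "width": bar_width},
        mech=MechParams(Lp=15.0),
        steric=StericParams(),
        entities=EntityParams(nucleators_per_region=nucleators,
                              arp_per_region=fibers_per_bar,
                              primer_enabled=True,
                              nucleation_efficiency=efficiency),
        run=RunParams(duration=duration, seed=seed, fiber_budget=budget),
    )


# ---------------------------------------------------------------------------
# single runs
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    world: World
    frames: List[Tuple[float, list]] = field(default_factory=list)

    @property
    def final_frame(self) -> list:
        return self.frames[-1][1] if self.frames else self.world.snapshot()


def run_simulation(config: SimConfig, seed: Optional[int] = None,
                   frame_times: Optional[Sequence[float]] = None) -> SimResult:
    """Run one simulation to its configured duration, storing snapshot
    frames at the requested times (always including the final state)."""
    world = World(config, seed=seed)
    res = SimResult(world=world)
    times = sorted(frame_times or [])
    if config.run.duration <= 0:
        res.frames.append((0.0, world.snapshot()))
        return res
    prev = 0.0
    for t in times:
        if t <= prev or t > config.run.duration:
            continue
        world.run(t - prev)
        res.frames.append((world.time, world.snapshot()))
        prev = t
    if prev < config.run.duration:
        world.run(config.run.duration - prev)
        res.frames.append((world.time, world.snapshot()))
    return res


# ---------------------------------------------------------------------------
# steric calibration sweep (bar pattern)
# ---------------------------------------------------------------------------

K_PUSH_GRID = (0.75, 7.5, 75.0)
K_PULL_GRID = (0.05, 0.5, 5.0)
CALIBRATED = {"K_push": 7.5, "K_pull": 0.5}


def run_calibration_sweep(K_push_values: Sequence[float] = K_PUSH_GRID,
                          K_pull_values: Sequence[float] = K_PULL_GRID,
                          replicates: int = 10, seed: int = 0,
                          bar_length: float = 8.0, budget: int = 170,
                          duration: float = 250.0,
                          reference_cell: Tuple[float, float] = (7.5, 0.5),
                          ks_tests: bool = True) -> pd.DataFrame:
    """Steric-parameter grid on the bar pattern: I_c and I_d per run, plus a
    Kolmogorov-Smirnov comparison of every cell against the calibrated
    reference cell's distribution."""
    rows = []
    for (kpush, kpull), rep in itertools.product(
            itertools.product(K_push_values, K_pull_values), range(replicates)):
        run_seed = int(spawn_rng(seed, int(kpush * 100), int(kpull * 100), rep)
                       .integers(2**31))
        cfg = bar_config(length=bar_length, budget=budget, duration=duration,
                         K_push=kpush, K_pull=kpull, seed=run_seed)
        world = run_simulation(cfg).world
        geo = world.geometry
        # fixed field of view: the metrics compare intensity distributions,
        # so the image extent must not depend on how far fibers happened
        # to reach
        half = bar_length / 2.0 + 5.0
        img = Q.render_density(world, pixel_size=0.2, blur_sigma=0.2,
                               extent=(-half, half, -5.0, 5.0))
        ic = Q.corner_intensity_ratio(img, geo)
        ctr, axes = Q.default_ellipse(geo.regions[0], margin=2.5)
        try:
            idv = Q.ellipse_intensity_deviation(img, ctr, axes)
        except ValueError:
            idv = np.nan      # nothing reached the ellipse
        rows.append({"K_push": kpush, "K_pull": kpull, "replicate": rep,
                     "seed": run_seed, "I_c": ic, "I_d": idv})
    df = pd.DataFrame(rows)
    if ks_tests and len(df):
        ref = df[(df.K_push == reference_cell[0]) & (df.K_pull == reference_cell[1])]
        if len(ref) >= 5:
            for metric in ("I_c", "I_d"):
                pvals = {}
                for (kpush, kpull), sub in df.groupby(["K_push", "K_pull"]):
                    try:
                        _, p = Q.ks_test(sub[metric], ref[metric])
                    except ValueError:
                        p = np.nan
                    pvals[(kpush, kpull)] = p
                df[f"ks_p_{metric}"] = [pvals[(r.K_push, r.K_pull)]
                                        for r in df.itertuples()]
    return df


# ---------------------------------------------------------------------------
# V-shape angle/rigidity sweeps and the length-ratio experiment
# ---------------------------------------------------------------------------

def run_vshape_cell(theta_deg: float, Lp: float, seed: int,
                    fibers_per_bar: int = 120, bar_length: float = 8.0,
                    duration: float = 250.0, geometry_scale: float = 1.0,
                    contact_radius: Optional[float] = None) -> Dict[str, object]:
    """One V-shape run; returns orientation fractions and meeting angles.

    ``geometry_scale`` shrinks the pattern, the primer length and the run
    duration together (used by the length sweep, where fiber length L,
    pattern size and simulated time co-vary)."""
    g = geometry_scale
    gap = None if g == 1.0 else (4.0 * g if theta_deg < 5.0 else 0.0)
    width = max(0.3, 1.0 * g)
    cfg = vshape_config(theta_deg, Lp=Lp, fibers_per_bar=fibers_per_bar,
                        bar_length=bar_length * g, bar_width=width,
                        inner_gap=gap, duration=duration, seed=seed)
    world = run_simulation(cfg).world
    fr = Q.median_line_fractions(world)
    # for (near-)collinear bars the stretch of the bisector between the
    # patterns is the gap corridor; away from it the two fans merge in
    # open space regardless of the pattern construction.  For an opened V
    # the whole bisector lies between the rays (the wedge and its
    # continuation below the vertex, where the networks also interleave).
    interval = (-width / 2 - 1.0, width / 2 + 1.0) if theta_deg < 5.0 else None
    ang = Q.meeting_angles(world, contact_radius=contact_radius,
                           line_interval=interval)
    return {"theta_deg": theta_deg, "Lp": Lp, "seed": seed,
            "fractions": fr, "meeting_angles": ang,
            "fiber_count": world.n_fibers}


def run_vshape_sweep(thetas: Sequence[float] = (0.0, 45.0, 90.0),
                     Lps: Sequence[float] = (2.0, 15.0, 1000.0),
                     replicates: int = 2, seed: int = 0,
                     fibers_per_bar: int = 120, bar_length: float = 8.0,
                     duration: float = 250.0) -> pd.DataFrame:
    """Angle × rigidity sweep: orientation fractions on the bisecting line
    and meeting-angle summaries per cell."""
    rows = []
    for theta, Lp, rep in itertools.product(thetas, Lps, range(replicates)):
        run_seed = int(spawn_rng(seed, int(theta * 10), int(Lp * 10), rep)
                       .integers(2**31))
        cell = run_vshape_cell(theta, Lp, run_seed, fibers_per_bar=fibers_per_bar,
                               bar_length=bar_length, duration=duration)
        ang = cell["meeting_angles"]
        rows.append({"theta_deg": theta, "Lp": Lp, "replicate": rep,
                     "seed": run_seed,
                     "frac_parallel": cell["fractions"]["parallel"],
                     "frac_antiparallel": cell["fractions"]["antiparallel"],
                     "frac_other": cell["fractions"]["other"],
                     "n_crossings": cell["fractions"]["n"],
                     "meeting_angle_median": float(np.median(ang)) if len(ang) else np.nan,
                     "n_meetings": len(ang)})
    return pd.DataFrame(rows)


def run_length_ratio_cells(theta_deg: float = 45.0, seed: int = 0,
                           replicates: int = 2, fibers_per_bar: int = 60,
                           Lp_pair: Tuple[float, float] = (15.0, 5.0),
                           duration_stiff: float = 150.0
                           ) -> pd.DataFrame:
    """Two cells matched in r = Lp/L: the collective organization should
    depend on Lp and fiber length only through their ratio, so the
    parallel fractions of the matched cells should agree.

    The stiff cell runs at (Lp1, standard geometry); the soft cell scales
    geometry, primer length and duration by Lp2/Lp1, which scales the final
    fiber length L by the same factor and leaves r unchanged.
    """
    Lp1, Lp2 = Lp_pair
    g = Lp2 / Lp1
    rows = []
    for name, Lp, gs, dur in (("stiff", Lp1, 1.0, duration_stiff),
                              ("soft", Lp2, g, duration_stiff * g)):
        for rep in range(replicates):
            run_seed = int(spawn_rng(seed, int(Lp * 10), rep).integers(2**31))
            cell = run_vshape_cell(theta_deg, Lp, run_seed,
                                   fibers_per_bar=fibers_per_bar,
                                   geometry_scale=gs, duration=dur,
                                   contact_radius=None)
            rows.append({"cell": name, "Lp": Lp, "geometry_scale": gs,
                         "replicate": rep, "seed": run_seed,
                         "frac_parallel": cell["fractions"]["parallel"],
                         "frac_antiparallel": cell["fractions"]["antiparallel"],
                         "n_crossings": cell["fractions"]["n"]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# primer-effect experiment (two parallel bars)
# ---------------------------------------------------------------------------

D_INF = 10.0  # µm: bars at this gap are considered isolated (simulation)


def run_primer_replicate(distance: float, efficiency: float, seed: int,
                         fibers_per_bar: int = 45, bar_length: float = 5.0,
                         duration: float = 500.0, strip_distance: float = 7.0,
                         strip_width: float = 1.0,
                         control_frames: Optional[Tuple[float, float]] = None
                         ) -> Dict[str, float]:
    """One primer-effect run plus its paired control (same seed, d = d_inf).

    The outer intensity sums both bars' outer-side strips (the two bars
    are statistically equivalent, and pooling them halves the chance of an
    empty strip at t_i in small desk-scale runs); t_i is 60% of the run so
    the strip is populated, t_f the end.  Each intensity is averaged over
    three closely spaced frames to suppress the shot noise of individual
    bundle tips crossing the strip boundary."""
    t_i, t_f = 0.6 * duration, duration

    def _intensities(dist):
        cfg = primer_config(dist, efficiency, fibers_per_bar=fibers_per_bar,
                            bar_length=bar_length, duration=duration, seed=seed)
        ti_times = [t_i - 0.1 * duration, t_i - 0.05 * duration, t_i]
        tf_times = [t_f - 0.1 * duration, t_f - 0.05 * duration]
        res = run_simulation(cfg, frame_times=ti_times + tf_times)
        world = res.world
        lower, upper = world.geometry.regions[:2]

        def strip(frame):
            return (Q.outer_strip_intensity(frame, lower,
                                            strip_distance=strip_distance,
                                            strip_width=strip_width, side=-1)
                    + Q.outer_strip_intensity(frame, upper,
                                              strip_distance=strip_distance,
                                              strip_width=strip_width, side=+1))

        frames = dict((round(t, 6), f) for t, f in res.frames)
        ts = sorted(frames)
        I_ti = float(np.mean([strip(frames[t]) for t in ts[:3]]))
        I_tf = float(np.mean([strip(frames[t]) for t in ts[3:]]))
        return I_ti, I_tf, world

    I_ti, I_tf, world = _intensities(distance)
    if control_frames is None:
        C_ti, C_tf, _ = _intensities(D_INF)
    else:
        C_ti, C_tf = control_frames
    rho = Q.rho_ext(I_ti, I_tf, C_ti, C_tf)
    return {"d": distance, "d_over_dinf": distance / D_INF,
            "efficiency": efficiency, "seed": seed, "rho_ext": rho,
            "I_ti": I_ti, "I_tf": I_tf, "I_inf_ti": C_ti, "I_inf_tf": C_tf,
            "captures": world.capture_count,
            "primer_fibers": world.primer_effect_count}


def run_primer_experiment(n_replicates: int = 40, seed: int = 0,
                          efficiencies: Sequence[float] = (0.0, 1.0, 0.025),
                          d_range: Tuple[float, float] = (2.0, 12.0),
                          fibers_per_bar: int = 45, bar_length: float = 5.0,
                          duration: float = 500.0, strip_distance: float = 7.0,
                          strip_width: float = 1.0) -> pd.DataFrame:
    """Replicated H1/H2 comparison.  Per replicate, a distance d is drawn
    uniformly from ``d_range`` and every efficiency is run with the same
    seed against one shared paired control at d = d_inf (the control has no
    captures, so it is hypothesis-independent).  Efficiency 0 is H1
    (entanglement only); 1.0 and 0.025 are the H2 variants.
    Wilcoxon-vs-zero and Spearman(d, rho_ext) summaries are attached as
    DataFrame attrs."""
    rows = []
    for rep in range(n_replicates):
        rrng = spawn_rng(seed, 7, rep)
        d = float(rrng.uniform(*d_range))
        run_seed = int(rrng.integers(2**31))
        control = None
        for eff in efficiencies:
            try:
                r = run_primer_replicate(d, eff, run_seed,
                                         fibers_per_bar=fibers_per_bar,
                                         bar_length=bar_length,
                                         duration=duration,
                                         strip_distance=strip_distance,
                                         strip_width=strip_width,
                                         control_frames=control)
            except ValueError:
                # strip empty at t_i in this replicate; rho_ext undefined
                continue
            control = (r["I_inf_ti"], r["I_inf_tf"])
            r["replicate"] = rep
            r["hypothesis"] = "H1" if eff == 0.0 else f"H2({eff:g})"
            rows.append(r)
    df = pd.DataFrame(rows)
    stats = {}
    for hyp, sub in df.groupby("hypothesis"):
        entry = {}
        try:
            _, entry["wilcoxon_p"] = Q.wilcoxon_vs_zero(sub.rho_ext)
        except ValueError:
            entry["wilcoxon_p"] = np.nan
        try:
            rho, p = Q.spearman_trend(sub.d, sub.rho_ext)
            entry["spearman_rho"], entry["spearman_p"] = rho, p
        except ValueError:
            entry["spearman_rho"] = entry["spearman_p"] = np.nan
        stats[hyp] = entry
    df.attrs["tests"] = stats
    return df


# ---------------------------------------------------------------------------
# ablation suite and variants
# ---------------------------------------------------------------------------

def _ablation_config(variant: str, length: float, fibers_per_ray: int,
                     duration: float, seed: int) -> SimConfig:
    steric_on = variant not in ("B1", "no_steric")
    Lp = 2.0 if variant in ("B1", "no_steric", "B2") else 15.0
    ent = EntityParams(nucleators_per_region=4, arp_per_region=fibers_per_ray,
                       binders_enabled=(variant != "no_binders"))
    budget = 8 * (fibers_per_ray + 4)
    if variant == "B4":
        ent.primer_enabled = True
        ent.nucleation_efficiency = 1.0
        budget = int(budget * 1.5)
    run = RunParams(duration=duration, seed=seed, fiber_budget=budget)
    if variant == "limited_growth":
        run.monomer_budget = 0.6 * budget * 0.033 * duration
    return SimConfig(
        geometry={"preset": "star8", "length": length,
                  "width": max(0.5, length / 8.0)},
        mech=MechParams(Lp=Lp),
        steric=StericParams(enabled=steric_on),
        entities=ent, run=run)


def run_ablation_suite(variants: Sequence[str] = ("B1", "B2", "B3", "B4"),
                       length: float = 4.0, fibers_per_ray: int = 20,
                       duration: float = 150.0, replicates: int = 1,
                       seed: int = 0) -> pd.DataFrame:
    """Cumulative feature panel on the eight-fold star (B1: no steric,
    soft; B2: +calibrated steric; B3: +Lp = 15 µm; B4: +primer-effect
    nucleation), plus the ``no_binders`` and ``limited_growth`` variants.
    Reports the mean radial distance of barbed tips from the star center,
    the fiber count, and the fraction of fiber vertices inside the
    pattern."""
    rows = []
    for variant, rep in itertools.product(variants, range(replicates)):
        run_seed = int(spawn_rng(seed, zlib.crc32(variant.encode()) % 10000, rep)
                       .integers(2**31))
        cfg = _ablation_config(variant, length, fibers_per_ray, duration, run_seed)
        world = run_simulation(cfg).world
        tips = world.X[world.tips]
        radial = float(np.mean(np.linalg.norm(tips, axis=1))) if len(tips) else np.nan
        inside = world.geometry.contains(world.X)
        bases = world.X[world.offsets[:-1]]
        bases_in = world.geometry.contains(bases) if len(bases) else np.zeros(0)
        rows.append({"variant": variant, "replicate": rep, "seed": run_seed,
                     "radial_extent": radial,
                     "fiber_count": world.n_fibers,
                     "total_length": world.total_length,
                     "in_pattern_fraction": float(inside.mean()) if len(inside) else np.nan,
                     # where the nucleation cores sit: pointed ends stay on
                     # the pattern only while binder friction holds them
                     "bases_in_pattern": float(bases_in.mean()) if len(bases_in) else np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# periodic dot-lattice predictions
# ---------------------------------------------------------------------------

def run_lattice_prediction(kinds: Sequence[str] = ("square", "triangular"),
                           spacing: float = 6.0, repeats: int = 1,
                           fibers_per_dot: int = 4, duration: float = 150.0,
                           seed: int = 0, pixel_size: float = 0.25
                           ) -> Dict[str, Dict[str, object]]:
    """Periodic dot-lattice runs; returns per-kind density images and the
    orientation angles (deg, mod 180) of fiber segments outside the dots
    (the inter-dot bundles)."""
    out = {}
    for kind in kinds:
        run_seed = int(spawn_rng(seed, zlib.crc32(kind.encode()) % 10000).integers(2**31))
        n_dots = 8 * repeats
        cfg = SimConfig(
            geometry={"preset": "lattice", "kind": kind, "spacing": spacing,
                      "repeats": repeats},
            mech=MechParams(Lp=15.0),
            steric=StericParams(),
            entities=EntityParams(nucleators_per_region=1,
                                  arp_per_region=fibers_per_dot,
                                  binder_density=25.0),
            run=RunParams(duration=duration, seed=run_seed,
                          fiber_budget=n_dots * (fibers_per_dot + 1)))
        world = run_simulation(cfg).world
        img = Q.render_density(world, pixel_size=pixel_size, blur_sigma=0.2)
        X = world.X
        seg_ok = world._seg_valid
        seg = X[1:] - X[:-1]
        mid = 0.5 * (X[1:] + X[:-1])
        outside = ~world.geometry.contains(mid)
        use = seg_ok & outside
        ang = np.degrees(np.arctan2(seg[use, 1], seg[use, 0])) % 180.0
        out[kind] = {"world": world, "image": img, "orientations": ang,
                     "seed": run_seed}
    return out


# ---------------------------------------------------------------------------
# deterministic test fixtures
# ---------------------------------------------------------------------------

def generate_fixture(name: str) -> World:
    """Tiny hand-specified worlds used by unit tests; no randomness.

    Available fixtures: "two_head_on" (two fibers growing toward each other
    along x, opposite origins), "uniform_grid" (a grid of fibers covering
    the field uniformly around a bar), "three_point_steric" (two short
    fibers whose vertices realize printed pair distances).
    """
    l0 = 0.2
    if name == "two_head_on":
        left = np.column_stack([np.arange(-5, 0.01, l0), np.zeros(26)])
        right = np.column_stack([np.arange(5, -0.01, -l0), np.zeros(26)])
        return World.from_fibers([left, right], origins=[0, 1],
                                 geometry=vshape(0.0))
    if name == "uniform_grid":
        fibers = []
        for y in np.arange(-6.0, 6.01, 0.5):
            fibers.append(np.column_stack([np.arange(-8.0, 8.01, l0),
                                           np.full(81, y)]))
        return World.from_fibers(fibers, geometry=bar(length=8.0, width=1.0))
    if name == "three_point_steric":
        # three collinear single-segment fibers; consecutive gaps 0.05 and
        # 0.15 µm (interacting), outer gap 0.20 µm
        f1 = np.array([[0.0, 0.0], [0.0, l0]])
        f2 = np.array([[0.05, 0.0], [0.05, l0]])
        f3 = np.array([[0.20, 0.0], [0.20, l0]])
        return World.from_fibers([f1, f2, f3])
    raise ValueError(f"unknown fixture {name!r}")
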