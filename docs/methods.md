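# Model and methods

`filasim` simulates the assembly of actin fibers nucleated from
micropatterned regions in two dimensions, together with the image
statistics used to characterize the emergent organization.  This note
documents the model, its numerical treatment, the choices made where the
design was genuinely open, and the limits of what the simulations show.

## Physical model

**Fibers.** A fiber is a polar chain of 2D vertices spaced l = 0.2 µm
(pointed end at index 0, growing barbed end last).  A simulated fiber is an
*effective* object: at the chosen steric diameter one fiber stands for
roughly ten crosslinked actin filaments, and densities are reduced
accordingly.  Bending follows the discrete worm-like chain,

    E_bend = (K / 2l) Σ_i θ_i²,        K = kBT · Lp,

with θ_i the turning angle at interior joint i.  In 2D this makes
equilibrium joint angles independent Gaussians with variance l/Lp, so
tangent correlations decay as ⟨cos Δθ(s)⟩ = exp(−s/2Lp); the
persistence-length estimator fits exactly this form.  Defaults:
kBT = 4.2×10⁻³ pN·µm (room temperature), Lp = 15 µm (single native
filament; 2 µm mimics ADF/cofilin-softened filaments, 1000 µm stiff
crosslinked bundles).

**Near-inextensibility.** Segments are held at their rest length by
stretching springs of 100 pN/µm (thermal length fluctuations ≈ 3%).  A hard
constraint imposed by re-projecting segment lengths after every step was
tried first and rejected: it distorts the angular equilibrium measure by
~20% independently of the time step, while the stiff-spring chain has the
exact product-Gaussian angle statistics of the worm-like chain.

**Growth.** Only barbed ends grow (no depolymerization, no monomer
depletion by default).  The elongation speed under a tip force f with
barbed-end tangent t is

    v = v0 · exp(f·t / fs)   if f·t < 0,   v = v0 otherwise,

with v0 = 0.033 µm/s and fs = 0.8 pN.  The terminal segment is subdivided
when it exceeds 1.5 l, so segment lengths stay within [0.5, 1.5] l at the
tip and at l elsewhere.  An optional finite "monomer budget" scales v by
(1 − L_total/budget) for the limited-growth ablation.

**Steric interaction.** The effective fiber–fiber interaction is piecewise
linear in the separation d: repulsive K_push(d−d0) below the effective
diameter d0 = 0.1 µm, attractive K_pull(d−d0) up to dm = 0.2 µm, zero
beyond.  The calibrated stiffnesses are K_push = 7.5 and
K_pull = 0.5 pN/µm.  The jump of K_pull·(dm−d0) = 0.05 pN at dm is a
property of the law, documented rather than smoothed.  In the dynamics the
force acts between each fiber's discretization points and the nearest
point of nearby *segments* of other fibers (reaction distributed
barycentrically to the segment endpoints).  This matters: with forces
between points only, a growing tip can slip through the zero-force saddle
between two interaction points and fibers cross freely, which destroys the
bend-and-zipper behavior at right-angle encounters.  Points closer than 3
segments in arc length along the same fiber never interact.  The
`steric` module additionally exposes the plain point–point primitives
(`pair_force`, `neighbor_pairs`, `steric_forces`).

**Entities.** All nucleation machinery is anchored on the pattern:

- *Nucleators* each create one two-segment "primer" fiber at t = 0 with a
  uniformly random orientation.
- *Arp2/3-like complexes* bind a passing fiber point (rate 10 s⁻¹ within
  0.1 µm) and immediately nucleate a daughter fiber whose pointed end sits
  at the branch point, oriented at ±70° (fair coin) to the local mother
  tangent with the barbed end pointing away from the mother's pointed end.
  The complex then turns into a Hookean link (100 pN/µm) plus an angular
  spring (0.5 pN·µm/rad about ±70°) riding the mother; each complex
  branches once and never unbinds.
- *Binders* are anchored springs (100 pN/µm) that attach to fiber points
  within 0.1 µm at 10 s⁻¹ and detach at 0.5 s⁻¹, creating the pattern
  friction that keeps the dense network on the activated region (their
  anchor is the substrate, so the reaction force is discarded).
- *Primer-effect entities* (parallel-bars experiment only) cap growing
  barbed ends arriving from the *other* bar; a fraction equal to the
  nucleation efficiency additionally nucleates a fresh fiber at the capture
  site.  Efficiency 0 is the pure-entanglement hypothesis H1; 1.0 and
  0.025 are the nucleation hypothesis H2 variants.

Entity rates and stiffnesses are effective values (no measured numbers
exist for them); they are defaults in `EntityParams`, recorded in every run
manifest.  The total fiber count is capped by a configured budget.

**Drag and thermal noise.** Each vertex has isotropic drag
γ_v = drag_per_length · l with drag_per_length = 1 pN·s/µm² (an effective
crowded-medium viscosity chosen so shapes equilibrate within the 250 s
runs); hydrodynamic anisotropy is ignored.  Thermal displacements have
per-coordinate variance 2 kBT dt/γ_v.

## Numerical integration

Inertia is negligible at this scale, so the dynamics is overdamped.  One
step solves

    M Δx = F(x) + (γ_v/dt) ξ,
    M = (γ_v/dt) I + A_bend/2 + H_stretch/2 + diag(D),

where F is the full nonlinear force (exact angle-gradient bending,
stretching, point-to-segment steric, entity springs), A_bend the
linearized bending operator, H_stretch = k_s t̂ t̂ᵀ the anisotropic
stretching Hessian assembled from the current segment directions, and D a
diagonal carrying the local stiffness of every engaged pair spring
(steric, binder, branch link, angular spring).  Treating the stiff linear
parts with a Crank–Nicolson half-step makes the scheme stable for stiff
fibers at dt = 0.01 s and — because Crank–Nicolson has the exact
stationary covariance for linear modes — keeps equilibrium statistics
essentially unbiased: the measured joint-angle variance is within ~2% of
l/Lp at both Lp = 2 and Lp = 15 µm, and persistence-length estimates are
unbiased within estimator noise.  Matching the implicit operator to the
*anisotropic* spring Hessian matters; an isotropic approximation
suppresses transverse fluctuations severely.  The diagonal damping D makes
the stiff pair springs unconditionally stable (their fluctuations are
slightly underdamped observables, not used in any statistic).

The per-fiber system is 2×2-block pentadiagonal and solved by a block
LDLᵀ factorization in a compiled (numba) kernel; a pure
numpy/LAPACK-banded reference implementation of the identical step is kept
and compared against the kernel in the tests.  Near-contact steric
dynamics are chaotic, so the two solvers agree to ~1e-9 only over short
horizons; determinism of either path is bitwise.

Two regularizations keep the explicit force parts inside the implicit
scheme's stability region: the bending lever arm is clamped below at
0.7 l (active only on freshly subdivided terminal segments; the public
`bending_forces` operation is the exact unclamped gradient), and branch
daughters start with a 0.1 µm first segment.  The time step is reduced
automatically when a pair stiffness demands it (k·dt/γ_v ≤ 0.5, e.g. the
K_push = 75 pN/µm calibration cells run at dt ≈ 1.3 ms); a configured dt
violating stability raises a configuration error naming the offending
parameters.

The engine's neighbor search is a compiled uniform-grid broad phase that
emits (point, segment) candidates within dm plus a 0.2 µm Verlet skin;
the cached list is refreshed whenever any vertex has moved by half the
skin.  The standalone `neighbor_pairs` operation uses a KD tree and is
cross-checked against an all-pairs scan, as is the grid builder.  With a
periodic domain (dot lattices) all distances use the minimum-image
convention.

Reproducibility: one seeded generator drives all randomness; entity sweeps
process entities in index order; identical (config, seed) gives
bit-identical trajectories.

## Quantification

- `render_density`: segments deposit intensity equal to their length by
  sub-pixel line sampling (≈4 samples per pixel crossed), optionally
  followed by a normalized Gaussian blur; total intensity equals total
  fiber length to <1%.
- `corner_intensity_ratio` (I_c): mean of the four 2 µm corner-adjacent
  box intensities over the whole-image mean (both per unit area); 1 for a
  uniform image, <1 when bundles deplete the corners.
- `ellipse_intensity_deviation` (I_d): standard deviation of bilinear
  intensity samples, normalized by their mean, at 720 points uniformly
  spaced in arc length along an ellipse around the pattern (default
  semi-axes: bar half-length + 3 µm, 3 µm); high values mean discrete
  bundles.
- `median_line_fractions`: fiber segments crossing the V-shape bisector
  classified by the acute angle of their tangent to the x-axis —
  [70°, 90°] "parallel" (aligned with the bisector), [0°, 20°]
  "antiparallel", else "other"; crossing-weighted.
- `meeting_angles`: for vertex pairs of opposite-origin fibers in steric
  contact (within dm of each other) inside a band of ±1 µm around the
  bisector, the unsigned angle between the local tangents (180° = head-on).
  The band is wider than the contact radius because the zipped bundles run
  with finite width beside the line; tying the band to dm hides them.
- `rho_ext` = I(d,t_f)/I(d,t_i) − I(d∞,t_f)/I(d∞,t_i), with I the fiber
  length in a 1 µm strip on the focal bar's outer side (7 µm from the bar
  center at full scale), t_i = half the run, t_f its end, and the control
  a paired run (same seed) at the isolation distance d∞ = 10 µm.
- Distribution tests wrap the standard two-sample Kolmogorov–Smirnov
  statistic (exact sup-distance, asymptotic p), the one-sample Wilcoxon
  signed-rank test against zero, and Spearman rank correlation (mid-ranks
  for ties); constant input raises.

## Experiments and problem sizes

The experiment drivers implement the reference experimental designs: the 3×3 steric
calibration grid on an 8 µm bar (K_push ∈ {0.75, 7.5, 75},
K_pull ∈ {0.05, 0.5, 5} pN/µm), V-shape sweeps over the opening angle
θ ∈ [0°, 120°] and rigidity, the ratio experiment matching r = Lp/L cells
by co-scaling geometry and duration, the two-bar primer-effect assay with
paired controls and Wilcoxon/Spearman summaries, the cumulative ablation
panel (no steric → +steric → +Lp = 15 µm → +primer nucleation, plus
no-binder and limited-growth variants) and the periodic square/triangular
dot-lattice predictions.

Full-scale runs use 510 fibers on the bar, 360 per V-shape bar, 135 per
primer bar and 250 s (500 s for the primer assay).  The package defaults
are desk scale — budgets divided by roughly three and replicates reduced —
chosen so a complete check runs on one CPU core in minutes.  Two emergent
results are density-sensitive and are run closer to full scale where they
are asserted: the right-angle V-shape zippering needs ≥ ~240 fibers/bar
for the parallel seam to dominate the contact statistics (at 120/bar the
parallel orientation fraction already dominates but the pooled
meeting-angle median does not fall below 20°), and V-shape bars meet at
the pattern vertex (inner gap 0, as in the eight-fold star whose rays
share the center); with a pattern-free gap at the vertex, fibers slip
between the bars and form spurious antiparallel seams.

The V-shape acceptance conditions therefore use: θ = 0° at 120 fibers/bar
(separated collinear bars) and θ = 90° at 240 fibers/bar (bars sharing
the vertex), both 8 µm bars, 250 s, angles pooled over seeds.

The primer-effect assay is the least scale-tolerant experiment.  Under H1
any foreign barbed end entering a region is capped (absolute
entanglement); under H2 capture is entity-mediated, so a minority of ends
cross and the nucleator fraction creates new fibers.  At the miniature
scale used in the test suite (18 fibers per 3 µm bar, 300 s, paired
same-seed controls at d∞ = 10 µm), the flatness of ρ_ext under H1 is
reproduced, but the chaotic run-to-run variability of outer-side growth
(σ_ρ ≈ 0.3–1 at small d) is comparable to the nucleation signal
(≈ +0.1–0.3), so the decreasing ρ_ext(d) trend under H2 does not reach
95% significance at an affordable replicate count; longer runs do not
help because beyond ≈350 s the d∞ control itself starts interacting
(fibers outgrow the 10 µm gap).  The full-scale experiment (135
fibers/bar, 100 replicates) self-averages these fluctuations; the
corresponding suite check documents this as an honest scale limitation
rather than loosening its threshold.

## What the synthetic conditions do and do not show

All inputs are generated by the model itself; there are no experimental
images in the pipeline.  Passing checks show that the *model* reproduces
the expected emergent phenomenology (bundling on the bar, the
angle/rigidity control of parallel vs antiparallel structures, the
primer-effect distance dependence, the ablation orderings) under the
printed parameters — not that the model is validated against micrographs.
Effective-medium drag, the 2D restriction, effective fibers (~10 filaments
each), the absence of explicit crosslinkers, motors, severing and monomer
depletion, and the single-use/no-unbind Arp2/3 complexes are all
simplifications; bundle thickness and absolute densities are therefore
only comparable to experiments at the order-of-magnitude level.

## Known limitations

- Explicitly treated near-contact forces make trajectories chaotic;
  statistics are reproducible, individual trajectories only per (config,
  seed).
- Very stiff fibers (Lp = 1000 µm) are supported but slow (the automatic
  time step does not shrink for bending — Crank–Nicolson handles it — but
  the nonlinear bending remainder grows; treat results at
  dt = 0.01 s as qualitative unless checked at smaller dt).
- I_c assumes a single axis-aligned bar; the ellipse for I_d assumes the
  pattern is centered.
- The binder/arp rate constants are effective; only their qualitative
  regime (binders confine, branching amplifies) is constrained by the
  study's observations.
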