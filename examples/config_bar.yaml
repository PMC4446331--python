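# Complete configuration for the calibration-bar experiment:
# an 8 µm nucleating bar, calibrated steric set, desk-scale budget.
# Run with:  filasim simulate --config examples/config_bar.yaml --out out/
geometry:
  preset: bar
  length: 8.0        # µm
  width: 1.0         # µm
mech:
  kBT: 0.0042        # pN·µm (room temperature)
  drag_per_length: 1.0   # pN·s/µm² (effective crowded medium)
  dt: null           # s; null = automatic (0.01 s here)
  Lp: 15.0           # µm, native single-filament persistence length
  v0: 0.033          # µm/s unloaded elongation speed
  fs: 0.8            # pN growth force sensitivity
  segment_length: 0.2    # µm discretization / interaction-point spacing
  stretch_stiffness: 100.0   # pN/µm near-inextensibility springs
steric:
  K_push: 7.5        # pN/µm repulsion (calibrated set)
  K_pull: 0.5        # pN/µm attraction (calibrated set)
  d0: 0.1            # µm effective fiber diameter
  dm: 0.2            # µm maximal interaction range
  enabled: true
entities:
  nucleators_per_region: 10   # primer fibers at t = 0
  arp_per_region: 170         # single-use branching complexes
  arp_k_on: 10.0              # 1/s within binding range
  arp_binding_range: 0.1      # µm
  arp_link_stiffness: 100.0   # pN/µm mother-daughter link
  arp_angular_stiffness: 0.5  # pN·µm/rad about the 70° branch angle
  branch_angle_deg: 70.0
  binder_density: 25.0        # anchors per µm² of pattern (friction)
  binder_k_on: 10.0           # 1/s
  binder_k_off: 0.5           # 1/s
  binder_range: 0.1           # µm
  binder_stiffness: 100.0     # pN/µm
  primer_enabled: false       # primer-effect entities (two-bar assay only)
  nucleation_efficiency: 0.0
run:
  duration: 250.0    # s
  seed: 0
  fiber_budget: 170  # desk scale (a third of the full 510)
  event_interval: 0.1    # s between entity binding/branching sweeps
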