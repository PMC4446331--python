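"""Steric calibration on a nucleating bar.

Runs three cells of the steric-parameter grid on a small bar and prints
the corner-intensity ratio I_c and the ellipse intensity deviation I_d.
The calibrated balance (K_push = 7.5, K_pull = 0.5 pN/µm) gives bundles
that leave the bar corners empty (I_c < 1); dominant repulsion fills the
corners with disorganized fibers (higher I_c); dominant attraction
collapses everything into a few dense bundles (higher I_d).
"""

import filasim as fs

df = fs.run_calibration_sweep(
    K_push_values=(0.75, 7.5, 75.0), K_pull_values=(0.5,),
    replicates=2, seed=1, bar_length=5.0, budget=60, duration=150.0,
    ks_tests=False)

print(df.groupby(["K_push", "K_pull"])[["I_c", "I_d"]].mean().round(3))
print("\nRows are steric cells; I_c < 1 signals bundling along the bar "
      "axis, large I_d signals discrete bundles.  At this miniature demo "
      "scale the values are noisy; the cell orderings are asserted at a "
      "larger validated scale in the test suite.")
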