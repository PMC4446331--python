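"""The primer effect between neighboring nucleation regions.

Two parallel nucleating bars: do fibers arriving from the neighbor bar
merely entangle (H1) or also trigger new nucleation (H2)?  The statistic
rho_ext compares the fold-change of outer-side fiber density against a
paired isolated-bar control: near zero under H1, positive and decreasing
with the bar distance d under H2.  Miniature ensemble (a few replicates).
"""

import filasim as fs

df = fs.run_primer_experiment(
    n_replicates=6, seed=5, efficiencies=(0.0, 1.0),
    fibers_per_bar=18, bar_length=3.0, duration=300.0,
    strip_distance=4.0, strip_width=4.6)

cols = ["hypothesis", "d", "rho_ext", "captures", "primer_fibers"]
print(df[cols].round(3).to_string(index=False))
for hyp, t in df.attrs["tests"].items():
    print(f"{hyp}: Wilcoxon-vs-0 p = {t['wilcoxon_p']:.3f}, "
          f"Spearman(d, rho_ext) rho = {t.get('spearman_rho', float('nan')):.2f}")
print("\nPositive rho_ext at small d with nucleation (H2) and flat ~0 "
      "under entanglement (H1) is the primer-effect signature; at this "
      "miniature demo scale the trend is noisy (see docs/methods.md).")
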