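"""Seeded ensembles of growth runs: the fold-outcome statistics.

Runs a small batch per growth model (5 seeds each here; raise n_runs for
tighter intervals) and tabulates where the center/special area ends up,
with an exact binomial 95% CI on the gyrus proportion.
"""

from gyrogen import BatchSpec, run_batch

spec = BatchSpec(modes=["homogeneous", "fast_patch", "stiff_patch:2"],
                 n_runs=5, base_seed=1)
report = run_batch(spec)

t = report.table3
for mode in t.counts:
    n = t.n_runs[mode]
    c = t.counts[mode]
    lo, hi = t.gyrus_ci[mode]
    print(f"{mode:14s} (n={n}): "
          + ", ".join(f"{k}={c.get(k, 0)}" for k in ("gyrus", "sulcus", "bank"))
          + f"; gyrus 95% CI [{lo:.2f}, {hi:.2f}]")

print("\nWith enough runs the fast-growing area forms a gyrus almost "
      "always, the stiffening area a sulcus, while homogeneous growth "
      "spreads across all three outcomes.")
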