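"""Longitudinal growth-rate analysis on a synthetic fetal surface series.

Generates white/pial surface pairs for pseudo-gestational weeks 25-31 on a
corrugated sheet (ridges thicken at 0.35 mm/week, valleys at 0.10 mm/week,
residual sd 0.26 mm), then runs the full measurement pipeline: per-timepoint
closest-vertex thickness, maximal principal curvature (MPC) on the final
white surface, per-vertex OLS slopes, the R^2 >= 0.6 reliability filter,
MPC-sign grouping, and the pooled t-test.
"""

from gyrogen import SynthGrowthParams, analyze_series, make_surface_series

params = SynthGrowthParams(seed=1)
series = make_surface_series(params)
res = analyze_series(series)

print(f"surface series: {series.n_vertices} vertices x "
      f"{len(series.timepoints)} weeks ({series.timepoints[0]}-"
      f"{series.timepoints[-1]})")
print(f"R^2 >= 0.6 keeps {100 * res.kept_fraction:.0f}% of vertices")
print(f"gyral group (MPC > 0):  slope {res.test.mean_a:.3f} +/- "
      f"{res.test.sd_a:.3f} mm/week (n={res.test.n_a})")
print(f"sulcal group (MPC < 0): slope {res.test.mean_b:.3f} +/- "
      f"{res.test.sd_b:.3f} mm/week (n={res.test.n_b})")
print(f"right-tail pooled t-test: t = {res.test.t:.1f}, "
      f"p = {res.test.p_right_tail:.2e}")
print("\nThe gyral mean recovers the generative 0.35 mm/week; the sulcal "
      "mean sits above the generative 0.10 because the R^2 filter "
      "preferentially keeps low-slope vertices whose noisy slope estimate "
      "happens to be large (see docs/methods.md).")
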