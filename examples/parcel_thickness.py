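"""Compare gyral vs sulcal cortical thickness over the packaged parcel table.

Loads the 30 gyral + 31 sulcal Destrieux parcel averages (mm), prints the
parcel-unweighted class means and the pooled-variance t-test.  Gyral parcels
being significantly thicker than sulcal ones is the cross-sectional
observation that motivates the heterogeneous-growth hypothesis.
"""

from gyrogen import parcel_comparison, table1_fixture

table = table1_fixture()
res = parcel_comparison(table)

print(f"gyral parcels : mean {res.gyral_mean:.2f} mm "
      f"(sd {res.gyral_sd:.2f}, n={res.n_gyral})")
print(f"sulcal parcels: mean {res.sulcal_mean:.2f} mm "
      f"(sd {res.sulcal_sd:.2f}, n={res.n_sulcal})")
print(f"pooled t = {res.test.t:.2f} (dof {res.test.dof}), "
      f"right-tail p = {res.test.p_right_tail:.1e}")
print("\nThe ~0.33 mm gyral excess (ratio ~1.13) is what the simulator's "
      "1.2x special-area growth rate emulates.")
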