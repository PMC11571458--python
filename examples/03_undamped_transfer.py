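"""Undamped-force extrapolation and per-layer transfer functions.

Runs the full synthetic study, fits F(x) = a*exp(b*x) through the peak
points of each (drop height, repetition) group, extrapolates to x = 0 for
the undamped force, and regresses undamped on measured through the origin,
one slope per layer count.
"""

from foamimpact import attenuation_ratio, predict_undamped, run_full_study

_, results = run_full_study(seed=1)

print("undamped forces per (height, repetition):")
table = results["undamped"].assign(
    a=lambda d: d.a.round(0), b=lambda d: d.b.round(1)
)
print(table.to_string(index=False))

print("\ntransfer functions (undamped = slope x measured):")
for layer, tf in sorted(results["transfer"].items()):
    print(f"  {layer} layer(s): slope {tf.slope:.1f}, R^2 = {tf.r_squared:.3f}")

tfs = results["transfer"]
print(f"\n2 layers attenuate {attenuation_ratio(tfs[2], tfs[1]):.1f}x more "
      f"than one; 3 layers {attenuation_ratio(tfs[3], tfs[1]):.1f}x more")

measured_kn = 2.9  # a typical measured direct-punch force
print(f"a {measured_kn} kN strike measured through one layer implies "
      f"{predict_undamped(measured_kn, tfs[1]):.1f} kN undamped")

# The slope is the factor a measured force must be multiplied by to recover
# the bare-impact force the load cell would see with no protective mat.
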