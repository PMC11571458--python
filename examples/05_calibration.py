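"""Re-run the factory calibration of the foam material parameters.

Fits (a_f, b_f, c_d) to the published 1- and 2-layer forces at 30 J plus
the densification anchor, then (n_u, kappa) to the repetition-2 relative
increases.  The 3-layer force is held out and reported as validation.
"""

from foamimpact import calibrate_defaults

params, diag = calibrate_defaults(full_output=True)

print("fitted foam parameters:")
for name in ("a_f", "b_f", "c_d", "n_u", "kappa"):
    print(f"  {name:6s} = {getattr(params, name):.5g}")
print("\nfirst-strike force-at-30J errors vs the published table:")
for layer, err in sorted(diag["force_errors"].items()):
    tag = " (held-out validation)" if layer == 3 else ""
    print(f"  {layer} layer(s): {err:+.1%}{tag}")
print("\nrepetition-2 relative increases:")
for layer, inc in sorted(diag["rel_increase_rep2"].items()):
    print(f"  {layer} layer(s): {inc:+.1%}")

# Layers 1-2 land within a fraction of a percent; the held-out 3-layer force
# sits ~18% high — the irreducible cost of one shared strain law across all
# stack thicknesses (see docs/methods.md).
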