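"""Enumerate the drop-test grid and its basic kinematics.

The study drops an 8-kg impactor from 0.15/0.25/0.50 m onto foam specimens
of 1-3 stacked 18-mm layers, three specimens per cell struck three times,
plus an extra five-strike block at 0.50 m for the repeated-loading analysis.
"""

from foamimpact import StudyConfig, enumerate_design, impact_energy, impact_velocity

config = StudyConfig()
design = enumerate_design(config)

print(f"specimens: {design.n_specimens}, individual tests: {design.n_tests}")
for h in config.drop_heights:
    v = impact_velocity(h, config.gravity)
    e = impact_energy(config.impactor_mass, h, config.gravity)
    print(f"  drop {h:.2f} m -> contact speed {v:.2f} m/s, impact energy {e:.1f} J")

# With the defaults this prints 36 specimens / 126 tests; the 0.15-m drop
# lands at 1.72 m/s, i.e. the gentle end of upper-limb strike speeds.
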