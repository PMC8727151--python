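"""Predict the shear stress-displacement curve of a rooted soil column.

Builds a willow-like specimen (0.409% root area ratio, 200 MPa roots,
tau' = 1.25 kPa, friction angle 36 deg) inside a 103 mm direct-shear tube
and compares four shear-zone-thickness treatments: constant 2 mm (the tube
gap), constant 30 mm (the peak), per-root positional thickness, and
positional thickness growing with displacement.
"""

import numpy as np

import rootshear as rs

zone = rs.ShearZoneModel(
    z_min_mm=2.0, z_max_mm=30.0, d_tube_mm=103.0,
    growth=rs.GrowthSchedule(u_step3_mm=8.15, u_final_mm=19.83),
)
base_u, base_s = rs.hyperbolic_baseline(s_ult_kpa=4.0, u_ref_mm=2.0, u_max_mm=21.0)
soil = rs.SoilParams(36.0, base_u, base_s, baseline_source="fitted hyperbolic")
roots = rs.generate_root_map(rs.RootMapConfig(target_rar=0.00409, seed=3))
spec = rs.Specimen(tuple(roots), soil, rs.InterfaceParams(1.25), zone, "willow-like")

u = np.concatenate([[0.0], rs.presets.STEP_SCHEDULES_MM["Willow C"]])
print(f"{len(roots)} roots, RAR = {100 * spec.rar:.3f}%")
print(f"{'policy':<28}{'dS(final) kPa':>14}{'total(final) kPa':>18}")
for policy, z_const in [
    ("constant", 2.0),
    ("constant", 30.0),
    ("positional", None),
    ("positional_with_growth", None),
]:
    pred = rs.predict_stress_curve(spec, u, policy, z_const)
    name = policy if z_const is None else f"{policy} Z={z_const:g} mm"
    print(f"{name:<28}{pred.delta_s_kpa[-1]:>14.2f}{pred.record.s_kpa[-1]:>18.2f}")

# dS(final) is the extra shear resistance the roots supply at ~20 mm of
# travel; the thin 2 mm zone mobilises roots hardest, the growing
# positional zone sits between the two constant-thickness extremes.
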