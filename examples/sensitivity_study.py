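"""Sensitivity of root reinforcement to zone thickness and bond stress.

Sweeps the added shear resistance dS and the stressed root length l for a
1 mm, 200 MPa root at a willow-like area ratio over shear-zone thickness
(2-30 mm), bond stress (0.5-5 kPa) and displacement (0-20 mm).
"""

import numpy as np

import rootshear as rs

table = rs.sensitivity_sweep(
    z_grid_mm=np.linspace(2.0, 30.0, 8),
    tau_grid_kpa=[0.5, 1.0, 2.0, 5.0],
    u_grid_mm=np.linspace(0.0, 20.0, 21),
)
final = table[table.u_mm == 20.0]
print("dS (kPa) at u = 20 mm:")
print(final.pivot(index="Z_mm", columns="tau_kpa", values="dS_kpa").round(2))

at_8 = table[(table.u_mm == 8.0) & (table.tau_kpa == 1.0)]
print("\ndS at u = 8 mm, tau' = 1 kPa, by thickness:")
print(at_8[["Z_mm", "dS_kpa", "l_mm"]].round(2).to_string(index=False))

# Reinforcement rises with tau' everywhere; it falls with thickness over
# the working range because thin zones strain roots faster. The stressed
# length l grows with thickness and drops with tau' (a stickier interface
# needs less embedded length).
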