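"""Study conditions: the direct-shear programme on willow-, gorse-rooted and
fallow Bullionfield-soil columns that this package's fixtures emulate.

Values here parameterize synthetic fixtures and examples; nothing in the
analysis code depends on them.
"""

from __future__ import annotations

#: inner diameter of the split specimen tube, mm
D_TUBE_MM = 103.0

#: vertical clearance gap between the upper and lower tube halves, mm —
#: the floor on shear-zone thickness at the sidewall
Z_GAP_MM = 2.0

#: upper bound on shear-zone thickness used in the positional model, mm
Z_MAX_MM = 30.0

#: soil internal friction angle, degrees
PHI_DEG = 36.0

#: root Young's moduli by species, MPa
E_ROOT_MPA = {"willow": 200.0, "gorse": 500.0}

#: interface bond stress found to reproduce final measured shear stress, kPa
TAU_PRIME_FITTED_KPA = 1.25

#: applied x-displacement (mm) at each of the 7 interrupted shear steps
STEP_SCHEDULES_MM = {
    "Willow C": [1.72, 4.87, 8.15, 11.39, 14.69, 17.93, 19.83],
    "Willow F": [1.23, 4.20, 7.44, 10.65, 13.82, 17.03, 18.75],
    "Fallow D": [2.17, 5.48, 8.80, 12.14, 15.47, 18.76, 20.84],
    "Fallow P": [3.17, 6.47, 9.79, 13.11, 16.41, 19.73, 20.46],
    "Gorse A": [1.49, 4.73, 8.03, 11.34, 14.63, 17.95, 20.14],
    "Gorse G": [0.77, 4.00, 7.31, 10.59, 13.89, 17.19, 19.31],
}

#: measured root area ratio (%) on the shear plane per specimen
RAR_PERCENT = {
    "Willow C": 0.409,
    "Willow E": 0.275,
    "Willow F": 0.340,
    "Willow H": 0.272,
    "Willow I": 0.575,
    "Gorse A": 0.036,
    "Gorse B": 0.065,
    "Gorse G": 0.063,
    "Gorse J": 0.013,
    "Gorse K": 0.050,
}

#: volume-correlation grid pitch, mm (32-voxel subsets, 46 um voxels, 75% overlap)
DVC_PITCH_MM = 0.37

#: one-step displacement noise of the correlation, mm (5.4 um); accumulates
#: linearly with step count because successive scans are correlated pairwise
DVC_NOISE_MM = 0.0054

#: XCT field of view, mm (cube side), centred on the tube axis
FOV_MM = 80.0
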