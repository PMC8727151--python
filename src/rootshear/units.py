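"""Unit helpers.

All file-level I/O in this package uses a single declared system — lengths in
mm, soil stresses in kPa, root stiffness in MPa, angles in degrees where a
human writes them (friction angle) and radians internally. These helpers make
the few conversions explicit and round-trippable.
"""

from __future__ import annotations

import math

MM_PER_M = 1000.0
KPA_PER_MPA = 1000.0
PA_PER_KPA = 1000.0

#: unit weight of water, kN/m^3 (9.81 kPa per metre of head)
GAMMA_WATER_KN_M3 = 9.81


def deg_to_rad(angle_deg: float) -> float:
    return math.radians(angle_deg)


def rad_to_deg(angle_rad: float) -> float:
    return math.degrees(angle_rad)


def mm_to_m(x_mm: float) -> float:
    return x_mm / MM_PER_M


def m_to_mm(x_m: float) -> float:
    return x_m * MM_PER_M


def kpa_to_pa(s_kpa: float) -> float:
    return s_kpa * PA_PER_KPA


def pa_to_kpa(s_pa: float) -> float:
    return s_pa / PA_PER_KPA


def mpa_to_kpa(s_mpa: float) -> float:
    return s_mpa * KPA_PER_MPA


def kpa_to_mpa(s_kpa: float) -> float:
    return s_kpa / KPA_PER_MPA
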