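"""Small closed-form quantities of the experimental set-up.

These are the arithmetic facts of the measurement rig that the analysis
relies on: the spacing of the displacement grid produced by subset-based
volume correlation, and the hydrostatic matric suction implied by a water
table held below the shear plane.
"""

from __future__ import annotations

from .units import GAMMA_WATER_KN_M3


def dvc_grid_pitch_mm(
    subset_voxels: int, voxel_size_um: float, overlap: float
) -> float:
    """Displacement-grid spacing of a subset-based volume correlation.

    With cubic subsets of ``subset_voxels`` voxels stepped at fractional
    ``overlap`` (0.75 means adjacent subsets share 75% of their extent), the
    displacement vectors land on a grid of ``subset_voxels * (1 - overlap)``
    voxels, i.e. 8 voxels for a 32-voxel subset at 75% overlap.

    Parameters
    ----------
    subset_voxels : side length of the correlation subset, in voxels.
    voxel_size_um : voxel edge length, in micrometres.
    overlap : fractional subset overlap in [0, 1).

    Returns
    -------
    Grid pitch in millimetres.
    """
    if subset_voxels <= 0:
        raise ValueError("subset_voxels must be positive")
    if voxel_size_um <= 0:
        raise ValueError("voxel_size_um must be positive")
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must lie in [0, 1)")
    step_voxels = subset_voxels * (1.0 - overlap)
    return step_voxels * voxel_size_um / 1000.0


def hydrostatic_suction_kpa(depth_to_water_table_m: float) -> float:
    """Matric suction at a point a given height above the water table.

    Under hydrostatic equilibrium the pore pressure decreases linearly above
    the water table, so a point ``h`` metres above it carries a suction of
    ``gamma_w * h``. A water table 0.5 m below the shear plane therefore
    gives about 5 kPa of suction at the plane.
    """
    if depth_to_water_table_m < 0:
        raise ValueError("depth to water table must be non-negative")
    return GAMMA_WATER_KN_M3 * depth_to_water_table_m
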