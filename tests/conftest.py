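import numpy as np
import pytest

import rootshear as rs


@pytest.fixture
def willow_zone() -> rs.ShearZoneModel:
    """Zone geometry of a willow-like specimen: 2 mm gap at the wall,
    30 mm at the axis, growth to 80% by step 3 (8.15 mm) and 100% by the
    final step (19.83 mm)."""
    return rs.ShearZoneModel(
        z_min_mm=2.0,
        z_max_mm=30.0,
        d_tube_mm=103.0,
        growth=rs.GrowthSchedule(u_step3_mm=8.15, u_final_mm=19.83),
    )


@pytest.fixture
def soil_with_baseline() -> rs.SoilParams:
    u, s = rs.hyperbolic_baseline(4.0, 2.0, 21.0)
    return rs.SoilParams(36.0, u, s, baseline_source="fitted hyperbolic")


@pytest.fixture
def willow_spec(willow_zone, soil_with_baseline) -> rs.Specimen:
    """Willow-like specimen: seeded random root map at 0.409% area ratio,
    200 MPa roots, tau' = 1.25 kPa."""
    roots = rs.generate_root_map(rs.RootMapConfig(target_rar=0.00409, seed=3))
    return rs.Specimen(
        roots=tuple(roots),
        soil=soil_with_baseline,
        interface=rs.InterfaceParams(1.25),
        zone=willow_zone,
        label="willow-like",
    )


@pytest.fixture
def fallow_spec(willow_zone, soil_with_baseline) -> rs.Specimen:
    return rs.Specimen(
        roots=(),
        soil=soil_with_baseline,
        interface=rs.InterfaceParams(1.25),
        zone=willow_zone,
        label="fallow",
    )


@pytest.fixture
def willow_u_grid() -> np.ndarray:
    return np.concatenate([[0.0], rs.presets.STEP_SCHEDULES_MM["Willow C"]])


def make_trilinear_profile(
    z_lower: float,
    z_upper: float,
    u_below: float = 2.0,
    u_above: float = 0.3,
    pitch: float = 0.37,
    half_span: float = 15.0,
):
    """Noiseless tri-linear (z, u) profile with prescribed knees."""
    z = np.arange(-half_span, half_span + pitch / 2, pitch)
    ramp = np.clip((z - z_lower) / (z_upper - z_lower), 0.0, 1.0)
    u = u_below + (u_above - u_below) * ramp
    return z, u


@pytest.fixture
def small_field_cfg() -> rs.FieldGenConfig:
    """Reduced-size noiseless field: 40 mm window at 1 mm pitch, band
    tapering 2 -> 20 mm. Small enough that a full map fits in seconds."""
    return rs.FieldGenConfig(
        extent_mm=40.0,
        pitch_mm=1.0,
        z_max_mm=20.0,
        noise_sigma_mm=0.0,
        schedule_mm=(2.0, 5.0, 8.0, 11.0, 14.0, 17.0, 20.0),
    )
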