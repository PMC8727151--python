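"""Synthetic direct-shear fixtures: displacement fields with a prescribed
shear-band geometry, root populations on the shear plane, forward-modelled
stress records and bent root paths.

The generator emulates the structure of volume-correlation output from an
in-scanner direct shear test on a rooted soil column: the lower half of the
column translates in x while the upper half stays fixed, with the
transition spread over a band whose thickness is largest at the tube axis
and pinched to the inter-tube gap at the sidewall (a double-cone in 3-D),
locally thickened near coarse roots, and overlaid with correlation noise
that accumulates linearly over displacement steps. Every output is
deterministic for a given seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Literal, Sequence

import numpy as np

from .field import DisplacementField
from .geometry import RootPath
from .model import (
    Root,
    ShearTestRecord,
    Specimen,
    StressCurvePrediction,
    ZPolicy,
    predict_stress_curve,
)
from . import presets

__all__ = [
    "Bump",
    "FieldGenConfig",
    "RootMapConfig",
    "zone_thickness",
    "generate_field",
    "generate_root_map",
    "generate_stress_record",
    "generate_root_path",
]


@dataclass(frozen=True)
class Bump:
    """Local thickening of the shear zone near a coarse root: a Gaussian
    bump of given peak amplitude (mm) and e-folding radius (mm)."""

    x_mm: float
    y_mm: float
    amplitude_mm: float
    radius_mm: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("bump radius must be > 0")


@dataclass(frozen=True)
class FieldGenConfig:
    """Geometry, schedule and noise of the synthetic displacement field.

    Defaults reproduce the imaging window of the study conditions: a cubic
    field of view of 80 mm at 0.37 mm grid pitch inside a 103 mm tube, band
    thickness tapering from 30 mm at the axis to the 2 mm tube gap at the
    wall, and 5.4 um single-step correlation noise. Tests typically shrink
    the window and coarsen the pitch; the estimator does not care.
    """

    extent_mm: float = presets.FOV_MM
    pitch_mm: float = presets.DVC_PITCH_MM
    d_tube_mm: float = presets.D_TUBE_MM
    z_min_mm: float = presets.Z_GAP_MM
    z_max_mm: float = presets.Z_MAX_MM
    bumps: tuple[Bump, ...] = ()
    ramp: Literal["trilinear", "smooth"] = "trilinear"
    schedule_mm: tuple[float, ...] = tuple(presets.STEP_SCHEDULES_MM["Willow C"])
    noise_sigma_mm: float = presets.DVC_NOISE_MM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pitch_mm <= 0 or self.extent_mm <= 0:
            raise ValueError("pitch and extent must be > 0")
        if not 0.0 < self.z_min_mm <= self.z_max_mm:
            raise ValueError("need 0 < Z_min <= Z_max")
        if self.pitch_mm >= self.z_min_mm:
            raise ValueError(
                "grid pitch must resolve the minimum zone thickness "
                f"(pitch {self.pitch_mm} mm >= Z_min {self.z_min_mm} mm)"
            )
        if self.noise_sigma_mm < 0:
            raise ValueError("noise sigma must be >= 0")
        if any(np.diff(self.schedule_mm) <= 0) or self.schedule_mm[0] <= 0:
            raise ValueError("displacement schedule must be positive and increasing")
        object.__setattr__(self, "bumps", tuple(self.bumps))
        object.__setattr__(self, "schedule_mm", tuple(self.schedule_mm))


def zone_thickness(cfg: FieldGenConfig, x_mm: np.ndarray, y_mm: np.ndarray) -> np.ndarray:
    """Ground-truth local band thickness Z(x, y), mm.

    Double-cone taper Z_min + (Z_max - Z_min)(1 - 2 r / D_tube) plus the
    configured Gaussian root bumps, floored at Z_min.
    """
    x = np.asarray(x_mm, dtype=float)
    y = np.asarray(y_mm, dtype=float)
    r = np.hypot(x, y)
    z = cfg.z_min_mm + (cfg.z_max_mm - cfg.z_min_mm) * (1.0 - 2.0 * r / cfg.d_tube_mm)
    for b in cfg.bumps:
        d2 = (x - b.x_mm) ** 2 + (y - b.y_mm) ** 2
        z = z + b.amplitude_mm * np.exp(-d2 / b.radius_mm**2)
    return np.maximum(z, cfg.z_min_mm)


_SMOOTH_CALIBRATION: dict[None, float] = {}


def _smooth_width_factor() -> float:
    """Ratio of tri-linear best-fit thickness to the tanh ramp width w in
    u(z) = u0 (1 - tanh(2 z / w)) / 2, computed once numerically so that a
    requested thickness Z maps to w = Z / factor."""
    if None not in _SMOOTH_CALIBRATION:
        from .trilinear import FitSettings, fit_trilinear

        z = np.linspace(-12.0, 12.0, 1201)
        u = 0.5 * (1.0 - np.tanh(2.0 * z / 1.0))  # w = 1
        fit = fit_trilinear(z, u, FitSettings(noise_sigma_mm=0.0))
        _SMOOTH_CALIBRATION[None] = fit.thickness_mm / 1.0
    return _SMOOTH_CALIBRATION[None]


def _ramp_profile(z: np.ndarray, zone: np.ndarray, u_step: float, ramp: str) -> np.ndarray:
    """Noiseless u_x(z) per column: u_step below the band, 0 above.

    ``z`` has shape (nz,), ``zone`` (nx, ny); returns (nx, ny, nz).
    """
    zz = z[None, None, :]
    half = (zone / 2.0)[:, :, None]
    if ramp == "trilinear":
        frac = np.clip((zz + half) / (2.0 * half), 0.0, 1.0)  # 0 below, 1 above
    elif ramp == "smooth":
        w = (zone / _smooth_width_factor())[:, :, None]
        frac = 0.5 * (1.0 + np.tanh(2.0 * zz / w))
    else:
        raise ValueError(f"unknown ramp {ramp!r}")
    return u_step * (1.0 - frac)


def generate_field(cfg: FieldGenConfig, step: int) -> DisplacementField:
    """Synthetic displacement field at one load step (1-based).

    Cumulative displacement of the lower half is the schedule value at that
    step; noise is i.i.d. Gaussian per component with sigma scaled linearly
    by the step count (successive-scan correlation accumulates noise). The
    noiseless part is identical across seeds.
    """
    if not 1 <= step <= len(cfg.schedule_mm):
        raise ValueError(
            f"step must lie in [1, {len(cfg.schedule_mm)}], got {step}"
        )
    u_step = cfg.schedule_mm[step - 1]
    half = cfg.extent_mm / 2.0
    n = int(round(cfg.extent_mm / cfg.pitch_mm)) + 1
    coords = -half + cfg.pitch_mm * np.arange(n)
    zone = zone_thickness(cfg, *np.meshgrid(coords, coords, indexing="ij"))
    ux = _ramp_profile(coords, zone, u_step, cfg.ramp)
    u = np.zeros((n, n, n, 3))
    u[..., 0] = ux
    if cfg.noise_sigma_mm > 0:
        rng = np.random.default_rng((cfg.seed, step))
        u = u + rng.normal(0.0, cfg.noise_sigma_mm * step, size=u.shape)
    return DisplacementField(
        u_mm=u,
        pitch_mm=cfg.pitch_mm,
        origin_mm=np.array([-half, -half, -half]),
        step_index=step,
    )


# ---------------------------------------------------------------------------
# root populations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RootMapConfig:
    """Random root population on the shear plane.

    Diameters are lognormal, truncated to [d_min, d_max]; positions are
    biased toward the sidewall (pot-grown systems deflect roots outward),
    with ``edge_bias`` the probability mass placed within ``edge_band_mm``
    of the wall. Either a target area ratio (draw-until-RAR, closed exactly
    by resizing the final root) or a fixed count may be requested.
    """

    target_rar: float | None = None
    n_roots: int | None = None
    d_tube_mm: float = presets.D_TUBE_MM
    diameter_log_mean: float = math.log(0.8)
    diameter_log_sigma: float = 0.6
    diameter_min_mm: float = 0.1
    diameter_max_mm: float = 4.0
    edge_bias: float = 0.6
    edge_band_mm: float = 20.0
    e_mpa: float = presets.E_ROOT_MPA["willow"]
    seed: int = 0
    max_attempts: int = 100_000

    def __post_init__(self) -> None:
        if (self.target_rar is None) == (self.n_roots is None):
            raise ValueError("give exactly one of target_rar or n_roots")
        if self.target_rar is not None and not 0.0 < self.target_rar < 0.05:
            raise ValueError("target RAR must lie in (0, 0.05)")
        if self.n_roots is not None and self.n_roots < 0:
            raise ValueError("n_roots must be >= 0")
        if not 0.0 <= self.edge_bias <= 1.0:
            raise ValueError("edge_bias must lie in [0, 1]")
        if not 0.0 < self.diameter_min_mm < self.diameter_max_mm:
            raise ValueError("need 0 < d_min < d_max")


def _draw_position(rng: np.random.Generator, cfg: RootMapConfig, d_mm: float):
    """Area-uniform position, in the edge band with probability edge_bias,
    keeping the whole root cross-section inside the tube."""
    r_out = cfg.d_tube_mm / 2.0 - d_mm / 2.0
    r_edge = max(cfg.d_tube_mm / 2.0 - cfg.edge_band_mm, 0.0)
    if rng.random() < cfg.edge_bias and r_edge < r_out:
        r1, r2 = r_edge, r_out
    else:
        r1, r2 = 0.0, r_out
    r = math.sqrt(rng.random() * (r2**2 - r1**2) + r1**2)
    theta = rng.random() * 2.0 * math.pi
    return r * math.cos(theta), r * math.sin(theta)


def generate_root_map(cfg: RootMapConfig) -> list[Root]:
    """Random list of roots on the shear plane.

    In draw-until-RAR mode the final root's diameter is shrunk so the
    achieved area ratio equals the target exactly; a target unreachable
    within ``max_attempts`` draws raises.
    """
    rng = np.random.default_rng(cfg.seed)
    plane_area = math.pi * (cfg.d_tube_mm / 2.0) ** 2
    roots: list[Root] = []

    def draw_diameter() -> float:
        for _ in range(cfg.max_attempts):
            d = float(rng.lognormal(cfg.diameter_log_mean, cfg.diameter_log_sigma))
            if cfg.diameter_min_mm <= d <= cfg.diameter_max_mm:
                return d
        raise RuntimeError("diameter distribution rejected every draw")

    if cfg.n_roots is not None:
        for i in range(cfg.n_roots):
            d = draw_diameter()
            x, y = _draw_position(rng, cfg, d)
            roots.append(Root(x, y, d, cfg.e_mpa, label=f"r{i:03d}"))
        return roots

    target_area = cfg.target_rar * plane_area
    area = 0.0
    for i in range(cfg.max_attempts):
        d = draw_diameter()
        if area + math.pi * (d / 2.0) ** 2 >= target_area:
            # close the target exactly with a resized final root
            d = 2.0 * math.sqrt((target_area - area) / math.pi)
            if d < 1e-6:
                break
            x, y = _draw_position(rng, cfg, d)
            roots.append(Root(x, y, d, cfg.e_mpa, label=f"r{i:03d}"))
            return roots
        x, y = _draw_position(rng, cfg, d)
        roots.append(Root(x, y, d, cfg.e_mpa, label=f"r{i:03d}"))
        area += roots[-1].area_mm2
    else:
        raise RuntimeError(
            f"target RAR {cfg.target_rar} not reached in {cfg.max_attempts} draws"
        )
    return roots


# ---------------------------------------------------------------------------
# stress records and root paths
# ---------------------------------------------------------------------------


def generate_stress_record(
    spec: Specimen,
    u_schedule_mm: Sequence[float],
    noise_sigma_kpa: float = 0.0,
    seed: int = 0,
    z_policy: ZPolicy = "positional_with_growth",
    z_const_mm: float | None = None,
) -> ShearTestRecord:
    """Forward-modelled stress record with i.i.d. Gaussian stress noise —
    the synthetic analogue of a measured shear trace, for testing the
    interface-stress back-analysis."""
    if noise_sigma_kpa < 0:
        raise ValueError("stress noise must be >= 0")
    pred: StressCurvePrediction = predict_stress_curve(
        spec, u_schedule_mm, z_policy, z_const_mm
    )
    s = pred.record.s_kpa.copy()
    if noise_sigma_kpa > 0:
        rng = np.random.default_rng(seed)
        s = s + rng.normal(0.0, noise_sigma_kpa, size=s.shape)
    return ShearTestRecord(pred.record.u_mm, s, label=spec.label or "synthetic")


def _fillet(p_prev, corner, p_next, radius, n_arc):
    """Replace a 2-D polyline corner by a tangent circular arc.

    Returns the arc points (excluding the neighbours); raises when the
    tangent length does not fit the adjoining segments.
    """
    v_in = corner - p_prev
    v_out = p_next - corner
    l_in, l_out = np.linalg.norm(v_in), np.linalg.norm(v_out)
    d_in, d_out = v_in / l_in, v_out / l_out
    cosang = float(np.clip(d_in @ d_out, -1.0, 1.0))
    theta = math.acos(cosang)  # turn angle
    if theta < 1e-12:
        return np.empty((0, 2))
    t = radius * math.tan(theta / 2.0)
    if t > l_in - 1e-9 or t > l_out - 1e-9:
        raise ValueError(
            f"bend radius {radius} mm too large for segments of "
            f"{l_in:.2f} and {l_out:.2f} mm"
        )
    t_in = corner - d_in * t
    # arc centre: offset from the in-tangent point perpendicular to d_in,
    # on the side of the turn
    turn = math.copysign(1.0, d_in[0] * d_out[1] - d_in[1] * d_out[0])
    normal_in = turn * np.array([-d_in[1], d_in[0]])
    centre = t_in + radius * normal_in
    a0 = math.atan2(*(t_in - centre)[::-1])
    angles = a0 + turn * np.linspace(0.0, theta, n_arc + 1)
    return centre + radius * np.column_stack([np.cos(angles), np.sin(angles)])


def generate_root_path(
    kind: Literal["trilinear", "curved"],
    z_mm: float,
    u_x_mm: float,
    bend_radius_mm: float = 0.0,
    anchor_margin_mm: float | None = None,
    label: str = "root",
    step_index: int = 7,
    n_arc: int = 64,
) -> RootPath:
    """Deformed path of an initially vertical root crossing the shear zone.

    Below the zone the root moves with the lower soil (offset ``u_x`` in x);
    above it stays put; across the zone the idealized shape is a straight
    inclined segment (``trilinear``). The ``curved`` variant replaces each
    knee with a circular arc of ``bend_radius_mm`` tangent to both limbs —
    the shape real roots take by locally compressing the soil — which is
    strictly shorter. ``u_x = 0`` gives the undeformed straight path; a zero
    bend radius degenerates to the tri-linear path.
    """
    if z_mm <= 0:
        raise ValueError("zone thickness must be > 0")
    if u_x_mm < 0 or bend_radius_mm < 0:
        raise ValueError("displacement and bend radius must be >= 0")
    margin = anchor_margin_mm if anchor_margin_mm is not None else max(z_mm, 10.0)
    lo, hi = -z_mm / 2.0 - margin, z_mm / 2.0 + margin
    pts2 = np.array(
        [
            [u_x_mm, lo],
            [u_x_mm, -z_mm / 2.0],
            [0.0, z_mm / 2.0],
            [0.0, hi],
        ]
    )
    if u_x_mm == 0.0:
        pts2 = np.array([[0.0, lo], [0.0, hi]])
    elif kind == "curved" and bend_radius_mm > 0.0:
        arc_b = _fillet(pts2[0], pts2[1], pts2[2], bend_radius_mm, n_arc)
        arc_c = _fillet(pts2[1], pts2[2], pts2[3], bend_radius_mm, n_arc)
        pts2 = np.vstack([pts2[0], arc_b, arc_c, pts2[3]])
    elif kind not in ("trilinear", "curved"):
        raise ValueError(f"unknown path kind {kind!r}")
    pts3 = np.column_stack([pts2[:, 0], np.zeros(len(pts2)), pts2[:, 1]])
    return RootPath(points_mm=pts3, label=label, step_index=step_index)
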