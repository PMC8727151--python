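"""Waldron-type root-reinforcement model for direct shear, with a spatially
non-uniform and displacement-dependent shear-zone thickness.

The classical model treats each root crossing the shear zone as a linear
elastic fibre, initially perpendicular to the zone. Relative displacement
``u_x`` across a zone of thickness ``Z`` rotates the in-zone segment to an
inclination ``beta = arctan(u_x / Z)`` and stretches it; the mobilised
tension, limited by the bond stress ``tau'`` at the root-soil interface,
adds shear resistance both directly and through extra normal stress on the
plane. Summing over roots, the added resistance is

    dS = sum_i  a_r,i * k_i * (sec beta_i - 1)^0.5
                * (sin beta_i + cos beta_i * tan phi')
    k   = (4 tau' Z E / D)^0.5

with ``a_r,i`` the root's area ratio on the shear plane, ``E`` its Young's
modulus and ``D`` its diameter.

The two modifications implemented here reflect what volumetric imaging of
sheared root-soil columns shows:

* the zone is not a uniform slab — it is pinched to the tube gap at the
  sidewall and thickest at the centre, so each root sees a local thickness
  interpolated linearly in its radial position (``local_shear_zone``);
* the zone grows as shear proceeds — thickness is ramped from zero to 80%
  of its peak by the third displacement step and to 100% by the final step
  (``grown_shear_zone``), floored at the tube gap so the kinematics never
  degenerate.

Units at the API surface follow lab convention: lengths in mm, soil
stresses in kPa, root stiffness in MPa, friction angle in degrees; angles
``beta`` are radians. Conversions happen once, inside the closed forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .units import deg_to_rad, mpa_to_kpa

__all__ = [
    "Root",
    "SoilParams",
    "InterfaceParams",
    "GrowthSchedule",
    "ShearZoneModel",
    "Specimen",
    "RootStressResult",
    "ShearTestRecord",
    "StressCurvePrediction",
    "ZPolicy",
    "compute_beta",
    "bond_factor_k",
    "root_delta_S",
    "specimen_delta_S",
    "local_shear_zone",
    "grown_shear_zone",
    "root_extension",
    "axial_stress",
    "stressed_length",
    "root_response",
    "predict_stress_curve",
    "sensitivity_sweep",
    "hyperbolic_baseline",
]

ZPolicy = Literal["constant", "positional", "positional_with_growth"]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Root:
    """A single root crossing the shear plane.

    Coordinates are on the shear plane relative to the tube axis (mm);
    ``diameter_mm`` is the root diameter at the plane and ``e_mpa`` the
    species-level Young's modulus.
    """

    x_mm: float
    y_mm: float
    diameter_mm: float
    e_mpa: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError(f"root {self.label!r}: diameter must be > 0")
        if self.e_mpa <= 0:
            raise ValueError(f"root {self.label!r}: Young's modulus must be > 0")

    @property
    def d_root_mm(self) -> float:
        """Radial distance from the tube axis."""
        return math.hypot(self.x_mm, self.y_mm)

    @property
    def area_mm2(self) -> float:
        return math.pi * (self.diameter_mm / 2.0) ** 2


@dataclass(frozen=True)
class SoilParams:
    """Soil strength inputs: friction angle and the fallow (unrooted)
    stress-displacement baseline the root contribution is added to.

    The baseline is a monotone piecewise-linear map, given as matched arrays
    of displacement (mm) and shear stress (kPa). It may come from a measured
    fallow test or a fitted curve; ``baseline_source`` records which.
    """

    phi_deg: float
    baseline_u_mm: np.ndarray | None = None
    baseline_s_kpa: np.ndarray | None = None
    baseline_source: str = "unspecified"

    def __post_init__(self) -> None:
        if not 0.0 < self.phi_deg < 90.0:
            raise ValueError("friction angle must lie in (0, 90) degrees")
        if (self.baseline_u_mm is None) != (self.baseline_s_kpa is None):
            raise ValueError("baseline displacement and stress must come together")
        if self.baseline_u_mm is not None:
            u = np.asarray(self.baseline_u_mm, dtype=float)
            s = np.asarray(self.baseline_s_kpa, dtype=float)
            if u.ndim != 1 or u.shape != s.shape or u.size < 2:
                raise ValueError("baseline must be two matched 1-D arrays, n >= 2")
            if np.any(np.diff(u) <= 0):
                raise ValueError("baseline displacements must be strictly increasing")
            if np.any(s < 0):
                raise ValueError("baseline stress must be non-negative")
            object.__setattr__(self, "baseline_u_mm", u)
            object.__setattr__(self, "baseline_s_kpa", s)

    @property
    def tan_phi(self) -> float:
        return math.tan(deg_to_rad(self.phi_deg))

    @property
    def has_baseline(self) -> bool:
        return self.baseline_u_mm is not None

    def baseline(self, u_mm: np.ndarray, extrapolate: bool = False) -> np.ndarray:
        """Evaluate the fallow baseline at displacements ``u_mm``.

        Outside the tabulated range this raises unless ``extrapolate=True``,
        in which case end values are held.
        """
        if not self.has_baseline:
            raise ValueError("no fallow baseline attached to these soil parameters")
        u = np.asarray(u_mm, dtype=float)
        lo, hi = self.baseline_u_mm[0], self.baseline_u_mm[-1]
        if not extrapolate and (np.any(u < lo - 1e-12) or np.any(u > hi + 1e-12)):
            raise ValueError(
                f"displacement outside baseline domain [{lo}, {hi}] mm; "
                "pass extrapolate=True to hold end values"
            )
        return np.interp(u, self.baseline_u_mm, self.baseline_s_kpa)


@dataclass(frozen=True)
class InterfaceParams:
    """Limiting bond (interface friction) stress between root and soil, kPa.

    This lumps interface friction and the anchoring effect of laterals and
    branches; it is the one model parameter usually obtained by fitting.
    """

    tau_prime_kpa: float

    def __post_init__(self) -> None:
        if self.tau_prime_kpa <= 0:
            raise ValueError("tau' must be > 0")


@dataclass(frozen=True)
class GrowthSchedule:
    """Piecewise-linear growth of shear-zone thickness with displacement.

    The thickness fraction rises from 0 at zero displacement to ``f_step3``
    (default 0.8) at the third displacement step ``u_step3_mm``, then to 1.0
    at the final step ``u_final_mm``, and is clamped at 1.0 beyond.
    """

    u_step3_mm: float
    u_final_mm: float
    f_step3: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 < self.u_step3_mm < self.u_final_mm:
            raise ValueError("need 0 < u_step3 < u_final")
        if not 0.0 < self.f_step3 <= 1.0:
            raise ValueError("f_step3 must lie in (0, 1]")

    def factor(self, u_mm: float) -> float:
        """Thickness fraction at displacement ``u_mm`` (scalar, in [0, 1])."""
        if u_mm < 0:
            raise ValueError("displacement must be non-negative")
        if u_mm <= self.u_step3_mm:
            return self.f_step3 * u_mm / self.u_step3_mm
        if u_mm >= self.u_final_mm:
            return 1.0
        span = self.u_final_mm - self.u_step3_mm
        return self.f_step3 + (1.0 - self.f_step3) * (u_mm - self.u_step3_mm) / span


@dataclass(frozen=True)
class ShearZoneModel:
    """Geometry of the shear zone across the tube cross-section.

    Thickness interpolates linearly from ``z_max_mm`` at the tube axis to
    ``z_min_mm`` (the inter-tube gap) at the sidewall; ``growth`` optionally
    scales it with applied displacement.
    """

    z_min_mm: float
    z_max_mm: float
    d_tube_mm: float
    growth: GrowthSchedule | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.z_min_mm <= self.z_max_mm:
            raise ValueError("need 0 < Z_min <= Z_max")
        if self.d_tube_mm <= 0:
            raise ValueError("tube diameter must be > 0")


@dataclass(frozen=True)
class Specimen:
    """A rooted (or fallow) direct-shear specimen: root population, soil,
    interface and shear-zone geometry."""

    roots: tuple[Root, ...]
    soil: SoilParams
    interface: InterfaceParams
    zone: ShearZoneModel
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "roots", tuple(self.roots))
        r_tube = self.zone.d_tube_mm / 2.0
        for root in self.roots:
            if root.d_root_mm > r_tube + 1e-9:
                raise ValueError(
                    f"root {root.label!r} at r={root.d_root_mm:.2f} mm lies "
                    f"outside the tube (radius {r_tube:.2f} mm)"
                )
        if not 0.0 <= self.rar < 1.0:
            raise ValueError("root area ratio must lie in [0, 1)")

    @property
    def plane_area_mm2(self) -> float:
        return math.pi * (self.zone.d_tube_mm / 2.0) ** 2

    @property
    def rar(self) -> float:
        """Root area ratio: summed root cross-section over shear-plane area."""
        return sum(r.area_mm2 for r in self.roots) / self.plane_area_mm2

    def area_ratio(self, root: Root) -> float:
        return root.area_mm2 / self.plane_area_mm2


@dataclass(frozen=True)
class RootStressResult:
    """Per-root state at one applied displacement: inclination, bond factor,
    shear-resistance contribution, axial stress and stressed length."""

    label: str
    z_mm: float
    beta_rad: float
    k_kpa: float
    delta_s_kpa: float
    delta_l_mm: float
    stressed_length_mm: float
    sigma_axial_mpa: float


@dataclass(frozen=True)
class ShearTestRecord:
    """Measured (or synthesized) shear stress-displacement trace."""

    u_mm: np.ndarray
    s_kpa: np.ndarray
    label: str = ""
    step_u_mm: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        u = np.asarray(self.u_mm, dtype=float)
        s = np.asarray(self.s_kpa, dtype=float)
        if u.ndim != 1 or u.shape != s.shape or u.size < 1:
            raise ValueError("record needs matched 1-D displacement/stress arrays")
        if np.any(np.diff(u) <= 0):
            raise ValueError("record displacements must be strictly increasing")
        if not np.all(np.isfinite(s)):
            raise ValueError("record stresses must be finite")
        object.__setattr__(self, "u_mm", u)
        object.__setattr__(self, "s_kpa", s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"u_mm": self.u_mm, "S_kpa": self.s_kpa})


@dataclass(frozen=True)
class StressCurvePrediction:
    """Model output: the predicted curve plus per-root diagnostics evaluated
    at the last displacement of the grid."""

    record: ShearTestRecord
    delta_s_kpa: np.ndarray
    diagnostics: pd.DataFrame
    z_policy: str
    baseline_source: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "u_mm": self.record.u_mm,
                "dS_kpa": self.delta_s_kpa,
                "total_kpa": self.record.s_kpa,
            }
        )


# ---------------------------------------------------------------------------
# closed-form pieces
# ---------------------------------------------------------------------------


def _sec_minus_one(beta_rad: float) -> float:
    """sec(beta) - 1 evaluated as 2 sin^2(beta/2) / cos(beta), which avoids
    the catastrophic cancellation of 1/cos(beta) - 1 at small inclinations."""
    return 2.0 * math.sin(beta_rad / 2.0) ** 2 / math.cos(beta_rad)


def compute_beta(u_x_mm: float, z_mm: float) -> float:
    """Inclination of the deformed in-zone root segment, arctan(u_x / Z)."""
    if z_mm <= 0:
        raise ValueError("shear zone thickness must be > 0")
    if u_x_mm < 0:
        raise ValueError("shear displacement must be >= 0")
    return math.atan2(u_x_mm, z_mm)


def bond_factor_k(
    tau_prime_kpa: float, z_mm: float, e_mpa: float, d_mm: float
) -> float:
    """Bond factor k = (4 tau' Z E / D)^0.5, in kPa.

    Z and D enter as a ratio so only the stiffness needs converting to kPa.
    """
    if min(tau_prime_kpa, z_mm, e_mpa, d_mm) <= 0:
        raise ValueError("all inputs to the bond factor must be > 0")
    return math.sqrt(4.0 * tau_prime_kpa * (z_mm / d_mm) * mpa_to_kpa(e_mpa))


def root_extension(z_mm: float, beta_rad: float) -> float:
    """Elongation of the in-zone segment, Z (sec beta - 1), assuming the
    idealised tri-linear deformed shape."""
    if z_mm <= 0:
        raise ValueError("shear zone thickness must be > 0")
    if not 0.0 <= beta_rad < math.pi / 2.0:
        raise ValueError("beta must lie in [0, pi/2)")
    return z_mm * _sec_minus_one(beta_rad)


def axial_stress(delta_l_mm: float, l0_mm: float, e_mpa: float) -> float:
    """Linear-elastic axial stress (Δl / l0) E, in MPa."""
    if l0_mm <= 0:
        raise ValueError("initial stressed length must be > 0")
    if delta_l_mm < 0:
        raise ValueError("extension must be >= 0")
    return (delta_l_mm / l0_mm) * e_mpa


def stressed_length(
    tau_prime_kpa: float,
    z_mm: float,
    e_mpa: float,
    d_mm: float,
    beta_rad: float,
) -> float:
    """Length of root over which tension is transferred into the soil, mm:
    l = k (sec beta - 1)^0.5 D / (2 tau')."""
    if not 0.0 <= beta_rad < math.pi / 2.0:
        raise ValueError("beta must lie in [0, pi/2)")
    k = bond_factor_k(tau_prime_kpa, z_mm, e_mpa, d_mm)
    return k * math.sqrt(_sec_minus_one(beta_rad)) * d_mm / (2.0 * tau_prime_kpa)


def local_shear_zone(zone: ShearZoneModel, d_root_mm: float) -> float:
    """Local zone thickness at radial position ``d_root_mm``:
    Z_max at the tube axis tapering linearly to Z_min at the sidewall."""
    r_tube = zone.d_tube_mm / 2.0
    if not 0.0 <= d_root_mm <= r_tube + 1e-9:
        raise ValueError(
            f"radial position {d_root_mm} mm outside tube radius {r_tube} mm"
        )
    d = min(d_root_mm, r_tube)
    return zone.z_max_mm - d * (zone.z_max_mm - zone.z_min_mm) / r_tube


def grown_shear_zone(
    zone: ShearZoneModel, z_peak_mm: float, u_x_mm: float
) -> float:
    """Displacement-dependent thickness: the growth factor applied to the
    peak local thickness, floored at the tube gap ``z_min_mm`` (the physical
    gap always exists, so the kinematics never see Z = 0)."""
    if u_x_mm < 0:
        raise ValueError("displacement must be >= 0")
    if zone.growth is None:
        raise ValueError("shear zone model has no growth schedule attached")
    f = zone.growth.factor(u_x_mm)
    return max(f * z_peak_mm, zone.z_min_mm)


# ---------------------------------------------------------------------------
# per-root and per-specimen assembly
# ---------------------------------------------------------------------------


def root_response(
    root: Root,
    a_r_i: float,
    u_x_mm: float,
    z_mm: float,
    soil: SoilParams,
    iface: InterfaceParams,
) -> RootStressResult:
    """Full per-root state at one displacement and zone thickness."""
    if a_r_i < 0:
        raise ValueError("per-root area ratio must be >= 0")
    beta = compute_beta(u_x_mm, z_mm)
    k = bond_factor_k(iface.tau_prime_kpa, z_mm, root.e_mpa, root.diameter_mm)
    sec_m1 = _sec_minus_one(beta)
    ds = a_r_i * k * math.sqrt(sec_m1) * (
        math.sin(beta) + math.cos(beta) * soil.tan_phi
    )
    dl = root_extension(z_mm, beta)
    ell = stressed_length(
        iface.tau_prime_kpa, z_mm, root.e_mpa, root.diameter_mm, beta
    )
    # sigma = (dl / l) E with l the stressed length at this state; both vanish
    # together at u_x = 0 where the root carries no load.
    sigma = axial_stress(dl, ell, root.e_mpa) if dl > 0 else 0.0
    return RootStressResult(
        label=root.label,
        z_mm=z_mm,
        beta_rad=beta,
        k_kpa=k,
        delta_s_kpa=ds,
        delta_l_mm=dl,
        stressed_length_mm=ell,
        sigma_axial_mpa=sigma,
    )


def root_delta_S(
    root: Root,
    a_r_i: float,
    u_x_mm: float,
    z_mm: float,
    soil: SoilParams,
    iface: InterfaceParams,
) -> float:
    """Single-root contribution to the added shear resistance, kPa."""
    return root_response(root, a_r_i, u_x_mm, z_mm, soil, iface).delta_s_kpa


def _root_thickness(
    spec: Specimen, root: Root, u_x_mm: float, z_policy: ZPolicy, z_const_mm: float | None
) -> float:
    if z_policy == "constant":
        if z_const_mm is None:
            raise ValueError("constant policy needs z_const_mm")
        return z_const_mm
    z_local = local_shear_zone(spec.zone, root.d_root_mm)
    if z_policy == "positional":
        return z_local
    if z_policy == "positional_with_growth":
        return grown_shear_zone(spec.zone, z_local, u_x_mm)
    raise ValueError(f"unknown Z policy {z_policy!r}")


def specimen_delta_S(
    spec: Specimen,
    u_x_mm: float,
    z_policy: ZPolicy = "positional",
    z_const_mm: float | None = None,
) -> float:
    """Added shear resistance of the whole specimen at one displacement, kPa.

    Additive over roots; zero for a fallow specimen. Under the ``constant``
    policy every root sees ``z_const_mm``; under ``positional`` each root
    sees its local thickness; ``positional_with_growth`` additionally scales
    it with the growth schedule evaluated at ``u_x_mm``.
    """
    total = 0.0
    for root in spec.roots:
        z = _root_thickness(spec, root, u_x_mm, z_policy, z_const_mm)
        total += root_delta_S(
            root, spec.area_ratio(root), u_x_mm, z, spec.soil, spec.interface
        )
    return total


def specimen_responses(
    spec: Specimen,
    u_x_mm: float,
    z_policy: ZPolicy = "positional",
    z_const_mm: float | None = None,
) -> list[RootStressResult]:
    """Per-root diagnostics at one displacement."""
    out = []
    for root in spec.roots:
        z = _root_thickness(spec, root, u_x_mm, z_policy, z_const_mm)
        out.append(
            root_response(
                root, spec.area_ratio(root), u_x_mm, z, spec.soil, spec.interface
            )
        )
    return out


def predict_stress_curve(
    spec: Specimen,
    u_grid_mm: Sequence[float] | np.ndarray,
    z_policy: ZPolicy = "positional_with_growth",
    z_const_mm: float | None = None,
    extrapolate_baseline: bool = False,
) -> StressCurvePrediction:
    """Predicted total shear stress-displacement curve.

    Total stress is the fallow baseline plus the summed root contribution;
    with no baseline attached the curve is the root contribution alone.
    Diagnostics (per-root sigma_axial and stressed length) are evaluated at
    the last grid displacement, where root loads peak.
    """
    u = np.asarray(u_grid_mm, dtype=float)
    if u.ndim != 1 or u.size < 1:
        raise ValueError("displacement grid must be a non-empty 1-D array")
    if np.any(np.diff(u) <= 0) or u[0] < 0:
        raise ValueError("displacement grid must be ascending and start >= 0")

    ds = np.array(
        [specimen_delta_S(spec, ui, z_policy, z_const_mm) for ui in u]
    )
    if spec.soil.has_baseline:
        total = spec.soil.baseline(u, extrapolate=extrapolate_baseline) + ds
        source = spec.soil.baseline_source
    else:
        total = ds.copy()
        source = "none (root contribution only)"

    responses = specimen_responses(spec, float(u[-1]), z_policy, z_const_mm)
    diag = pd.DataFrame(
        {
            "label": [r.label for r in responses],
            "Z_mm": [r.z_mm for r in responses],
            "beta_rad": [r.beta_rad for r in responses],
            "sigma_axial_MPa": [r.sigma_axial_mpa for r in responses],
            "l_mm": [r.stressed_length_mm for r in responses],
        }
    )
    record = ShearTestRecord(u, total, label=spec.label)
    return StressCurvePrediction(
        record=record,
        delta_s_kpa=ds,
        diagnostics=diag,
        z_policy=z_policy,
        baseline_source=source,
    )


# ---------------------------------------------------------------------------
# sensitivity study
# ---------------------------------------------------------------------------


def sensitivity_sweep(
    z_grid_mm: Sequence[float],
    tau_grid_kpa: Sequence[float],
    u_grid_mm: Sequence[float],
    d_mm: float = 1.0,
    e_mpa: float = 200.0,
    phi_deg: float = 36.0,
    a_r: float = 0.00409,
) -> pd.DataFrame:
    """Tidy sweep of added resistance and stressed length over zone
    thickness, bond stress and displacement.

    Defaults probe a 1 mm willow-like root at a willow-specimen area ratio.
    Columns: ``Z_mm, tau_kpa, u_mm, dS_kpa, l_mm``.
    """
    soil = SoilParams(phi_deg=phi_deg)
    rows = []
    for z in z_grid_mm:
        for tau in tau_grid_kpa:
            iface = InterfaceParams(tau_prime_kpa=float(tau))
            root = Root(0.0, 0.0, d_mm, e_mpa, label="probe")
            for u in u_grid_mm:
                res = root_response(root, a_r, float(u), float(z), soil, iface)
                rows.append(
                    {
                        "Z_mm": float(z),
                        "tau_kpa": float(tau),
                        "u_mm": float(u),
                        "dS_kpa": res.delta_s_kpa,
                        "l_mm": res.stressed_length_mm,
                    }
                )
    return pd.DataFrame(rows)


def hyperbolic_baseline(
    s_ult_kpa: float, u_ref_mm: float, u_max_mm: float, n: int = 200
) -> tuple[np.ndarray, np.ndarray]:
    """Tabulate a hyperbolic fallow curve S = S_ult u / (u_ref + u) as the
    piecewise-linear baseline table the model consumes."""
    if s_ult_kpa < 0 or u_ref_mm <= 0 or u_max_mm <= 0:
        raise ValueError("baseline parameters must be positive")
    u = np.linspace(0.0, u_max_mm, n)
    return u, s_ult_kpa * u / (u_ref_mm + u)
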