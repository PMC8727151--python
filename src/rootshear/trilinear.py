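"""Tri-linear changepoint fitting of depth vs shear-direction displacement
profiles.

Across a shear band, a column of soil shows a characteristic profile of
x-displacement against depth: constant below the band (the displaced half),
constant above it (the fixed half), and a linear ramp between two knees.
Fitting that tri-linear shape by least squares and taking the z-distance
between the knees gives an operator-free measure of local shear-zone
thickness, repeatable across tens of thousands of columns.

The fit minimises sum (u_obs - u_model)^2 over knee depths (z_lower,
z_upper) and plateau displacements (u_below, u_above), with the model
continuous at both knees; the plateaus are "vertical lines" in the depth vs
displacement plot, i.e. zero strain outside the band. The solver is a
deterministic two-stage scheme: an exhaustive search over knee pairs placed
at the profile's own z-levels (plateaus solved in closed form for each
candidate), followed by continuous local refinement of the knees. Ties in
the search stage break toward the smallest thickness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .field import DisplacementField

__all__ = ["TrilinearFit", "FitSettings", "extract_profile", "fit_trilinear"]


@dataclass(frozen=True)
class FitSettings:
    """Solver settings for the tri-linear fit.

    ``noise_sigma_mm`` is the expected displacement noise of one
    correlation step (used only for the fit-quality flag; multiply by the
    step count upstream when profiles accumulate steps);
    ``plateau_snr`` flags fits whose plateau separation is below
    ``plateau_snr * noise_sigma_mm`` as unreliable; ``candidate_stride``
    subsamples the knee-candidate levels in the search stage; ``refine``
    switches the continuous knee refinement.
    """

    noise_sigma_mm: float = 0.0054
    plateau_snr: float = 3.0
    candidate_stride: int = 1
    refine: bool = True
    min_points: int = 6

    def __post_init__(self) -> None:
        if self.noise_sigma_mm < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.candidate_stride < 1:
            raise ValueError("candidate stride must be >= 1")


@dataclass(frozen=True)
class TrilinearFit:
    """Result of one profile fit. ``thickness_mm = z_upper - z_lower``;
    ``ok`` is False when the profile carries no resolvable shear band."""

    z_lower_mm: float
    z_upper_mm: float
    u_below_mm: float
    u_above_mm: float
    rss: float
    ok: bool
    message: str = ""

    @property
    def thickness_mm(self) -> float:
        return self.z_upper_mm - self.z_lower_mm


def _failed(message: str) -> TrilinearFit:
    nan = float("nan")
    return TrilinearFit(nan, nan, nan, nan, nan, ok=False, message=message)


def extract_profile(
    field: DisplacementField, x_mm: float, y_mm: float, min_points: int = 6
) -> tuple[np.ndarray, np.ndarray]:
    """z-sorted (z, u_x) profile of one grid column, masked nodes excluded.

    Off-grid (x, y) raises; a column with fewer than ``min_points`` valid
    nodes returns empty arrays (a flagged-empty profile).
    """
    i, j = field.nearest_column(x_mm, y_mm)
    valid = field.mask[i, j, :]
    if valid.sum() < min_points:
        return np.empty(0), np.empty(0)
    z = field.z_mm[valid]
    ux = field.u_mm[i, j, valid, 0]
    order = np.argsort(z)
    return z[order], ux[order]


# ---------------------------------------------------------------------------
# candidate-search machinery (shared with the map builder)
# ---------------------------------------------------------------------------


class _CandidateBasis:
    """Precomputed knee-pair candidates and their normal-equation terms for
    one z-grid; reusable across every column sharing that grid."""

    MAX_ELEMENTS = 4e7  # cap on ncand * npts; stride grows to respect it

    def __init__(self, z: np.ndarray, stride: int = 1):
        self.z = z
        n = z.size
        # coarsen the candidate lattice on very fine grids; the continuous
        # refinement stage recovers sub-stride knee positions
        while (n / stride) ** 2 / 2.0 * n > self.MAX_ELEMENTS:
            stride += 1
        levels = np.arange(0, n, stride)
        il, iu = np.meshgrid(levels, levels, indexing="ij")
        keep = iu > il
        self.zl = z[il[keep]]
        self.zu = z[iu[keep]]
        width = self.zu - self.zl
        # ramp fraction phi in [0, 1]: 0 on the lower plateau, 1 on the upper
        phi = np.clip((z[None, :] - self.zl[:, None]) / width[:, None], 0.0, 1.0)
        self.phi = phi
        self.s22 = np.einsum("cn,cn->c", phi, phi)
        sum_phi = phi.sum(axis=1)
        self.s12 = sum_phi - self.s22
        self.s11 = n - 2.0 * sum_phi + self.s22
        self.det = self.s11 * self.s22 - self.s12**2

    def solve(self, u: np.ndarray):
        """Closed-form plateau displacements and RSS for every candidate,
        for one profile ``u`` (or a stack of profiles, shape (n, ncol))."""
        single = u.ndim == 1
        U = u[:, None] if single else u
        b2 = self.phi @ U                      # (ncand, ncol)
        b1 = U.sum(axis=0)[None, :] - b2
        det = self.det[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            u_b = (b1 * self.s22[:, None] - b2 * self.s12[:, None]) / det
            u_a = (b2 * self.s11[:, None] - b1 * self.s12[:, None]) / det
        rss = (U * U).sum(axis=0)[None, :] - (u_b * b1 + u_a * b2)
        bad = ~np.isfinite(rss)
        rss[bad] = np.inf
        if single:
            return u_b[:, 0], u_a[:, 0], rss[:, 0]
        return u_b, u_a, rss

    def best(self, rss: np.ndarray) -> int:
        """Index of the minimal-RSS candidate; ties break to the smallest
        thickness so a degenerate band is never widened by the tie."""
        rmin = rss.min()
        tol = max(abs(rmin) * 1e-12, 1e-15)
        tied = np.flatnonzero(rss <= rmin + tol)
        widths = self.zu[tied] - self.zl[tied]
        return int(tied[np.argmin(widths)])


def _plateaus_and_rss(z, u, zl, zu):
    """Closed-form plateaus and residuals for given knees on one profile."""
    if zu - zl < 1e-12:
        phi = (z > 0.5 * (zl + zu)).astype(float)
    else:
        phi = np.clip((z - zl) / (zu - zl), 0.0, 1.0)
    one = 1.0 - phi
    s11, s12, s22 = one @ one, one @ phi, phi @ phi
    b1, b2 = one @ u, phi @ u
    det = s11 * s22 - s12 * s12
    if det <= 1e-12 * max(s11 * s22, 1e-30):
        mean = u.mean()
        return mean, mean, u - mean
    u_b = (b1 * s22 - b2 * s12) / det
    u_a = (b2 * s11 - b1 * s12) / det
    return u_b, u_a, u - (u_b * one + u_a * phi)


def _refine(z, u, zl0, zu0):
    """Continuous knee refinement from the search-stage optimum.

    Parametrised as (z_lower, width >= 0); the residual is continuous and
    piecewise smooth in the knees, so a bounded trust-region least-squares
    from the best grid cell converges to the continuous optimum.
    """
    z0, z1 = z[0], z[-1]

    def resid(p):
        zl = p[0]
        zu = zl + p[1]
        return _plateaus_and_rss(z, u, zl, zu)[2]

    sol = least_squares(
        resid,
        x0=[zl0, zu0 - zl0],
        bounds=([z0, 0.0], [z1, z1 - z0]),
        method="trf",
        xtol=1e-12,
        ftol=1e-14,
        gtol=1e-14,
    )
    zl = float(sol.x[0])
    zu = zl + float(sol.x[1])
    return zl, zu


def fit_trilinear(
    z_mm: np.ndarray,
    u_mm: np.ndarray,
    settings: FitSettings | None = None,
    _basis: _CandidateBasis | None = None,
) -> TrilinearFit:
    """Least-squares tri-linear fit to one (z, u_x) profile.

    Returns ``ok=False`` (with a message) rather than raising when the
    profile is too short, constant within noise, or the fitted band is not
    resolvable (plateau separation below the noise floor, or a knee pinned
    to the profile boundary).
    """
    settings = settings or FitSettings()
    z = np.asarray(z_mm, dtype=float)
    u = np.asarray(u_mm, dtype=float)
    if z.ndim != 1 or z.shape != u.shape:
        raise ValueError("profile must be two matched 1-D arrays")
    if z.size < settings.min_points:
        return _failed(f"profile has {z.size} points; need >= {settings.min_points}")
    order = np.argsort(z)
    z, u = z[order], u[order]

    span = float(u.max() - u.min())
    if span < max(1e-12, 0.1 * settings.noise_sigma_mm):
        return _failed("constant profile: no shear band present")

    basis = _basis if _basis is not None else _CandidateBasis(z, settings.candidate_stride)
    u_b_all, u_a_all, rss_all = basis.solve(u)
    c = basis.best(rss_all)
    zl, zu = float(basis.zl[c]), float(basis.zu[c])

    if settings.refine:
        zl, zu = _refine(z, u, zl, zu)
    u_b, u_a, r = _plateaus_and_rss(z, u, zl, zu)
    rss = float(r @ r)

    sep = abs(u_a - u_b)
    if sep < settings.plateau_snr * settings.noise_sigma_mm:
        return TrilinearFit(zl, zu, u_b, u_a, rss, ok=False,
                            message="plateau separation below noise floor")
    edge = 1e-9
    if zl <= z[0] + edge or zu >= z[-1] - edge:
        return TrilinearFit(zl, zu, u_b, u_a, rss, ok=False,
                            message="knee pinned to profile boundary")
    return TrilinearFit(zl, zu, u_b, u_a, rss, ok=True)
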