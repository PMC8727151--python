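"""Shear-zone thickness maps: the tri-linear fit applied column-by-column
over the (x, y) footprint of a displacement field, plus step-to-step growth
maps and near-root summaries."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .field import DisplacementField
from .model import Root
from .trilinear import FitSettings, TrilinearFit, _CandidateBasis, fit_trilinear

logger = logging.getLogger(__name__)

__all__ = ["ShearZoneMap", "thickness_map", "growth_map", "summarize_map"]


@dataclass
class ShearZoneMap:
    """Per-(x, y) shear-zone thickness and knee depths from tri-linear fits.

    ``thickness_mm`` etc. are (nx, ny) arrays; ``ok`` flags columns whose
    fit resolved a band. Non-ok entries hold NaN.
    """

    x_mm: np.ndarray
    y_mm: np.ndarray
    thickness_mm: np.ndarray
    z_lower_mm: np.ndarray
    z_upper_mm: np.ndarray
    ok: np.ndarray
    step_index: int = 0

    def __post_init__(self) -> None:
        nx, ny = self.x_mm.size, self.y_mm.size
        for name in ("thickness_mm", "z_lower_mm", "z_upper_mm", "ok"):
            arr = getattr(self, name)
            if arr.shape != (nx, ny):
                raise ValueError(f"{name} must have shape (nx, ny) = {(nx, ny)}")

    @property
    def n_ok(self) -> int:
        return int(self.ok.sum())

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: one row per (x, y) column."""
        xg, yg = np.meshgrid(self.x_mm, self.y_mm, indexing="ij")
        return pd.DataFrame(
            {
                "x_mm": xg.ravel(),
                "y_mm": yg.ravel(),
                "thickness_mm": self.thickness_mm.ravel(),
                "z_lower_mm": self.z_lower_mm.ravel(),
                "z_upper_mm": self.z_upper_mm.ravel(),
                "ok": self.ok.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, step_index: int = 0) -> "ShearZoneMap":
        x = np.unique(df["x_mm"].to_numpy())
        y = np.unique(df["y_mm"].to_numpy())
        shape = (x.size, y.size)
        if len(df) != shape[0] * shape[1]:
            raise ValueError("frame does not tile a regular (x, y) grid")
        d = df.sort_values(["x_mm", "y_mm"])
        return cls(
            x_mm=x,
            y_mm=y,
            thickness_mm=d["thickness_mm"].to_numpy().reshape(shape),
            z_lower_mm=d["z_lower_mm"].to_numpy().reshape(shape),
            z_upper_mm=d["z_upper_mm"].to_numpy().reshape(shape),
            ok=d["ok"].to_numpy().astype(bool).reshape(shape),
            step_index=step_index,
        )


def _store(maps: ShearZoneMap, i: int, j: int, fit: TrilinearFit) -> None:
    maps.ok[i, j] = fit.ok
    if fit.ok:
        maps.thickness_mm[i, j] = fit.thickness_mm
        maps.z_lower_mm[i, j] = fit.z_lower_mm
        maps.z_upper_mm[i, j] = fit.z_upper_mm


def thickness_map(
    field: DisplacementField, settings: FitSettings | None = None
) -> ShearZoneMap:
    """Fit every (x, y) column of a field and assemble the thickness map.

    Columns sharing the full z-grid (no masked nodes) run through a batched
    search stage — the candidate normal equations depend only on the z-grid,
    so they are computed once; partially masked columns fall back to the
    per-column path. One bad column never aborts the map: it is flagged and
    the rest proceed. Deterministic for a given field and settings.
    """
    settings = settings or FitSettings()
    nx, ny, nz = field.shape
    nan = np.full((nx, ny), np.nan)
    out = ShearZoneMap(
        x_mm=field.x_mm.copy(),
        y_mm=field.y_mm.copy(),
        thickness_mm=nan.copy(),
        z_lower_mm=nan.copy(),
        z_upper_mm=nan.copy(),
        ok=np.zeros((nx, ny), dtype=bool),
        step_index=field.step_index,
    )
    z = field.z_mm
    full = field.mask.all(axis=2)
    basis = _CandidateBasis(z, settings.candidate_stride) if full.any() else None

    # batched search for fully valid columns, chunked to bound memory
    idx = np.argwhere(full)
    chunk = 256
    for start in range(0, len(idx), chunk):
        block = idx[start : start + chunk]
        U = np.stack(
            [field.u_mm[i, j, :, 0] for i, j in block], axis=1
        )  # (nz, ncol)
        _, _, rss = basis.solve(U)
        for c, (i, j) in enumerate(block):
            best = basis.best(rss[:, c])
            u = U[:, c]
            fit = _finish_column(z, u, basis, best, settings)
            _store(out, i, j, fit)

    for i, j in np.argwhere(~full):
        valid = field.mask[i, j, :]
        if valid.sum() < settings.min_points:
            continue
        fit = fit_trilinear(z[valid], field.u_mm[i, j, valid, 0], settings)
        _store(out, i, j, fit)

    n_bad = nx * ny - out.n_ok
    if n_bad:
        logger.info("thickness_map: %d of %d columns without a resolved band",
                    n_bad, nx * ny)
    return out


def _finish_column(z, u, basis, best, settings):
    """Refinement + quality flags for one batched column (mirrors
    fit_trilinear after its search stage)."""
    span = float(u.max() - u.min())
    if span < max(1e-12, 0.1 * settings.noise_sigma_mm):
        return TrilinearFit(np.nan, np.nan, np.nan, np.nan, np.nan, ok=False,
                            message="constant profile: no shear band present")
    from .trilinear import _plateaus_and_rss, _refine

    zl, zu = float(basis.zl[best]), float(basis.zu[best])
    if settings.refine:
        zl, zu = _refine(z, u, zl, zu)
    u_b, u_a, r = _plateaus_and_rss(z, u, zl, zu)
    rss = float(r @ r)
    if abs(u_a - u_b) < settings.plateau_snr * settings.noise_sigma_mm:
        return TrilinearFit(zl, zu, u_b, u_a, rss, ok=False,
                            message="plateau separation below noise floor")
    if zl <= z[0] + 1e-9 or zu >= z[-1] - 1e-9:
        return TrilinearFit(zl, zu, u_b, u_a, rss, ok=False,
                            message="knee pinned to profile boundary")
    return TrilinearFit(zl, zu, u_b, u_a, rss, ok=True)


def growth_map(map_a: ShearZoneMap, map_b: ShearZoneMap) -> ShearZoneMap:
    """Pointwise thickness change between two load steps, b minus a.

    Positive values mean the zone thickened between the steps. Columns
    without a resolved band in either map are NaN and flagged not-ok.
    Knee-depth fields carry the later map's values where both are ok.
    """
    if map_a.x_mm.shape != map_b.x_mm.shape or map_a.y_mm.shape != map_b.y_mm.shape:
        raise ValueError("maps are on different grids")
    if not (np.allclose(map_a.x_mm, map_b.x_mm) and np.allclose(map_a.y_mm, map_b.y_mm)):
        raise ValueError("maps are on different grids")
    ok = map_a.ok & map_b.ok
    diff = np.where(ok, map_b.thickness_mm - map_a.thickness_mm, np.nan)
    return ShearZoneMap(
        x_mm=map_a.x_mm.copy(),
        y_mm=map_a.y_mm.copy(),
        thickness_mm=diff,
        z_lower_mm=np.where(ok, map_b.z_lower_mm, np.nan),
        z_upper_mm=np.where(ok, map_b.z_upper_mm, np.nan),
        ok=ok,
        step_index=map_b.step_index,
    )


def summarize_map(
    zmap: ShearZoneMap, roots: list[Root] | None = None, radius_mm: float = 5.0
) -> pd.DataFrame:
    """At-root vs away-from-root thickness summary.

    One row per root with the mean thickness within ``radius_mm`` of it,
    plus a ``far_field`` row (mean beyond twice the radius from every root)
    and a ``global`` row (max/min/median over all resolved columns). With
    ``radius_mm = 0`` the at-root value is the nearest resolved node. Roots
    outside the map footprint are skipped with a warning.
    """
    if radius_mm < 0:
        raise ValueError("radius must be >= 0")
    roots = roots or []
    xg, yg = np.meshgrid(zmap.x_mm, zmap.y_mm, indexing="ij")
    ok = zmap.ok
    thick = zmap.thickness_mm
    rows = []
    near_any = np.zeros_like(ok)
    for root in roots:
        in_x = zmap.x_mm.min() - 1e-9 <= root.x_mm <= zmap.x_mm.max() + 1e-9
        in_y = zmap.y_mm.min() - 1e-9 <= root.y_mm <= zmap.y_mm.max() + 1e-9
        if not (in_x and in_y):
            warnings.warn(f"root {root.label!r} lies outside the map footprint; skipped")
            continue
        dist = np.hypot(xg - root.x_mm, yg - root.y_mm)
        near_any |= dist <= 2.0 * radius_mm
        if radius_mm == 0.0:
            masked = np.where(ok, dist, np.inf)
            i, j = np.unravel_index(np.argmin(masked), dist.shape)
            val = thick[i, j] if ok[i, j] else np.nan
            n = int(ok[i, j])
        else:
            sel = (dist <= radius_mm) & ok
            n = int(sel.sum())
            val = float(thick[sel].mean()) if n else np.nan
        rows.append(
            {"region": "root", "label": root.label, "mean_thickness_mm": val,
             "n_nodes": n}
        )
    far = ok & ~near_any
    rows.append(
        {
            "region": "far_field",
            "label": "",
            "mean_thickness_mm": float(thick[far].mean()) if far.any() else np.nan,
            "n_nodes": int(far.sum()),
        }
    )
    vals = thick[ok]
    rows.append(
        {
            "region": "global",
            "label": "",
            "mean_thickness_mm": float(vals.mean()) if vals.size else np.nan,
            "n_nodes": int(vals.size),
            "max_thickness_mm": float(vals.max()) if vals.size else np.nan,
            "min_thickness_mm": float(vals.min()) if vals.size else np.nan,
            "median_thickness_mm": float(np.median(vals)) if vals.size else np.nan,
        }
    )
    return pd.DataFrame(rows)
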