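"""Root-path length measurement and the comparison between the idealised
tri-linear extension Z (sec beta - 1) and extensions measured directly from
imaged root centrelines.

Real roots do not kink at the edges of the shear zone: they bend with a
finite radius, locally compressing the soil, so their deformed path between
two fixed anchor points is shorter than the tri-linear idealisation. The
idealised extension is therefore an upper bound on the measured one, and
imaged roots typically come in 10-30% below it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import compute_beta, root_extension

__all__ = ["RootPath", "path_length", "measured_delta_l", "compare_extension"]


@dataclass(frozen=True)
class RootPath:
    """Ordered 3-D centreline of one root between two anchor features
    (branching points above and below the shear zone), mm."""

    points_mm: np.ndarray
    label: str = ""
    step_index: int = 0

    def __post_init__(self) -> None:
        pts = np.asarray(self.points_mm, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise ValueError("path needs an (n >= 2, 3) point array")
        if not np.all(np.isfinite(pts)):
            raise ValueError("path points must be finite")
        object.__setattr__(self, "points_mm", pts)


def path_length(path: RootPath) -> float:
    """Arc length of the polyline, mm — never less than the straight
    anchor-to-anchor distance."""
    seg = np.diff(path.points_mm, axis=0)
    return float(np.linalg.norm(seg, axis=1).sum())


def measured_delta_l(path_0: RootPath, path_t: RootPath) -> float:
    """Change in measured root length between two states of the same root.

    A negative value (possible under measurement noise) is returned as-is;
    clipping it would bias any model-vs-measurement comparison. Paths with
    different labels are rejected — the lengths must belong to one root.
    """
    if path_0.label != path_t.label:
        raise ValueError(
            f"anchor mismatch: paths belong to {path_0.label!r} and {path_t.label!r}"
        )
    return path_length(path_t) - path_length(path_0)


def compare_extension(
    pairs: list[tuple[RootPath, RootPath]],
    z_mm: float | dict[str, float],
    u_x_mm: float,
) -> pd.DataFrame:
    """Per-root comparison of idealised vs measured extension.

    For each (undeformed, deformed) path pair, evaluates the tri-linear
    extension Z (sec beta - 1) at beta = arctan(u_x / Z) — with Z either a
    single thickness or a per-root-label map — against the measured length
    change. The ratio idealised/measured exceeds 1 for bent roots; it is
    NaN (flagged) when the measured change is not positive or u_x is zero.
    """
    if u_x_mm < 0:
        raise ValueError("displacement must be >= 0")
    rows = []
    for p0, pt in pairs:
        z = z_mm[p0.label] if isinstance(z_mm, dict) else z_mm
        dl_meas = measured_delta_l(p0, pt)
        if u_x_mm == 0.0:
            dl_model, ratio, flagged = 0.0, np.nan, True
        else:
            beta = compute_beta(u_x_mm, z)
            dl_model = root_extension(z, beta)
            flagged = dl_meas <= 0
            ratio = dl_model / dl_meas if not flagged else np.nan
        rows.append(
            {
                "label": p0.label,
                "Z_mm": z,
                "delta_l_model_mm": dl_model,
                "delta_l_measured_mm": dl_meas,
                "ratio": ratio,
                "flagged": flagged,
            }
        )
    return pd.DataFrame(rows)
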