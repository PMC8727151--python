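"""Regular-grid 3-D displacement fields, the post-correlation product of
volumetric image correlation, plus lossless HDF5 round-tripping.

Conventions, enforced at load time: right-handed axes with the origin on the
tube axis at the nominal shear plane (the tube-gap mid-height), x the shear
direction, z vertical and increasing upward; displacements in mm on a grid
of uniform pitch.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["DisplacementField", "read_field", "write_field"]


@dataclass
class DisplacementField:
    """Displacement vectors on a regular (nx, ny, nz) grid at one load step.

    ``u_mm[i, j, k]`` is the 3-vector displacement at node
    ``origin + pitch * (i, j, k)``; ``mask`` flags nodes with a valid
    correlation.
    """

    u_mm: np.ndarray
    pitch_mm: float
    origin_mm: np.ndarray
    step_index: int
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.u_mm = np.asarray(self.u_mm, dtype=float)
        if self.u_mm.ndim != 4 or self.u_mm.shape[-1] != 3:
            raise ValueError("u_mm must have shape (nx, ny, nz, 3)")
        if self.pitch_mm <= 0:
            raise ValueError("grid pitch must be > 0")
        self.origin_mm = np.asarray(self.origin_mm, dtype=float).reshape(3)
        if self.mask is None:
            self.mask = np.ones(self.u_mm.shape[:3], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.u_mm.shape[:3]:
                raise ValueError("mask shape must match the grid")
        if not np.all(np.isfinite(self.u_mm[self.mask])):
            raise ValueError("masked-valid displacements must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.u_mm.shape[:3]

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of the grid nodes along one axis."""
        n = self.shape[axis]
        return self.origin_mm[axis] + self.pitch_mm * np.arange(n)

    @property
    def x_mm(self) -> np.ndarray:
        return self.axis_coords(0)

    @property
    def y_mm(self) -> np.ndarray:
        return self.axis_coords(1)

    @property
    def z_mm(self) -> np.ndarray:
        return self.axis_coords(2)

    def nearest_column(self, x_mm: float, y_mm: float, tol: float = 1e-6):
        """Grid indices (i, j) of the column at (x, y); raises if the point
        is farther than ``tol`` off the node lattice (pass ``tol=pitch/2``
        to snap to the nearest column instead)."""
        i = int(round((x_mm - self.origin_mm[0]) / self.pitch_mm))
        j = int(round((y_mm - self.origin_mm[1]) / self.pitch_mm))
        nx, ny, _ = self.shape
        if not (0 <= i < nx and 0 <= j < ny):
            raise ValueError(f"({x_mm}, {y_mm}) mm lies outside the grid")
        dx = abs(self.x_mm[i] - x_mm)
        dy = abs(self.y_mm[j] - y_mm)
        if dx > tol or dy > tol:
            raise ValueError(
                f"({x_mm}, {y_mm}) mm is {max(dx, dy):.3g} mm off the grid"
            )
        return i, j


def write_field(path, field: DisplacementField) -> None:
    """Write a field to HDF5: datasets ``/u`` and ``/mask``, grid metadata
    as root attributes."""
    with h5py.File(path, "w") as f:
        f.create_dataset("u", data=field.u_mm)
        f.create_dataset("mask", data=field.mask)
        f.attrs["pitch_mm"] = field.pitch_mm
        f.attrs["origin_mm"] = field.origin_mm
        f.attrs["step_index"] = field.step_index


def read_field(path) -> DisplacementField:
    """Read a field written by :func:`write_field`.

    Missing pitch/origin metadata is an error (no silent defaults); a
    missing mask is tolerated as all-valid, with a warning.
    """
    with h5py.File(path, "r") as f:
        if "u" not in f:
            raise ValueError(f"{path}: missing displacement dataset '/u'")
        u = f["u"][...]
        if u.ndim != 4 or u.shape[-1] != 3:
            raise ValueError(f"{path}: '/u' must have shape (nx, ny, nz, 3)")
        for attr in ("pitch_mm", "origin_mm"):
            if attr not in f.attrs:
                raise ValueError(f"{path}: missing required attribute {attr!r}")
        if "mask" in f:
            mask = f["mask"][...].astype(bool)
        else:
            warnings.warn(f"{path}: no '/mask' dataset; assuming all nodes valid")
            mask = None
        return DisplacementField(
            u_mm=u,
            pitch_mm=float(f.attrs["pitch_mm"]),
            origin_mm=np.asarray(f.attrs["origin_mm"], dtype=float),
            step_index=int(f.attrs.get("step_index", 0)),
            mask=mask,
        )
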