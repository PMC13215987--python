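"""Physical quantification: areas in cm², distribution indices, volumes.

Pixel area comes from the acquisition geometry: (FOV_row / rows) x
(FOV_col / cols), converted from mm² to cm².  The geometry must refer to
the grid the masks actually live on (the export grid when images were
interpolated on export) so that total area is conserved.

Adipose distribution is summarized by VAT/TAT (%) and the VAT/SAT ratio.
Multi-slice volumes aggregate per-slice areas as V = (t + h) * sum(A_i)
with slice thickness t and between-slice gap h (both cm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class PixelGeometry:
    fov_row_mm: float
    fov_col_mm: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.fov_row_mm <= 0 or self.fov_col_mm <= 0:
            raise ValueError("FOV must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be >= 1")

    @property
    def pixel_area_cm2(self) -> float:
        # mm^2 -> cm^2
        return (self.fov_row_mm / self.n_rows) * (self.fov_col_mm / self.n_cols) / 100.0


@dataclass(frozen=True)
class SurfaceReport:
    sat_cm2: float
    vat_cm2: float

    @property
    def tat_cm2(self) -> float:
        return self.sat_cm2 + self.vat_cm2

    @property
    def vat_tat_pct(self) -> float:
        """VAT as a percentage of TAT; NaN when TAT is zero."""
        if self.tat_cm2 == 0:
            return math.nan
        return 100.0 * self.vat_cm2 / self.tat_cm2

    @property
    def vat_sat_ratio(self) -> float:
        """VAT/SAT ratio; NaN when SAT is zero and VAT is not."""
        if self.sat_cm2 == 0:
            return 0.0 if self.vat_cm2 == 0 else math.nan
        return self.vat_cm2 / self.sat_cm2


def surface(mask: np.ndarray, geom: PixelGeometry) -> float:
    """Mask area in cm²: foreground pixel count x pixel area."""
    mask = np.asarray(mask)
    if mask.shape != (geom.n_rows, geom.n_cols):
        raise ValueError(
            f"mask shape {mask.shape} does not match geometry grid "
            f"({geom.n_rows}, {geom.n_cols})"
        )
    return float(np.count_nonzero(mask)) * geom.pixel_area_cm2


def distribution_indices(sat_cm2: float, vat_cm2: float) -> SurfaceReport:
    """Summarize adipose distribution from compartment areas."""
    if sat_cm2 < 0 or vat_cm2 < 0:
        raise ValueError("areas must be non-negative")
    return SurfaceReport(sat_cm2=sat_cm2, vat_cm2=vat_cm2)


@dataclass(frozen=True)
class VolumeSpec:
    slice_thickness_t_cm: float
    between_slice_gap_h_cm: float
    areas_cm2: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.slice_thickness_t_cm <= 0:
            raise ValueError("slice thickness must be > 0")
        if self.between_slice_gap_h_cm < 0:
            raise ValueError("between-slice gap must be >= 0")
        if len(self.areas_cm2) < 1:
            raise ValueError("at least one slice area is required")


def volume(spec: VolumeSpec) -> float:
    """Multi-slice volume in cm³: (t + h) * sum of slice areas.

    Each slice area represents a slab of extent t + h along the scan axis
    (contiguous slabs when h = 0).
    """
    return (spec.slice_thickness_t_cm + spec.between_slice_gap_h_cm) * float(
        np.sum(spec.areas_cm2)
    )
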