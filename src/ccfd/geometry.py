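"""Scan geometry and raster containers for en-face OCTA slabs.

All rasters are row-major 2-D arrays, origin at the top-left corner,
0-based indices.  Physical scale comes from a :class:`ScanGeometry`
attached to every image and mask, so pixel-count metrics convert to
micrometres/millimetres without global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

Channel = Literal["flow", "structure", "compensated"]

#: Valid bit depths for en-face rasters.
BIT_DEPTHS = (8, 16)


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


@dataclass(frozen=True)
class ScanGeometry:
    """Physical extent and pixel grid of an en-face scan.

    Parameters
    ----------
    field_width_mm, field_height_mm
        Physical size of the scanned field in millimetres.
    grid_cols, grid_rows
        Number of pixel columns / rows of the exported raster.
    """

    field_width_mm: float
    field_height_mm: float
    grid_cols: int
    grid_rows: int

    def __post_init__(self) -> None:
        if self.field_width_mm <= 0 or self.field_height_mm <= 0:
            raise ValidationError("field dimensions must be positive")
        if self.grid_cols < 2 or self.grid_rows < 2:
            raise ValidationError("grid must be at least 2x2 pixels")

    @property
    def pixel_width_um(self) -> float:
        return 1000.0 * self.field_width_mm / self.grid_cols

    @property
    def pixel_height_um(self) -> float:
        return 1000.0 * self.field_height_mm / self.grid_rows

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_width_um * self.pixel_height_um

    @property
    def field_area_mm2(self) -> float:
        return self.field_width_mm * self.field_height_mm

    @property
    def shape(self) -> tuple[int, int]:
        return (self.grid_rows, self.grid_cols)


#: 6 x 6 mm macular field on a 500 x 500 grid (12 um pixel pitch), the
#: device-class default; geometry is always an explicit parameter.
DEFAULT_GEOMETRY = ScanGeometry(6.0, 6.0, 500, 500)


def _dtype_for(bit_depth: int):
    if bit_depth == 8:
        return np.uint8
    if bit_depth == 16:
        return np.uint16
    raise ValidationError(f"bit depth must be one of {BIT_DEPTHS}, got {bit_depth}")


@dataclass(frozen=True)
class EnFaceImage:
    """Single-channel en-face slab raster with physical geometry.

    ``pixels`` holds nonnegative integer intensities within
    ``[0, 2**bit_depth - 1]``; ``channel`` tags the slab's provenance in
    the processing chain.
    """

    pixels: np.ndarray
    bit_depth: int
    geometry: ScanGeometry
    channel: Channel

    def __post_init__(self) -> None:
        dtype = _dtype_for(self.bit_depth)
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValidationError(f"expected a 2-D raster, got ndim={px.ndim}")
        if px.shape != self.geometry.shape:
            raise ValidationError(
                f"pixel grid {px.shape} does not match geometry "
                f"{self.geometry.shape}"
            )
        if px.dtype != dtype:
            if np.issubdtype(px.dtype, np.floating):
                raise ValidationError("intensities must be integral")
            info = np.iinfo(dtype)
            if px.min() < info.min or px.max() > info.max:
                raise ValidationError(
                    f"intensities outside [0, {info.max}] for {self.bit_depth}-bit"
                )
            px = px.astype(dtype)
        object.__setattr__(self, "pixels", px)

    @property
    def max_value(self) -> int:
        """Full-scale intensity, ``2**bit_depth - 1``."""
        return (1 << self.bit_depth) - 1

    def normalized(self) -> np.ndarray:
        """Intensities mapped to ``[0, 1]`` as float64."""
        return self.pixels.astype(np.float64) / self.max_value

    def with_pixels(self, pixels: np.ndarray, channel: Channel | None = None) -> "EnFaceImage":
        return EnFaceImage(pixels, self.bit_depth, self.geometry,
                           channel if channel is not None else self.channel)


@dataclass(frozen=True)
class BinaryMask:
    """Per-pixel flow/deficit classification aligned to an EnFaceImage.

    ``pixels`` is boolean with ``True`` marking a flow deficit;
    ``radius_px`` records the thresholding window radius that produced
    the mask (0 for masks not produced by thresholding, e.g. ground truth).
    """

    pixels: np.ndarray
    geometry: ScanGeometry
    radius_px: int = 0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValidationError(f"expected a 2-D mask, got ndim={px.ndim}")
        if px.shape != self.geometry.shape:
            raise ValidationError(
                f"mask grid {px.shape} does not match geometry {self.geometry.shape}"
            )
        if px.dtype != np.bool_:
            vals = np.unique(px)
            if not np.isin(vals, (0, 1)).all():
                raise ValidationError("mask pixels must be binary")
            px = px.astype(bool)
        object.__setattr__(self, "pixels", px)

    @property
    def deficit_fraction(self) -> float:
        return float(self.pixels.mean())

    @property
    def deficit_pixel_count(self) -> int:
        return int(self.pixels.sum())
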