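"""Phansalkar local adaptive thresholding.

For each pixel, the threshold is computed from the mean ``mu`` and the
population standard deviation ``sd`` of the normalized intensities in a
window of radius ``radius_px`` centred on it:

    t = mu * (1 + p * exp(-q * mu) + k * (sd / r - 1))

A pixel is labelled *deficit* when its normalized intensity is strictly
below ``t``.  The exponential term lifts the threshold in dark regions,
which makes the method suitable for low-contrast angiograms; ``k``
scales the local-contrast correction and ``r`` normalizes the dynamic
range of the standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage as ndi

from .geometry import BinaryMask, EnFaceImage, ValidationError

WindowShape = Literal["circular", "square"]


@dataclass(frozen=True)
class ThresholdParams:
    """Window radius, shape, and the four Phansalkar constants.

    Defaults (k=0.25, r=0.5, p=2, q=10) are the published constants for
    intensities normalized to [0, 1], as used by the Fiji Auto Local
    Threshold plugin.  ``circular`` windows contain the pixels whose
    centre distance is <= radius; ``square`` windows are the full
    (2*radius+1)^2 neighbourhood.
    """

    radius_px: int
    k: float = 0.25
    r: float = 0.5
    p: float = 2.0
    q: float = 10.0
    window_shape: WindowShape = "circular"

    def __post_init__(self) -> None:
        if not (isinstance(self.radius_px, (int, np.integer)) and self.radius_px >= 1):
            raise ValidationError("radius_px must be an integer >= 1")
        if self.r <= 0:
            raise ValidationError("r must be > 0")
        if self.p < 0 or self.q < 0:
            raise ValidationError("p and q must be >= 0")
        if self.window_shape not in ("circular", "square"):
            raise ValidationError(f"unknown window shape {self.window_shape!r}")


def window_footprint(radius_px: int, shape: WindowShape = "circular") -> np.ndarray:
    """Boolean window mask of side ``2*radius+1``."""
    size = 2 * radius_px + 1
    if shape == "square":
        return np.ones((size, size), dtype=bool)
    yy, xx = np.mgrid[-radius_px : radius_px + 1, -radius_px : radius_px + 1]
    return (yy * yy + xx * xx) <= radius_px * radius_px


def local_mean_std(
    norm: np.ndarray, radius_px: int, shape: WindowShape = "circular"
) -> tuple[np.ndarray, np.ndarray]:
    """Windowed mean and population SD with edge-replicated borders."""
    fp = window_footprint(radius_px, shape).astype(np.float64)
    kernel = fp / fp.sum()
    mu = ndi.correlate(norm, kernel, mode="nearest")
    ex2 = ndi.correlate(norm * norm, kernel, mode="nearest")
    var = np.maximum(ex2 - mu * mu, 0.0)
    return mu, np.sqrt(var)


def phansalkar_threshold(image: EnFaceImage, params: ThresholdParams) -> BinaryMask:
    """Binarize an en-face slab; deficit where intensity < local threshold.

    Intensities are normalized to [0, 1] by the bit-depth full scale.
    Ties go to *flow* (strict inequality), so an all-zero image contains
    no deficit.
    """
    if params.radius_px > min(image.geometry.shape) // 2:
        raise ValidationError(
            f"radius {params.radius_px} exceeds half the smaller image dimension"
        )
    norm = image.normalized()
    mu, sd = local_mean_std(norm, params.radius_px, params.window_shape)
    t = mu * (1.0 + params.p * np.exp(-params.q * mu) + params.k * (sd / params.r - 1.0))
    return BinaryMask(norm < t, image.geometry, radius_px=params.radius_px)
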