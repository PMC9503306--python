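"""Shadow-artifact compensation of en-face flow slabs.

Overlying tissue (chiefly the RPE) attenuates both the OCT structure
signal and the OCTA decorrelation signal beneath it.  The standard
correction multiplies the flow slab by the inverted, Gaussian-smoothed
structure slab: dark (attenuated) structure regions become bright in the
inverse and boost the co-attenuated flow signal.  Processing order is
fixed: invert -> blur -> multiply.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage as ndi

from .geometry import EnFaceImage, ValidationError

RescaleMode = Literal["linear_to_full_range", "none"]


@dataclass(frozen=True)
class CompensationParams:
    """Tunables of the compensation chain.

    gaussian_sigma_px
        Standard deviation of the smoothing kernel applied to the
        inverted structure image, in pixels.  Default 2.0.
    output_rescale
        ``linear_to_full_range`` (default) affinely maps the floating
        product onto the full bit-depth range before quantization;
        ``none`` quantizes the raw product (clipped), for strict
        emulation of integer image-calculator arithmetic.
    """

    gaussian_sigma_px: float = 2.0
    output_rescale: RescaleMode = "linear_to_full_range"

    def __post_init__(self) -> None:
        if self.gaussian_sigma_px < 0:
            raise ValidationError("gaussian_sigma_px must be >= 0")
        if self.output_rescale not in ("linear_to_full_range", "none"):
            raise ValidationError(f"unknown rescale mode {self.output_rescale!r}")


def _quantize(values: np.ndarray, max_value: int) -> np.ndarray:
    """Round half up and clip to the integer intensity range."""
    q = np.floor(values + 0.5)
    return np.clip(q, 0, max_value)


def invert(image: EnFaceImage) -> EnFaceImage:
    """Map every pixel v to ``(2**bit_depth - 1) - v``."""
    return image.with_pixels(image.max_value - image.pixels)


def gaussian_smooth(image: EnFaceImage, sigma_px: float) -> EnFaceImage:
    """Convolve with a normalized 2-D Gaussian; borders edge-replicated.

    sigma 0 returns the input unchanged.  The floating result is
    quantized back to the source bit depth by round-half-up.
    """
    if sigma_px < 0:
        raise ValidationError("sigma_px must be >= 0")
    if sigma_px == 0:
        return image
    blurred = ndi.gaussian_filter(
        image.pixels.astype(np.float64), sigma=sigma_px, mode="nearest"
    )
    return image.with_pixels(_quantize(blurred, image.max_value).astype(image.pixels.dtype))


def attenuation_weight(structure: EnFaceImage, params: CompensationParams) -> np.ndarray:
    """Inverted, smoothed structure slab as a float multiplier.

    Returned on the source intensity scale (0 .. full range); bright
    values mark shadowed regions whose flow signal must be boosted.
    """
    return gaussian_smooth(invert(structure), params.gaussian_sigma_px).pixels.astype(
        np.float64
    )


def compensate(
    flow: EnFaceImage,
    structure: EnFaceImage,
    params: CompensationParams = CompensationParams(),
) -> EnFaceImage:
    """Pixelwise product of the flow slab and the processed structure slab.

    The product is computed in floating precision; under the default
    rescale mode its min..max is mapped affinely onto the full intensity
    range, making the result invariant to any positive scaling of the
    attenuation weight.  A constant product maps to all zeros.
    """
    if flow.geometry != structure.geometry:
        raise ValidationError("flow and structure geometry differ")
    if flow.bit_depth != structure.bit_depth:
        raise ValidationError("flow and structure bit depth differ")
    weight = attenuation_weight(structure, params)
    return combine_with_weight(flow, weight, params)


def combine_with_weight(
    flow: EnFaceImage, weight: np.ndarray, params: CompensationParams
) -> EnFaceImage:
    """Multiply ``flow`` by a precomputed attenuation weight and quantize."""
    if weight.shape != flow.pixels.shape:
        raise ValidationError("weight grid does not match flow image")
    product = flow.pixels.astype(np.float64) * np.asarray(weight, dtype=np.float64)
    max_value = flow.max_value
    if params.output_rescale == "linear_to_full_range":
        lo, hi = float(product.min()), float(product.max())
        if hi > lo:
            product = (product - lo) * (max_value / (hi - lo))
        else:
            product = np.zeros_like(product)
    else:
        # raw integer-calculator emulation: product of two full-scale
        # images overflows the range, so clip after scaling by full range
        product = product / max_value
    out = _quantize(product, max_value).astype(flow.pixels.dtype)
    return flow.with_pixels(out, channel="compensated")
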