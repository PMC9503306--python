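"""Synthetic en-face flow/structure pairs with known ground truth.

The generator emulates the statistical structure the analysis chain
assumes, not OCTA physics.  A pair consists of:

* a *flow* image: a bright capillary plateau with (a) mild correlated
  texture, (b) sparse darker "pits" drawn from the negative tail of the
  texture field (the false-positive floor any local threshold sees on
  real angiograms), and (c) stamped elliptical deficit blobs whose
  union is the ground-truth mask;
* a *structure* image: near-uniform reflectance at 2/3 of full scale;
* optional horizontal *shadow bands* that multiply BOTH images by an
  attenuation factor — the RPE-shadowing artefact that compensation
  must undo.  At the 2/3 structure level, an attenuation of 0.5 is
  undone exactly (to first order) by invert-and-multiply compensation,
  which makes the compensation benefit analytically expectable rather
  than an accident of tuning;
* additive Gaussian pixel noise.

All randomness flows from ``spec.seed`` through one Generator instance.
The returned truth mask is the pre-shadow, pre-noise blob union.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy import ndimage as ndi

from .binarization import ThresholdParams, phansalkar_threshold
from .compensation import CompensationParams, compensate
from .geometry import BinaryMask, EnFaceImage, ScanGeometry, ValidationError
from .quant import FDReport, quantify

# intensity model, on the [0, 1] normalized scale
FLOW_PLATEAU = 0.70        # bright capillary background level
PLATEAU_TEXTURE_AMP = 0.02 # SD of the correlated plateau ripple
PIT_ONSET_SD = 1.5         # texture z-score below which pits begin
PIT_GAIN = 0.35            # pit depth per z-score unit past onset
PIT_FLOOR = 0.25           # darkest pit level (blobs are darker still)
DEFICIT_LEVEL = 0.10       # flow level inside a true deficit blob
STRUCTURE_LEVEL = 2.0 / 3.0  # chosen so attenuation 0.5 compensates exactly
STRUCTURE_TEXTURE_AMP = 0.02
STRUCTURE_TEXTURE_SCALE_PX = 6.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth parameters for one generated flow/structure pair.

    ``shadow_bands`` is a sequence of ``(row_start, row_end,
    attenuation)`` with attenuation in (0, 1]; ``blob_size_mean_px`` and
    ``blob_size_sd_px`` parameterize the lognormal blob-area
    distribution (pixels).  ``noise_sd`` is the additive Gaussian noise
    SD on the [0, 1] intensity scale.
    """

    geometry: ScanGeometry
    target_fd_fraction: float = 0.30
    n_blobs: int = 4000
    blob_size_mean_px: float = 40.0
    blob_size_sd_px: float = 60.0
    capillary_texture_scale_px: float = 3.0
    shadow_bands: tuple[tuple[int, int, float], ...] = ()
    noise_sd: float = 0.01
    seed: int = 0
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_fd_fraction <= 1.0:
            raise ValidationError("target_fd_fraction must lie in [0, 1]")
        if self.n_blobs < 0 or self.blob_size_mean_px <= 0 or self.blob_size_sd_px < 0:
            raise ValidationError("blob parameters out of range")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        for r0, r1, att in self.shadow_bands:
            if not (0 <= r0 < r1 <= self.geometry.grid_rows):
                raise ValidationError(f"shadow band rows ({r0}, {r1}) out of range")
            if not 0.0 < att <= 1.0:
                raise ValidationError("attenuation factors must lie in (0, 1]")
        object.__setattr__(self, "shadow_bands", tuple(
            (int(r0), int(r1), float(att)) for r0, r1, att in self.shadow_bands
        ))


@dataclass(frozen=True)
class SyntheticPair:
    """Generated triplet plus generation metadata (warnings)."""

    flow: EnFaceImage
    structure: EnFaceImage
    truth: BinaryMask
    warnings: tuple[str, ...] = ()

    def __iter__(self) -> Iterator:
        return iter((self.flow, self.structure, self.truth))


def _correlated_field(rng: np.random.Generator, shape: tuple[int, int],
                      scale_px: float) -> np.ndarray:
    """Zero-mean unit-SD Gaussian field with correlation length scale_px."""
    f = ndi.gaussian_filter(rng.standard_normal(shape), sigma=scale_px, mode="wrap")
    sd = f.std()
    return (f - f.mean()) / sd if sd > 0 else np.zeros(shape)


def _stamp_blobs(rng: np.random.Generator, spec: SyntheticSpec) -> tuple[np.ndarray, list[str]]:
    rows, cols = spec.geometry.shape
    truth = np.zeros((rows, cols), dtype=bool)
    warnings: list[str] = []
    target = spec.target_fd_fraction
    if target <= 0 or spec.n_blobs == 0:
        if target > 0.01:
            warnings.append(
                f"target fraction {target} unreachable with n_blobs={spec.n_blobs}"
            )
        return truth, warnings
    # lognormal parameterized by area mean/SD in pixels
    s2 = math.log1p((spec.blob_size_sd_px / spec.blob_size_mean_px) ** 2)
    mu = math.log(spec.blob_size_mean_px) - s2 / 2.0
    total_px = rows * cols
    for _ in range(spec.n_blobs):
        if truth.sum() / total_px >= target - 0.01:
            break
        area = rng.lognormal(mu, math.sqrt(s2))
        aspect = rng.uniform(1.0, 3.0)
        theta = rng.uniform(0.0, math.pi)
        a = math.sqrt(area * aspect / math.pi)   # semi-axes in px
        b = math.sqrt(area / (aspect * math.pi))
        cy, cx = rng.uniform(0, rows), rng.uniform(0, cols)
        ext = int(math.ceil(max(a, b))) + 1
        y0, y1 = max(0, int(cy) - ext), min(rows, int(cy) + ext + 1)
        x0, x1 = max(0, int(cx) - ext), min(cols, int(cx) + ext + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dy, dx = yy - cy, xx - cx
        ct, st = math.cos(theta), math.sin(theta)
        u = dx * ct + dy * st
        v = -dx * st + dy * ct
        truth[y0:y1, x0:x1] |= (u / a) ** 2 + (v / b) ** 2 <= 1.0
    frac = truth.sum() / total_px
    if frac < target - 0.01:
        warnings.append(
            f"reached deficit fraction {frac:.4f} < target {target} "
            f"after {spec.n_blobs} blobs"
        )
    return truth, warnings


def generate_pair(spec: SyntheticSpec) -> SyntheticPair:
    """Generate a co-registered (flow, structure, truth) triplet.

    Identical specs (including seed) yield bit-identical triplets.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.geometry.shape
    max_value = (1 << spec.bit_depth) - 1

    tex = _correlated_field(rng, (rows, cols), spec.capillary_texture_scale_px)
    background = (
        FLOW_PLATEAU
        + PLATEAU_TEXTURE_AMP * tex
        - PIT_GAIN * np.maximum(0.0, -tex - PIT_ONSET_SD)
    )
    background = np.clip(background, PIT_FLOOR, 1.0)

    truth_px, warnings = _stamp_blobs(rng, spec)
    flow = np.where(truth_px, DEFICIT_LEVEL + PLATEAU_TEXTURE_AMP * tex, background)

    struct_tex = _correlated_field(rng, (rows, cols), STRUCTURE_TEXTURE_SCALE_PX)
    structure = STRUCTURE_LEVEL + STRUCTURE_TEXTURE_AMP * struct_tex

    for r0, r1, att in spec.shadow_bands:
        flow[r0:r1, :] *= att
        structure[r0:r1, :] *= att

    if spec.noise_sd > 0:
        flow = flow + rng.normal(0.0, spec.noise_sd, flow.shape)
        structure = structure + rng.normal(0.0, spec.noise_sd, structure.shape)

    def _raster(values: np.ndarray) -> np.ndarray:
        q = np.floor(np.clip(values, 0.0, 1.0) * max_value + 0.5)
        return np.clip(q, 0, max_value).astype(np.uint8 if spec.bit_depth == 8 else np.uint16)

    return SyntheticPair(
        flow=EnFaceImage(_raster(flow), spec.bit_depth, spec.geometry, "flow"),
        structure=EnFaceImage(_raster(structure), spec.bit_depth, spec.geometry, "structure"),
        truth=BinaryMask(truth_px, spec.geometry, radius_px=0),
        warnings=tuple(warnings),
    )


def recovery_experiment(
    spec: SyntheticSpec,
    threshold: ThresholdParams = ThresholdParams(radius_px=8),
    compensation_params: CompensationParams = CompensationParams(),
    apply_compensation: bool = True,
    connectivity: int = 8,
    min_size_px: int = 0,
) -> tuple[FDReport, float]:
    """Run a generated pair through the full chain; return (measured, truth %).

    With ``apply_compensation=False`` the raw flow image is thresholded
    directly, which quantifies what the compensation stage buys on
    shadowed scans.
    """
    pair = generate_pair(spec)
    image = (
        compensate(pair.flow, pair.structure, compensation_params)
        if apply_compensation
        else pair.flow
    )
    mask = phansalkar_threshold(image, threshold)
    report = quantify(mask, connectivity=connectivity, min_size_px=min_size_px)
    return report, 100.0 * pair.truth.deficit_fraction
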