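# Methods

## Problem and pipeline

The package quantifies choriocapillaris (CC) hypoperfusion from en-face
swept-source OCTA slabs. The inputs are co-registered single-channel
*flow* (decorrelation) and *structure* (reflectance) rasters covering a
6 × 6 mm macular field; the outputs are four per-eye biomarkers of
*flow deficits* (FD) — regions whose flow signal falls below a locally
adaptive threshold — plus cohort-level statistics over them.

The per-eye chain is:

1. **Shadow compensation.** The structure slab is inverted
   (`v ↦ 2^bit_depth − 1 − v`), smoothed with a Gaussian kernel
   (σ = 2 px by default, edge-replicated borders), and multiplied
   pixelwise into the flow slab. Tissue that attenuates the OCT beam
   (chiefly the RPE) darkens both slabs; the inverted structure image
   is bright exactly where the flow signal was suppressed, so the
   product restores shadowed flow signal to first order. The floating
   product is affinely rescaled to the full intensity range before
   quantization (`output_rescale="linear_to_full_range"`).
2. **Phansalkar binarization.** For each pixel, with window mean µ and
   population SD σ over a circular window of radius R (default runs use
   R = 4 and R = 8 px), the threshold is
   `t = µ·(1 + p·e^(−q·µ) + k·(σ/r − 1))` on [0, 1]-normalized
   intensities, with the published constants k = 0.25, r = 0.5, p = 2,
   q = 10. A pixel is a deficit when its intensity is *strictly* below
   t (ties go to flow, so an all-zero image has no deficit).
3. **Component quantification.** Deficit pixels are grouped into
   maximal connected components (8-connectivity by default) and reduced
   to FD% (deficit pixels / all pixels × 100), FD count, mean component
   area in µm², and total deficit area in mm², using the pixel area
   implied by the scan geometry.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| grid | 500 × 500 | px | 12 µm pitch on a 6 × 6 mm field, the common export size for this device class; always explicit because a "4 px" radius means different µm at different pitches |
| compensation σ | 2.0 | px | common practice for CC compensation at this pitch; the single most sensitivity-relevant knob |
| rescale mode | linear_to_full_range | — | without rescaling, compensated images sit at ~0.2 of full scale, where the `p·e^(−qµ)` term alone pushes t above µ and most of the image binarizes as deficit; `"none"` is kept for integer-arithmetic emulation studies |
| Phansalkar k, r, p, q | 0.25, 0.5, 2, 10 | — | published defaults for [0, 1] intensities, as used by the Fiji Auto Local Threshold plugin |
| window shape | circular | — | matches rank-filter neighbourhoods; `square` exists for oracle cross-checks |
| connectivity | 8 | — | "contiguous" is read as including diagonal contact; 4 selectable for sensitivity analysis |
| min component size | 0 | px | no small-deficit exclusion by default; the knob exists because CC pipelines are often asked to drop deficits below normal intercapillary distance |

Every report CSV records the full parameter set in a `#` header
comment, since FD metrics are known to shift materially with slab
definition, σ, window radius, and the threshold constants.

## Synthetic image model

Patient scans cannot ship with the package, so every stage is validated
on generated pairs with known ground truth (`ccfd.synthetic`).

* **Flow background**: a bright plateau at 0.70 of full scale with a
  mild correlated ripple (SD 0.02, correlation length 3 px) plus sparse
  dark *pits* carved from the texture field's tail below −1.5 SD
  (depth 0.35 per SD, floored at 0.25). The skew is deliberate: local
  adaptive thresholds flag the dark tail of *any* texture, and the pits
  are the controlled false-positive floor (≈2–4 FD% at radius 8 with
  no planted deficits). A symmetric texture would make that floor
  ~25% after full-range rescaling — no parameter choice avoids it —
  so the skewed background is what makes "truth ≈ measured" a
  meaningful calibration at all.
* **Deficits**: ellipses (aspect 1–3, random orientation) with
  lognormal areas, stamped at flow level 0.10 until the ground-truth
  fraction is within 0.01 of target or the blob budget is exhausted
  (then a warning is attached to the result, never a silent failure).
  The lognormal right tail mirrors the observed regime where diseased
  eyes carry most deficit area in few large lesions.
* **Structure**: near-uniform at 2/3 of full scale (ripple SD 0.02).
  The level is chosen so that a multiplicative shadow of attenuation
  0.5 satisfies `att·(1 − s·att) = 1 − s` exactly: invert-and-multiply
  compensation then restores the banded flow to its unshadowed level
  up to blur and noise, making the compensation benefit a property of
  the model rather than of tuning.
* **Shadow bands** multiply both flow and structure rows by the
  attenuation factor; **noise** is additive Gaussian (SD 0.01 of full
  scale by default). The returned truth mask is the pre-shadow,
  pre-noise blob union. All randomness flows from one `seed` through a
  single `numpy` Generator.

What the model does **not** emulate: OCTA speckle and decorrelation
statistics, projection artifacts, motion, vessel-shaped (non-elliptic)
deficits, or spatially varying signal strength. Passing the recovery
experiments therefore demonstrates that the *chain* is correct and that
compensation undoes multiplicative shadowing — not that FD% on patient
scans is accurate in any absolute sense.

## Numerical and design choices

* Quantization back to integer intensities is round-half-up
  (`floor(x + 0.5)`), used identically after smoothing, compensation,
  and synthesis.
* Window statistics use the population SD (divisor n) and
  edge-replicated borders, consistent with the smoothing stage.
* The compensation product is invariant (after full-range rescale) to
  any positive scaling of the *processed* structure multiplier; the
  inversion itself is affine, so scaling the raw structure image is not
  an invariance and is not claimed as one.
* A constant compensated product rescales to all zeros (degenerate
  min = max case), which then binarizes to all flow under the strict
  tie rule.
* Mann–Whitney p-values switch from exact enumeration to the
  tie-corrected normal approximation above a combined n of 12 or in the
  presence of ties; Kruskal–Wallis on fully identical samples returns
  H = 0, p = 1 by convention (the tie-corrected statistic is 0/0
  there). Welch's t on two zero-variance samples returns p = 1 when
  the means agree and is an error otherwise.
* The regression stage rejects rank-deficient designs with an error
  naming the collinear columns rather than silently dropping terms.
* Eyes are independent observations and p-values are uncorrected, by
  design parity with the study the package mirrors; both choices are
  statistically anticonservative and flagged here deliberately.

## Validation experiments and problem sizes

The test suite and `scripts/acceptance.py` generate their own inputs at
run time. Simulation grids are 144–200 px on the 6 × 6 mm field
(coarser pitch than the 500 px default) — the package's chosen sizes
for its validation experiments; results there are stable across seeds:

* thresholding is compared pixel-for-pixel against a literal per-pixel
  reimplementation over radii 1–8, both window shapes, both bit depths;
* component metrics are checked for conservation (component sizes sum
  to the deficit pixel count; mean × count = total × 10⁶) over random
  masks at both connectivities;
* recovery: planted fractions 10/25/40% over ten seeds give measured
  FD% monotone in the planted fraction with mean |error| ≈ 1–2.5
  points at both radii;
* shadowed pairs (two bands, attenuation 0.5): mean |measured − truth|
  ≈ 2 points with compensation vs ≈ 5 without;
* a three-arm cohort planted with the diseased-arm phenotype (largest
  deficit fraction carried by few large lesions) reproduces the
  qualitative pattern — highest FD% and mean deficit size and lowest
  count in that arm at both radii;
* the published per-arm summary table is internally consistent
  (FD% × 36 mm²/100 vs total area) to < 0.01 mm² for the two arms used
  as anchors; the third arm's printed pair is mutually inconsistent
  and is excluded from the check rather than reconciled.

## Known limitations

* The synthetic texture is a stand-in chosen for controllability;
  absolute FD% levels on real scans depend strongly on device, slab
  definition, and signal strength and are not predicted by these
  experiments.
* Compensation is exact in the generator only at the default
  attenuation/structure-level pairing; real RPE shadowing is neither
  purely multiplicative nor band-shaped.
* No large-vessel exclusion mask is applied before thresholding.
* Inter-eye correlation is ignored in all tests and regressions.
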