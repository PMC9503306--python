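# ccfd — choriocapillaris flow-deficit quantification

`ccfd` quantifies choriocapillaris (CC) hypoperfusion from en-face
swept-source OCTA slabs. It is written for retinal-imaging researchers
who export co-registered *flow* and *structure* en-face CC slabs (e.g.
a thin sub-RPE slab over a 6 × 6 mm macular field) and want the
standard flow-deficit (FD) biomarkers plus cohort statistics, with the
image-processing chain pinned down and testable:

1. **shadow compensation** — multiply the flow slab by the inverted,
   Gaussian-smoothed structure slab to undo RPE signal attenuation;
2. **Phansalkar local thresholding** — binarize with
   `t = µ·(1 + p·e^(−q·µ) + k·(σ/r − 1))` over a sliding circular
   window (radius 4 and 8 px by default; k = 0.25, r = 0.5, p = 2,
   q = 10 on [0, 1] intensities);
3. **component metrics** — FD% (deficit area fraction), FD count, mean
   FD size (µm²), and total FD area (mm²) from connected components of
   the deficit mask.

Because no patient data ship with the package, a synthetic-image module
generates flow/structure pairs with known ground-truth deficits
(including multiplicative shadow bands the compensation must undo), and
the test suite validates every stage against brute-force oracles and
recovery experiments. A statistics module reproduces the cohort-level
analysis plan (Kruskal–Wallis, exact/approximate Mann–Whitney, Welch's
t, multivariable regression of FD metrics on dose covariates).

## Worked example

Generate a synthetic eye with ~30% planted deficit area and quantify it:

```sh
$ ccfd synth --grid 200 200 --target-fd 0.30 --seed 7 --out eye1
wrote triplet to eye1 (truth FD fraction 0.2936)

$ python -c "from ccfd import RunConfig, ScanGeometry; \
    RunConfig(geometry=ScanGeometry(6.0, 6.0, 200, 200)).to_yaml('config.yaml')"
$ ccfd quantify --flow eye1/flow.tiff --structure eye1/structure.tiff \
    --config config.yaml --out eye1_report.csv
radius 4: FD% 30.34, count 183, mean size 59690.2 um^2, total 10.923 mm^2
radius 8: FD% 30.85, count 174, mean size 63832.8 um^2, total 11.107 mm^2
```

The planted ground truth was 29.36% deficit area; the full chain
measures 30.3–30.9% at the two window radii — the residual ~1 point
comes from the dark-texture false-positive floor and blob-edge effects.
`count` is the number of connected deficit components, `mean size`
their average area, and `total` the summed deficit area on the 36 mm²
field (FD%/100 × 36 up to one pixel's area). The same chain runs over a
whole cohort manifest with `ccfd cohort`, which also writes omnibus and
pairwise group comparisons.

The `analysis/` scripts are numbered narrative drivers over the same
library: `01_generate_cohort.py` synthesizes a three-arm cohort
(healthy controls, treated-without-toxicity, toxic-retinopathy
phenotype), `02_quantify_cohort.py` runs the per-eye chain,
`03_group_statistics.py` reproduces the statistical plan, and
`04_recovery_validation.py` measures ground-truth recovery and the
benefit of compensation on shadowed scans. Tables land in `results/`.

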