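"""Generate a synthetic three-arm cohort of en-face OCTA pairs.

Arms mirror the qualitative phenotypes of the hydroxychloroquine study
design: arm 1b (toxic retinopathy) gets the largest deficit fraction
carried by few large lesions, arm 1a (treated, no toxicity) the
smallest fraction in many small lesions, arm 2 (healthy controls) sits
in between.  Images and the manifest go to scratch/cohort/ (binary
artefacts); the cohort design table and ground truth go to results/.

Run from the repository root:  python analysis/01_generate_cohort.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ccfd import ScanGeometry, SyntheticSpec, generate_pair
from ccfd.io import write_enface, write_mask

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"

GEOM = ScanGeometry(6.0, 6.0, 200, 200)
EYES_PER_ARM = 10
MASTER_SEED = 20220914

# arm -> (target FD fraction, lognormal blob area mean/sd in px)
ARMS = {
    "1a": (0.33, 10.0, 6.0),
    "1b": (0.48, 300.0, 400.0),
    "2": (0.42, 30.0, 25.0),
}


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    rng = np.random.default_rng(MASTER_SEED)
    manifest_rows, design_rows, covariate_rows = [], [], []
    seed = 0
    for arm, (frac, blob_mean, blob_sd) in ARMS.items():
        for i in range(EYES_PER_ARM):
            eye_id = f"{arm}_{i:02d}"
            # small per-eye jitter of the planted fraction gives the arms
            # realistic within-group variance
            eye_frac = float(np.clip(frac + rng.normal(0, 0.02), 0.02, 0.9))
            spec = SyntheticSpec(
                geometry=GEOM, target_fd_fraction=eye_frac,
                blob_size_mean_px=blob_mean, blob_size_sd_px=blob_sd, seed=seed,
            )
            pair = generate_pair(spec)
            flow_path = SCRATCH / f"{eye_id}_flow.tiff"
            struct_path = SCRATCH / f"{eye_id}_structure.tiff"
            write_enface(pair.flow, flow_path)
            write_enface(pair.structure, struct_path)
            write_mask(pair.truth, SCRATCH / f"{eye_id}_truth.png")
            manifest_rows.append({
                "eye_id": eye_id, "group": arm,
                "flow_path": str(flow_path), "structure_path": str(struct_path),
            })
            design_rows.append({
                "eye_id": eye_id, "group": arm, "seed": seed,
                "target_fd_fraction": eye_frac,
                "truth_fd_percent": 100.0 * pair.truth.deficit_fraction,
                "blob_size_mean_px": blob_mean, "blob_size_sd_px": blob_sd,
            })
            if arm in ("1a", "1b"):  # only treated eyes carry dose covariates
                covariate_rows.append({
                    "eye_id": eye_id,
                    "age": rng.uniform(35, 75),
                    "treatment_duration": rng.uniform(2, 25),
                    "daily_dose_mg_per_kg": rng.uniform(4, 7),
                    "cumulative_dose_g": rng.uniform(600, 3500),
                })
            seed += 1
    pd.DataFrame(manifest_rows).to_csv(SCRATCH / "manifest.csv", index=False)
    pd.DataFrame(covariate_rows).to_csv(SCRATCH / "covariates.csv", index=False)
    design = pd.DataFrame(design_rows)
    design.to_csv(RESULTS / "cohort_design.csv", index=False)
    print(f"wrote {len(manifest_rows)} eyes to {SCRATCH}")
    print(design.groupby("group")["truth_fd_percent"].agg(["mean", "std"]).round(2))


if __name__ == "__main__":
    main()
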