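"""Tumor vs non-tumor characterization on synthetic brain scans.

Simulates a cohort of tumor-bearing brain FET-PET scans, runs the three-step
segmentation (1.8 x background threshold, exclusion cleanup, V_PETmax /
V_PET3mm / V_Bg contours), extracts features from all three contours and
tests (a) which features discriminate tumor from the 4 cc background sphere
(paired Wilcoxon, Bonferroni over the family) and (b) which features add
information beyond SUV_max and volume.

Writes per-contour feature tables and the two reports under results/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from fetrad.features import FeatureExtractor
from fetrad.screening import added_value, tumor_vs_background
from fetrad.segmentation import segment_tumor
from fetrad.synthetic import LesionSpec, ScannerProfile, gen_brain_pet

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
N_SUBJECTS = 32
OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

rng = np.random.default_rng(SEED)
scanner = ScannerProfile(psf_fwhm_mm=4.8, noise_sd=0.04)
extractor = FeatureExtractor()
shape = (48, 48, 48)

rows = {"petmax": [], "pet3mm": [], "bg": []}
for _ in range(N_SUBJECTS):
    lesion = LesionSpec(
        center=(shape[0] * 0.35, shape[1] * 0.35, shape[2] * 0.5),
        radius_mm=float(rng.uniform(8.0, 14.0)),
        contrast=float(rng.uniform(2.5, 5.0)),
        heterogeneity_sd=0.25,
    )
    img, _ = gen_brain_pet(1.0, [lesion], scanner, shape, seed=int(rng.integers(2**31)))
    contours = segment_tumor(
        img,
        bg_centers=((shape[0] * 0.75, shape[1] * 0.72, shape[2] * 0.3),
                    (shape[0] * 0.75, shape[1] * 0.72, shape[2] * 0.7)),
        bg_diameter_mm=16.0,
    )
    rows["petmax"].append(extractor.extract(img, contours.v_petmax))
    rows["pet3mm"].append(extractor.extract(img, contours.v_pet3mm))
    rows["bg"].append(extractor.extract(img, contours.v_bg))

tables = {k: pd.DataFrame(v) for k, v in rows.items()}
for k, t in tables.items():
    t.to_csv(OUT / f"features_v_{k}.csv", index=False)

for contour in ("petmax", "pet3mm"):
    rep = tumor_vs_background(tables[contour], tables["bg"])
    rep.to_csv(OUT / f"tumor_vs_background_v_{contour}.csv")
    print(f"V_PET{contour[3:]}: {100 * rep['discriminates_tumor'].mean():.0f}% of "
          f"features separate tumor from background (Bonferroni, n={N_SUBJECTS})")

av = added_value(tables["petmax"], tables["petmax"]["SUV_max"],
                 tables["petmax"]["Volume_cc"])
av.to_csv(OUT / "added_value_v_petmax.csv")
print(f"independent of SUV_max and volume: {int(av['independent_of_suvmax_volume'].sum())}"
      f" of {len(av)} features")
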