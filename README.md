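# fetrad

A tested, fully synthetic re-implementation of an FET-PET radiomics
prognostic pipeline for recurrent glioblastoma (rGBM) before re-irradiation.
It is aimed at medical-physics / radiomics researchers who want the complete
analysis chain — segmentation → features → screening → survival models — as
reusable, verifiable code rather than as a one-off in-house script.

Patients with rGBM may be offered re-irradiation, but the treatment carries
real morbidity, so identifying who will progress early (and where) matters.
The pipeline quantifies the pre-treatment amino-acid PET tumor signal with
radiomics features and asks which features predict time-to-progression
(TTP), overall survival (OS) and recurrence location (RL, inside vs outside
the initial PET-positive volume). Because no patient or phantom scans ship
with this package, a first-class synthetic-data module generates all inputs
with controllable ground truth, which is what makes every stage testable.

## The pipeline

1. **Segmentation** (`fetrad.segmentation`) — background SUV from two
   reference spheres; threshold V_Threshold = {SUV ≥ 1.8 × SUV(Bg)}; expert
   exclusion mask → V_PET; a 3 mm Euclidean margin → V_PET3mm; the
   contiguous component holding SUV_max → V_PETmax; a 4 cc background
   sphere V_Bg.
2. **Features** (`fetrad.preprocessing`, `fetrad.texture`,
   `fetrad.features`) — 135 named features: histogram and shape statistics
   plus GLCM/GLRLM/GLSZM/NGTDM texture features computed on the
   fixed-bin-width (W = 0.01 SUV) discretized ROI, with equal-probability
   quantized ("Q") and wavelet band-pass filtered ("WF_") variants. The
   headline texture feature is Small-Zone Low-Gray-Level Emphasis,
   SZLGE = Σ_{i,s} p(i,s)/(i²s²) over the gray-level size-zone matrix.
3. **Screening** (`fetrad.screening`) — phantom-based filters: scanner
   robustness (paired Wilcoxon over 18 contours rendered under two scanner
   profiles), intrinsic size dependence (Spearman vs voxel count over 102
   background contours; strong correlation ⇔ p < 0.05 and |r| > 0.8),
   tumor-vs-background discrimination (paired Wilcoxon, Bonferroni), and
   added value over SUV_max and volume.
4. **Prognostic models** (`fetrad.prognostic`) — median-split Kaplan–Meier
   with the log-rank test per feature under a Bonferroni α/K family
   threshold; redundancy pruning by strong-correlation groups; multivariate
   Cox signatures (risk score β′x) with likelihood-ratio, Wald and score
   overall tests; and an imbalance-adjusted bootstrap logistic model for RL
   with 0.632+ AUC/sensitivity.

## Worked example

Everything below runs from scratch in a couple of minutes; all numbers are
computed, none are bundled.

```bash
python analysis/01_phantom_screening.py      # phantom robustness + size screen
python analysis/02_tumor_characterization.py # tumor vs background, added value
python analysis/03_survival_signatures.py    # KM screen + Cox signatures
python analysis/04_recurrence_location.py    # bootstrap RL models
```

With the default seed this prints (abridged):

```
robust to the two scanner renderings: 59% of 135 features
strongly size-dependent over 102 background contours: 55%
V_PETmax: 94% of features separate tumor from background (Bonferroni, n=32)
independent of SUV_max and volume: 58 of 135 features
restricting to scanner-robust features: ['QLRHGE', 'QVariance_CM', 'SZLGE', 'WF_GLV']
univariate family K=4, Bonferroni threshold 0.0125; significant: []
TTP-radiomics-signature: ['SZLGE'] HR={'SZLGE': 2.4} (LR p=0.0016, Wald p=0.0025,
  score p=0.0026); risk-score KM log-rank p=0.0325
ttp_signature: AUC=0.70, sensitivity=0.56 (apparent 0.72, out-of-bag 0.70)
```

Reading: in this synthetic cohort SZLGE truly drives the progression hazard
(generator β = 0.8), and the pipeline recovers it — SZLGE survives the
phantom robustness screen, is the best univariate TTP predictor (though at
n = 32 it does not clear this run's Bonferroni bar), forms the TTP signature
with hazard ratio ≈ 2.4 per SD, and its risk score predicts whether the
recurrence falls inside the initial PET volume with bootstrap AUC ≈ 0.70.
High SZLGE ⇒ earlier, in-field progression, which is exactly the pattern
the generator encodes.

The same run is available as a single command, writing all tables plus a
provenance manifest to a run directory:

```bash
fetrad demo --seed 0 --out demo_run
```

Other subcommands (`simulate`, `segment`, `extract`, `screen`, `model`,
`rl-predict`, `run --config cfg.json`) expose each stage over NIfTI images,
CSV tables and JSON configs; see `fetrad --help`.

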