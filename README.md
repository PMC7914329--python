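# petrad

Robustness analysis of PET radiomic features under segmentation and
intensity-discretization variability, exercised end-to-end on synthetic
somatostatin-receptor PET phantom cohorts.

## The problem

Radiomic features (RFs) — quantitative descriptors of tumor uptake,
histogram shape, morphology and gray-level texture — are candidate imaging
biomarkers for neuroendocrine tumors imaged with ⁶⁸Ga-DOTA-peptide PET.
Before a feature can carry biological meaning, it must survive the two
largest controllable sources of methodological variability:

* **segmentation** — who (or what) draws the volume of interest: different
  human operators, a semi-automatic level-set algorithm, or SUVmax
  percentage thresholds applied inside a parent VOI;
* **intensity discretization** — how SUV values are binned into gray
  levels before texture matrices are built: absolute resampling (fixed bin
  size, here 64 bins over 0–60 SUV, "AR60") versus relative resampling
  (fixed bin number over the per-VOI min–max range, "RR").

`petrad` implements the full analysis for researchers who want to quantify
feature robustness on controlled synthetic data: a seeded phantom cohort
generator, the delineation tools, both discretizations, 51 features, and
the statistics layer that classifies robustness.

## What it computes

For every lesion, features are extracted under 5 segmentations
(4 simulated operators + the seed-initialized hybrid level set)
× 4 threshold settings (none, 20, 30, 40 % of in-VOI SUVmax)
× 2 discretizations = **40 combinations**, with **51 features** per
combination (10 conventional SUV statistics, 5 histogram, 4 shape, and 32
texture features from the GLCM, GLRLM, GLZLM/GLSZM and NGLDM families,
merged over the 13 unique 3-D directions at distance 1).

Robustness statistics:

* Dice similarity coefficient, DSC(V₁,V₂) = 2|V₁∩V₂| / (|V₁|+|V₂|);
* STAPLE: EM estimation of a consensus segmentation with per-rater
  sensitivity p and specificity q;
* two-way mixed-effects consistency ICC,
  ICC = (BMS − RMS) / (BMS + (N−1)·RMS), from the between-lesion and
  residual mean squares of the lesion × method ANOVA, classified as
  highly robust (ICC > 0.9), robust (> 0.8), moderate (0.5–0.8) or poor
  (< 0.5);
* per-lesion coefficient of variation, COVᴸ = 100·sd/mean of one feature
  across the N settings;
* Pearson correlation of each feature (averaged across segmentations) with
  lesion volume and SUVmax.

## Worked example

```python
import dataclasses
from petrad import PhantomConfig
from petrad.pipeline import RunConfig, run_experiment

phantom = dataclasses.replace(PhantomConfig(), n_lesions=8, n_patients=8)
result = run_experiment(RunConfig(phantom=phantom, seed=42))

seg = result.robustness_table("segmentation", threshold="none",
                              discretization="AR60")
op = result.dsc[(result.dsc.comparison == "operator_pair")
                & (result.dsc.threshold == "none")].dsc
print(f"lesions: {result.manifest.shape[0]},"
      f" feature rows: {result.features.shape[0]}")
print(f"mean inter-operator Dice: {op.mean():.3f}")
for feat in ("CONV_SUVmean", "CONV_TLSRE", "GLCM_Homogeneity", "GLZLM_SZLGE"):
    r = seg.icc[feat]
    print(f"{feat:18s} ICC={r.icc:6.3f} ({seg.robustness_class(feat):8s})"
          f" median COV_L={seg.median_covl(feat):5.1f}%")
```

prints

```
lesions: 8, feature rows: 320
mean inter-operator Dice: 0.708
CONV_SUVmean       ICC= 0.992 (high    ) median COV_L= 11.7%
CONV_TLSRE         ICC= 0.998 (high    ) median COV_L= 33.2%
GLCM_Homogeneity   ICC= 0.914 (high    ) median COV_L=  4.7%
GLZLM_SZLGE        ICC= 0.030 (poor    ) median COV_L= 67.9%
```

Reading the output: across the five delineations of each lesion, mean SUV
is both consistent (high ICC) and in good agreement; total lesion receptor
expression (TLSRE = SUVmean × volume in mL) stays perfectly rank-consistent
but disperses with the delineated volume (high COVᴸ); and the small-zone
low-gray-level texture feature collapses entirely, because it is driven by
the low-uptake lesion rim where delineations disagree most.

The same pipeline is available from the shell:

```sh
petrad simulate --seed 7 --outdir cohort/          # NIfTI cohort + manifest
petrad segment saeb --image cohort/L000_suv.nii.gz --seed-point 12 12 12 --out saeb.nii.gz
petrad segment staple cohort/L000_operator*.nii.gz --out staple.nii.gz
petrad extract --image cohort/L000_suv.nii.gz --mask saeb.nii.gz --out feats.csv
petrad run-all --seed 7 --outdir run/              # the full experiment
```

`run-all` writes `features.csv` (one row per lesion × combination),
`dsc.csv`/`dsc_summary.csv`, `robustness.csv` (per-feature ICC, class,
COVᴸ quantiles per comparison axis), `pearson.csv` and `summary.json`.

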