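# capnet

Quantifies en-face OCTA angiograms of the superficial retinal plexus into two
capillary metrics — **vessel skeleton density (VSD)**, the skeletonized-vessel
pixel count divided by the total image pixel count, and **vessel diameter
index (VDI)**, the binarized flow-pixel count divided by the skeleton pixel
count (average caliber in pixels) — and evaluates how much these metrics add
to demographic covariates when discriminating diabetic-retinopathy (DR)
severity.

The package is aimed at researchers studying OCTA-derived biomarkers of DR:
it supplies the full analysis chain (image binarization → skeletonization →
metric extraction → mixed-effects severity models → ROC evaluation) *plus* a
synthetic data layer — capillary-network angiograms with exact ground truth,
and eye-level cohorts with published group statistics — so every stage can be
validated without access to clinical images.

## The model

Eyes are nested in subjects and centers. DR severity (control / mild NPDR /
referable DR) is modeled by mixed-effects logistic regression:

```
logit P(severity) = β₀ + β_vsd·VSD + β_vdi·VDI + β_sex + β_htn + β_hld + u_subject + v_center
u_subject ~ N(0, σ_u²),  v_center ~ N(0, σ_c²)
```

fit by marginal maximum likelihood (adaptive Gauss–Hermite quadrature for the
subject intercept; Newton–Raphson with ridging inside). Odds ratios are
reported per 0.001-unit VSD and 0.01-unit VDI. Discrimination is evaluated by
ROC/AUC with paired AUC contrasts via the DeLong structural-components
covariance, subject-grouped 10-fold cross-validation, frozen-coefficient
external validation, and ROC-optimal VSD/VDI cutoffs maximizing the correct
classification rate.

## Worked example

```python
from capnet import (DEFAULT_PRESETS, NoiseModel, generate_capillary_network,
                    rasterize_angiogram, quantify)

truth = generate_capillary_network(245, DEFAULT_PRESETS["control"], seed=1)
img, mask, skel = rasterize_angiogram(truth, seed=1)
m = quantify(img)
print(f"VSD {m.vsd:.4f}  VDI {m.vdi:.3f}  skeleton px {m.n_skeleton_px}")
```

prints

```
VSD 0.1488  VDI 3.060  skeleton px 8932
```

— one uncalibrated control-like angiogram: 8932 of the 60 025 image pixels
are skeleton centerline (VSD 0.149), and on average each centerline pixel
carries about 3 flow pixels of caliber. After `calibrate_preset` tunes the
dropout and dilation knobs, batches of such images reproduce the published
group means (control VSD ≈ 0.153, referable VSD ≈ 0.131, referable VDI ≈ 3.01).

The full study pipeline writes its report bundle in one call:

```python
from capnet import RunConfig, run_pipeline
run_pipeline(RunConfig(seed=3), "run1/")   # demographics.csv, odds_ratios.csv,
                                           # evaluation.csv, cutoffs.json, log.txt
```

or from the shell: `capnet run --out run1/ --seed 3`. On the default
synthetic cohorts the evaluation table shows the familiar pattern: adding VSD
and VDI lifts the any-DR-vs-control AUC from ≈0.82 (covariates only) to
≈0.92, and the referable-vs-mild AUC from ≈0.66 to ≈0.88, with the
paired-contrast p-values < 0.001.

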