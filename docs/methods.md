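# Methods

## Scope

`capnet` implements the quantification of superficial-plexus OCTA angiograms
into vessel skeleton density (VSD) and vessel diameter index (VDI), and the
downstream severity analysis — mixed-effects multinomial/binary logistic
models, paired AUC contrasts, cross-validation, external transport, and
ROC-optimal cutoffs. It does not acquire or segment OCT volumes: inputs are
en-face grayscale flow images (vessels bright on dark). Projection-artifact
removal, deep-layer analysis, FAZ segmentation and area-based perfusion
density are out of scope.

## Metric definitions

For a binarized flow map B and its one-pixel skeleton S inside an N-pixel
image,

* VSD = |S| / N (dimensionless; the denominator is the **full** image area,
  including the foveal avascular zone),
* VDI = |B| / |S| (pixels; undefined when |S| = 0, and ≥ 1 otherwise since
  S ⊆ B).

Both are exact integer ratios; nothing downstream depends on image intensity
once the binary map is fixed.

### Binarization

The source analyses used a validated external tool whose exact thresholding
chain is not public, so absolute VSD/VDI values are binarization-dependent;
this package therefore anchors its accuracy claims to calibrated synthetic
images (below) rather than to any specific clinical device. Three methods
are provided and recorded in output metadata:

* `adaptive` (default): subtract a wide-Gaussian background estimate
  (σ = 12 px), clip at zero, global Otsu on the residual;
* `global_otsu`: plain Otsu;
* `vesselness_then_threshold`: multiscale Sato ridge response seeds a
  morphological reconstruction over the background-subtracted intensity map
  (guards against the ridge filter's caliber shrinkage), Otsu fallback.

A constant image binarizes to an empty map by convention. On noiseless
synthetic renders all three methods reach Dice ≥ 0.9 against the rasterizer's
ground-truth mask (in practice ≈ 1.0).

### Skeletonization

Morphological thinning (Lee's method, 8-connectivity), followed by a
simple-point pruning pass that deletes any pixel of a residual 2×2 skeleton
block whose removal preserves local connectivity. The only 2×2 blocks that
survive are irreducible diagonal vessel crossings, where every pixel is
needed to keep all four arms connected; these are counted as skeleton, since
the VSD definition counts all skeletonized vessels. No spur pruning is done
by default. A consequence of pixel counting is that skeleton *length* is
orientation-dependent for a single straight segment (a 45° line has ~29%
fewer pixels than its Euclidean length); for isotropically oriented networks
like the capillary mesh this bias is uniform and rotation-robust, which is
the property the tests check.

## Synthetic angiograms

The generator emulates a 3-mm macular scan sampled on a 245×245 grid.

* **Topology**: edges of a Voronoi diagram over a jittered grid of seed
  points (density 0.0097 points/px², chosen so the undropped mesh slightly
  exceeds the densest observed group), giving a polygonal capillary bed with
  the right density degrees of freedom; a circular FAZ (radius 9.5% of the
  field) is cut out; four wider, gently curved trunk vessels cross the field
  to give the caliber distribution a realistic tail.
* **Severity knobs**: *dropout* removes random edges until the rasterized
  centerline pixel union scales as (1−d) of the full mesh (linear-in-d
  skeleton length despite junction pixel sharing); *dilation* multiplies all
  calibers. Microaneurysms and hemorrhages are deliberately not simulated —
  the metrics do not measure them.
* **Rasterization**: centerlines drawn at 1× for the skeleton ground truth;
  the vessel mask is rendered at 2× (pixel within half a caliber of the
  nearest centerline pixel) and area-majority downsampled, so effective
  caliber responds smoothly to sub-pixel width changes. Base capillary width
  2.7 px with ±8% per-segment jitter, trunks 1.5–1.9×. Noise is additive
  Gaussian (σ = 14 gray levels) on a background floor of 28 with vessels at
  200; with zero noise the image is nonzero exactly on the mask.
* **Calibration** (`calibrate_preset`): nested 1-D Brent root-finds on
  dropout (targeting mean measured VSD) and dilation (targeting mean
  measured VDI), evaluated with common random numbers — the same `n_calib`
  network seeds at every knob value — so the objective is a smooth,
  effectively deterministic monotone function of the knob. Two outer passes
  absorb the weak dropout→VDI and dilation→VSD cross-couplings.

**What the simulator does not emulate**: OCT speckle statistics, flow-signal
physics, projection artifacts, motion artifacts, axial-length scaling, and —
importantly — the full between-eye biological variance. Per-image scatter is
geometric (network realization plus noise), with SD ≈ 0.002 in VSD, smaller
than the published between-eye SDs (0.006–0.012); the published group SDs
enter the analysis through the cohort generator's Gaussian draws instead.
Passing metric-recovery tests therefore demonstrates that the measurement
pipeline is unbiased and tightly calibrated for mesh-like vasculature, not
that it reproduces clinical image heterogeneity.

## Synthetic cohorts

Eye-level tables mirror the two published cohorts: a training cohort of 509
eyes / 331 subjects (159/155/195 eyes control/mild/referable) across 3
centers, and a validation cohort of 85 eyes / 54 subjects (16/69
mild/referable) from one screening center. VSD/VDI are Gaussian with the
published group means/SDs, decomposed into a subject component (variance
share = within-subject correlation, default 0.5) plus an eye residual;
binary covariates (sex, hypertension, hyperlipidemia) are subject-level
Bernoulli draws at the published prevalences; age is generated from the
published means/SDs but excluded from default models (it was not retained as
a confounder in the source analysis). Small Gaussian center offsets
(0.0005 VSD / 0.005 VDI) stand in for center effects. Neither the
within-subject correlation nor center variance is published; both are
config-exposed defaults, not data-derived.

A fraction (default 0.3 of eligible two-eye subject pairs per adjacent class
pair) of two-eye subjects exchange one eye's class label in count-preserving
swaps, so some subjects carry eyes of differing severity. Without any
discordance the severity outcome is constant within subject and the subject
random intercept's likelihood increases without bound; real cohorts contain
such subjects (the source demographics explicitly footnote them).

`simulate_logistic_cohort` is a separate generator whose outcome really is
Bernoulli with a known logit (fixed β, subject intercept SD 0.7, ~1.55
eyes/subject); it is the ground truth for parameter-recovery and CI-coverage
checks.

## Estimation

* **Binary mixed logit** (`MixedLogit`): marginal ML. With only a subject
  intercept, the per-subject scalar integral is computed by adaptive
  Gauss–Hermite quadrature (7 nodes, centered and scaled at the per-subject
  posterior mode found by damped Newton). With a crossed center intercept,
  subjects are still integrated by AGQ while the few large center effects are
  carried as penalized parameters in the outer optimizer with a Laplace
  log-determinant correction — Laplace is essentially exact for clusters of
  that size, whereas for 1–2-eye subject clusters it materially
  under-penalizes large variances (it made the profile likelihood monotone in
  σ on concordant data), which is why quadrature is used wherever the random
  effect is scalar per subject.
* **Multinomial mixed logit** (`MixedMultinomialLogit`): baseline-category
  logits (reference = control) with one subject intercept shared across the
  non-reference contrasts, so the u-dependence enters only through the total
  non-reference probability and the same scalar-AGQ machinery applies
  (7 nodes by default).
* Outer optimization is L-BFGS-B over (β, σ) with σ bounded in [1e-6, 8];
  inner mode searches are Newton with Levenberg-style diagonal ridging on
  non-PD Hessians. Design columns are internally centered/scaled (VSD enters
  at ~0.14 with unit-scale coefficients ~−160, which is otherwise badly
  conditioned) and mapped back afterwards. Standard errors come from the
  numerically differentiated Hessian of the marginal log-likelihood;
  significance tests are Wald z. (The source analysis quotes a
  Satterthwaite denominator-df method; SAS does not document an
  implementable recipe for this model class, so Wald is used and the
  difference is immaterial at these sample sizes.)
* With the random-effect SD pinned at zero the fit reduces exactly to a
  ridged-Newton IRLS logistic (or baseline-category multinomial) fit; tests
  pin this against statsmodels `Logit`/`MNLogit` at 1e-6.
* Complete separation raises an explicit convergence error; rank-deficient
  designs raise a singular-design error. Cross-validation folds that
  separate are refit with a weak (1e-4) L2 ridge, which leaves the held-out
  ranking intact.
* **Variable selection**: backward elimination on Wald p-values until all
  retained terms have p < α, then a single forward re-entry sweep in the
  original candidate order — a deterministic rendering of
  backward-plus-stepwise selection. The result is a fixed point: every
  retained term significant, every excluded term non-significant on
  re-entry.
* **Calibration check**: Hosmer–Lemeshow decile-of-risk χ² with g−2 df
  (observations sorted by fitted probability, g near-equal groups).

## Discrimination analysis

AUC is the empirical Mann–Whitney probability (ties ½), identical to the
trapezoid area of the empirical ROC; its variance and the covariance of two
AUCs on the same eyes use the DeLong structural-components estimator over
placement values, with the paired difference referred to χ²(1). Eyes are
treated as independent in the AUC contrast — the clustering adjustment lives
in the model, not the ROC test — a documented limitation shared with the
source analysis. Cross-validation splits by subject (both eyes travel
together) with outcome stratification; models are refit per fold and score
held-out eyes through the fixed linear predictor only. External validation
freezes the training-cohort coefficients. Optimal metric cutoffs scan
midpoints of sorted distinct values for the maximal correct classification
rate on one best eye per subject (fewest artifacts, then higher signal
strength, then OD), with rate ties resolved toward the grand median;
reported thresholds are rounded to 3 decimals (VSD) / 2 (VDI). The
operating points quoted alongside AUCs use Youden's J, a documented choice —
the source tables do not state their rule.

## Power check

The post-hoc power utility uses the two-sample normal approximation
power = Φ(z − z₁₋α/₂) + Φ(−z − z₁₋α/₂) with z = |Δ|/√(s₁²/n₁ + s₂²/n₂),
with eye counts as n (the sampling unit of the published table). A
Monte-Carlo Welch-test oracle validates it in the tests.

## Problem sizes and determinism

All randomness descends from one top-level seed through named CRC-keyed
substreams (network geometry, noise, cohorts, folds, calibration,
evaluation), so every table and image is bit-reproducible per seed. Default
problem sizes: calibration with 40 common-random-number seeds per knob
evaluation (25 in the test suite), 100 evaluation images per group, 200
replicates for coverage/power-style property checks, 10-fold (tests: 4–5)
cross-validation. These sizes put calibration bias and Monte-Carlo error
well inside the tolerances checked while keeping any single check in the
minutes range.

## Known limitations

* Absolute VSD/VDI are binarization-dependent; cross-device comparability is
  exactly as good as the binarization is matched.
* The Voronoi mesh has no hierarchy, flow physics, or pathology other than
  dropout/dilation; conclusions about the *measurement* pipeline transfer to
  real angiograms only insofar as their vasculature is mesh-like at this
  resolution.
* Conditional (subject-specific) odds ratios from the mixed fits on the
  distribution-generated cohorts are farther from 1 than the published
  marginal-looking values whenever the estimated subject variance is large;
  this is the usual conditional-vs-marginal effect, not a fitting defect
  (the logistic-generative recovery tests confirm unbiasedness when the
  model is true).
* The chi-square AUC contrast ignores eye clustering; with ~1.5 eyes per
  subject its p-values are mildly anti-conservative.
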