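# Methods

This note documents the models, conventions and design decisions behind
`swe_radiomics`, in the order the pipeline runs them.

## Synthetic phantom cohorts

The generator (`swe_radiomics.synthetic`) produces paired B-mode / SWE case
bundles with the statistical structure the analysis assumes, not acoustic
realism.  Each case is a star-convex lesion (radius modulated by random
low-order harmonics, so segmentation and ROI code faces realistic,
non-elliptical boundaries) on a fatty background:

| parameter | default | meaning |
|---|---|---|
| `benign_stiffness_mean` | 25 kPa | lesion Young's modulus, benign class |
| `malignant_stiffness_mean` | 120 kPa | lesion Young's modulus, malignant class |
| `fat_stiffness_mean` | 8 kPa | background fatty tissue |
| `stiffness_noise_sd` | 8 kPa | additive within-lesion noise |
| `rim_stiffness_boost` | 40 kPa | stiff peritumoral annulus (malignant only) |
| `texture_heterogeneity` | (0.05, 0.25) | log-normal speckle sigma per class |
| `boundary_irregularity` | (0.08, 0.18) | radial-harmonic amplitude per class |
| `lesion_diameter_range` | 5–9 mm | uniform draw |
| `pixel_spacing` | 0.15 mm/px | free parameter (no canonical value exists) |
| image size | 96 × 128 px | desk scale |

The defaults put the two classes on either side of the ~46 kPa
E<sub>max</sub> working cutoff for breast masses, with malignant lesions
heterogeneous, irregular and rim-stiffened — the observation that the
stiffest tissue of a malignant mass is peritumoral is encoded both in the
elasticity map (rim annulus) and in the SWE contouring convention below.

Segmentation conventions are encoded **in the generator**, since contouring
is a human act the pipeline merely consumes: homogeneous (benign-type)
masses are contoured at the mass border; rim-stiffened masses include the
peritumoral annulus.  The dilation is keyed to the actual rim stiffening
(`rim_stiffness_boost > 0`), not to the class label, so a null cohort
(equal class distributions via `null_spec`) carries no label-dependent
contouring artifact — this matters for the anti-leakage end-to-end test.

Repeat segmentations (second session, second rater) are simulated by
`perturb_mask`: the signed distance to the mask boundary is thresholded
against a Gaussian-smoothed noise field scaled to a chosen amplitude
(default 1.5 px), which keeps Dice agreement in the "excellent" band
(> 0.75), matching the agreement level the screening step assumes.

The SWE color overlay maps kPa monotonically onto a dark-blue → light-blue
→ green → orange → red ramp (matplotlib "jet"), clamped at a display
maximum (180 kPa default).

An ordinal `birads_like` category (3 / 4a / 4b / 4c / 5) is drawn from a
label-conditional distribution with a configurable error rate.  It exists
solely to exercise the comparison statistics and makes no claim of
modelling radiologist behaviour.

What the phantoms do **not** model: speckle statistics of real ultrasound,
posterior acoustic features, operator pressure artifacts, vendor color
scales, lesion-size/age confounding.  Passing tests therefore demonstrate
that the pipeline machinery is correct and leak-free, not that the
signatures would perform comparably on clinical images.

## Patch extraction

The mask's axis-aligned bounding box (optionally margin-expanded, clipped
to the image) is cropped and resized bilinearly to the network input with
no aspect preservation — target size (height 302, width 430) at full scale,
interpreted as landscape, and (96, 128) at desk scale.  Intensities are
min–max scaled to [0, 1] per patch (constant crops map to zeros); whether
the original work scaled intensities is unstated, so this choice is logged
here and in the extractor version tag.  Masks are never resampled;
grayscale inputs are replicated to three channels so one architecture
serves both modalities.

## CNN feature extractor

Layer stack: conv3×3(32)+ReLU → maxpool2×2 → conv3×3(64)+ReLU → maxpool2×2
→ flatten → FC512+ReLU → dropout(0.5) → FC256+ReLU → FC2.  Same-padding is
used (padding is unstated in the source description; same-padding keeps the
pooling arithmetic transparent).  Odd spatial dimensions are cropped by the
pool layers (302 → 151 → 75).

Training: stratified 8:2 train/internal-validation split, SGD with learning
rate 0.01 (momentum 0, batch size 8 — batch size, initialization and
momentum have no published values, so He initialization and these defaults
are fixed in `TrainingConfig` and reported rather than guessed), categorical
cross-entropy, 80 epochs at full scale.  On-the-fly augmentation on the
training stream only: random horizontal/vertical flips and random zoom in
[0.9, 1.1] ("rescaling" has no published range; ±10% is a conventional
choice).  The checkpoint with the best internal-validation **accuracy** is
kept (the selection metric is described only as "performance").

Features are the concatenated post-ReLU activations of the FC512 and FC256
layers, evaluated in inference mode (dropout inactive):
512 + 256 = 768 per patch.  "Second and third to the last" fully connected
layers are read counting the 2-node output as last, which is the only
reading that yields 768.  The feature length is independent of input size.

At the full 302×430 geometry the FC512 layer alone holds ≈2.6×10⁸ weights;
the architecture description (`build_network`) supports that geometry, but
training at desk scale uses the reduced 96×128 input (and the test suite
uses 48×64), with epochs scaled down accordingly (15–20).  These problem
sizes are the package's desk-scale defaults; the full regimen remains
available through `NetworkConfig`/`TrainingConfig`.

The CNN is implemented directly in NumPy (im2col convolution, explicit
backward passes, seeded Generator for init/dropout/shuffling/augmentation),
which makes training bit-reproducible for a fixed seed on a given BLAS.

## ICC reproducibility screen

Per feature, the intra-rater ICC (rater 1, sessions 1 vs 2) and inter-rater
ICC (rater 1 vs rater 2) are computed from the two-way ANOVA decomposition.
The form is the two-way random-effects, absolute-agreement, single-measure
ICC(2,1) — chosen because the question is agreement of measurement values
across raters, where systematic shifts should be penalized; the consistency
form ICC(3,1) is available as an option.  Negative estimates are kept
as-is; zero-variance features yield an undefined ICC and are not retained.
Retention requires **strictly** greater than the threshold (default 0.6) on
both ICCs, matching the published "ICC > 0.6" criterion; note that at a
threshold of exactly 1.0 strict inequality retains nothing.

## Rad-score signature

LASSO selection uses L1-penalized logistic regression (the published
procedure names only "LASSO regression" for a binary outcome; binomial
deviance is the natural likelihood), with the penalty chosen by stratified
cross-validation minimizing deviance over a logarithmic grid (25 points,
1e−4…1e3 on the `C` scale), 10 folds by default and clamped to the class
size at desk scale.  Features are standardized before the fit;
coefficients are reported on the standardized scale and the
standardization constants travel with the serialized model, flagged in the
JSON, so raw vectors score identically through `rad_score`.

The rad-score is the fitted linear predictor:
`intercept + Σ coefficient_i · feature_i` over the selected (non-zero)
features.  Orientation (whether higher scores indicate malignancy) is set
by requiring training AUC ≥ 0.5 and recorded in the model — the package's
own fits are higher-is-malignant by construction, while the shipped
reference signatures (all-negative coefficients) record
lower-is-malignant as a documented assumption.

The operating threshold maximizes the Youden index over candidate
cutpoints: midpoints between adjacent sorted unique scores plus the two
extreme cutpoints (call-none / call-all; without these an anti-oriented
score vector would return a negative J where exhaustive enumeration finds
J = 0).  Ties break toward higher specificity, then the lower threshold.

The two frozen reference signatures under `swe_radiomics/fixtures/` are
published formulas transcribed verbatim (indices into the 768-vector,
coefficients, intercepts, operating thresholds −1.28 / −0.24).  They
validate scoring arithmetic and report rendering only; fits on synthetic
cohorts select different indices, necessarily.

## Quantitative SWE parameters

* **Max-stiffness ROI**: a circle of 2 mm² (radius `sqrt(area/π)/spacing`
  px) whose admissible centers lie within the lesion mask dilated by one
  ROI radius — the smallest neighbourhood consistent with "within or
  adjacent to the mass" — with the whole circle inside the acquisition
  box.  The center maximizing mean elasticity wins; exact ties resolve to
  the smallest row, then column (the implementation is tested equal to
  exhaustive search).
* **Fat ROI**: same size, fully inside the fat mask and the box, placed at
  the admissible center farthest from the lesion.
* **E<sub>SD</sub> ROI**: the "round ROI adjusted to the mass contour to
  encompass the maximum area" is operationalized as the maximum inscribed
  circle of the lesion mask (distance-transform argmax).
* Parameters: E<sub>max</sub>/E<sub>mean</sub> = max/mean over the lesion
  ROI; E<sub>ratio</sub> = lesion-ROI mean over fat-ROI mean (assumed to
  share the lesion ROI's numerator, which is implied but not stated);
  E<sub>SD</sub> = standard deviation over the E<sub>SD</sub> ROI,
  population form (n denominator) by default since the device convention
  is unknown — `sd_ddof=1` switches to the sample form.
* **Triplicates**: each case is measured three times (synthetic repeats add
  seeded 2-kPa acquisition jitter before re-placement) and collapsed as the
  maximum of E<sub>max</sub> and the median of the other three parameters.

## Diagnostic statistics

* Proportions: exact Clopper–Pearson 95% CIs; table percentages round half
  up to integers with the raw counts bracketed.
* Likelihood ratios: PLR = sens/(1−spec), NLR = (1−sens)/spec; 95% CIs by
  the Simel log method on the counts; a perfect specificity yields an
  infinite PLR (rendered "∞"), a perfect sensitivity yields NLR = 0, and
  CIs are omitted at those boundaries.  Interpretation bands: positive
  > 10 large, 5–10 moderate, else small; negative < 0.1 large, 0.1–0.2
  moderate, else small.  LRs print with two decimals (integers from 100).
* AUC: Mann–Whitney statistic with ties at 1/2; variance, 95% CI and the
  two-sided paired z-test from DeLong's structural components (the
  implementation is cross-checked against R's pROC and against brute-force
  pair counting).  Zero-variance differences report p = 1 for identical
  scores and p = 0 otherwise.
* McNemar: exact binomial when the discordant total is below 25, otherwise
  chi-square with continuity correction; (b, c) = (0, 0) reports p = 1.
* Bonferroni: adjusted p = min(1, m·p), comparison-wise threshold α/m.
* Baseline comparisons: Shapiro normality per group (α 0.05) selects
  Student's t (both normal) vs Mann–Whitney U; chi-square for categoricals.
* The proportion-CI and LR-CI methods above are standard choices fixed by
  this package; published tables of this kind usually leave them unnamed.

## Pipeline

Three cohorts (training / independent validation / external validation;
desk defaults 40/16/8 cases) are generated from per-cohort seeds derived
from one pipeline seed.  Validation cohorts never enter network training,
ICC screening or signature fitting; a case-id disjointness check hard-stops
the run otherwise.  Operating thresholds for every classifier — both
rad-scores, each quantitative parameter, their "combined" score and the
ordinal category — are fixed on the training cohort (Youden) and applied
unchanged to the validation cohorts.  The combined quantitative model is an
unpenalized logistic regression on the four parameters, fitted on training
only (how such a combination was obtained originally, and its threshold,
is unpublished; this choice is documented, not claimed equivalent).  All
artifacts (signature JSONs, ICC tables, feature CSVs, per-cohort
performance tables, rad-score scatter data, run log with config hash and
seeds) are written to the run directory.

## Known limitations

* Phantom realism is deliberately minimal (see above); absolute performance
  numbers on phantoms say nothing about clinical images.
* The per-feature significance test between readers' selected feature sets
  reported alongside the original ICC screen has no published definition
  and is not implemented.
* Bit-reproducibility of CNN training holds for a fixed BLAS/threading
  configuration; across different BLAS builds results may differ in the
  last float digits.
* The full 302×430 training geometry is supported but impractical without
  hardware acceleration; desk-scale geometry is the tested path.
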