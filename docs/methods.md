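# Methods

## Generalized polarization imaging

Laurdan partitions into the plasma membrane and shifts its emission with
lipid packing; the generalized polarization

GP = (I_blue − G·I_green) / (I_blue + G·I_green)

is computed per pixel from the background-subtracted intensity images of
the two emission bands (blue 400–460 nm, green 470–530 nm).  For
non-negative intensities GP lies in [−1, +1]; pixels whose total intensity
I_blue + G·I_green does not exceed 1e−9 (photon-count scale) are removed
from the validity mask instead of producing unstable ratios.  Off-mask
values are stored as NaN, never as zero.

The instrument calibration factor `G` corrects the relative detection
efficiency of the two bands.  No calibration value is assumed; the default
is 1.0 and any positive value can be configured.

Preprocessing follows the standard chain for this assay:

* **Background** is estimated per image as the mean intensity below the
  global Otsu threshold (an explicitly measured value can be supplied
  instead), then subtracted with clamping at zero.
* **Segmentation / debris removal**: Otsu threshold on the summed two-band
  image, 8-connected components, and components below `min_area_px`
  (default 100 px = 4 µm² at 200 nm/pixel) are discarded.  An RBC footprint
  is two orders of magnitude above this area, typical debris below it.
* **Summaries**: mean, population variance and a histogram with fixed edges
  spanning [−1, 1] (default 100 bins) over masked pixels, so histograms are
  comparable across images and patients.

Coordinates are row-major, origin top-left, 0-based everywhere.

## Synthetic cohort model

No public images exist for this assay, so all pipeline stages are exercised
on a simulator that emulates the study design and retains ground truth.

**Membrane geometry.** Each image holds one cell as an annular footprint
(outer radius 3.5 µm, inner 2.5 µm, centred with ±5 % jitter): the dye
reports only the plasma membrane, and the annulus represents the
membrane-dominated signal of a disc-shaped cell viewed en face.  Images are
256×256 px at 200 nm/pixel by default.

**GP field.** The membrane carries a smooth background GP field —
low-pass-filtered white noise with 1 µm correlation length, scaled to a
marginal SD of 0.03 — around a group base level, plus circular *fluid
domains*: the count is Poisson with mean `density × membrane area`, centres
uniform on the membrane, diameters uniform in 500–1000 nm, each lowering GP
by 0.2 inside its disc.  Overlaps stack and values clamp to [−1, 1].
Defaults per group:

| group | base GP | expected domains / cell |
|-------|---------|-------------------------|
| G0    | 0.45    | 0                       |
| G1    | 0.40    | 40                      |
| G2    | 0.33    | 120                     |

Base levels are declared simulation values chosen to reproduce the
qualitative group ordering (absolute per-group GP levels are not published
for this assay); densities are stored per µm² but configured as expected
counts per cell via the default annulus area (18.85 µm²).  With these
defaults the realized group means of true GP are ≈ 0.45 / 0.20 / −0.20 with
strictly increasing variance — a monotone fluidification with widening
spread, which is the structure the classifier consumes.

**Rendering.** Per membrane pixel the photon budget S (default 2000) is
split to invert the GP definition exactly: I_blue = S(1+GP)/2, I_green =
S(1−GP)/(2G).  Off-membrane pixels carry a flat background (default 20
photons).  Shot noise is Poisson per channel; Gaussian read noise is
available but off by default.  A noiseless render followed by the GP map is
an exact algebraic round-trip (tested to 1e−9), and at S = 500 the
shot-noise GP estimator bias at GP = 0.4 is below 0.01.

**Covariates.** Gaussian per group unless noted: HbA1c G0 ~ N(5.3, 1.05),
G1 = G2 ~ N(7.9, 1.2) — identical by design, emulating cohorts matched for
metabolic control, and giving the control group a coefficient of variation
near 0.2; total cholesterol 170/185/205 (SD 25/28/30) and LDL 95/108/122
mg/dl rise with stage; disease duration is uniform in 1–14 y (G1) and
15–34 y (G2), zero for controls; diabetics receive MDI or CSII insulin
therapy with probability 0.5 each, with therapy-specific dose distributions
(MDI 0.62 ± 0.15, CSII 0.45 ± 0.12 U/kg, floored at 0.1) and a therapy GP
offset (CSII −0.08, MDI 0) representing the more fluid membranes of pump
patients.  Each patient contributes 10 independent fields as a z-stack (a
per-patient count is not dictated by the assay; it is a config value).

A cohort is a pure function of its config including the seed; the
ground-truth ledger records per-image cluster counts and true GP moments.

**What the simulator does not model:** optics (no point-spread function,
the membrane edge is pixel-sharp), discocyte 3-D geometry, hemoglobin
autofluorescence, photobleaching, spatial covariate effects beyond the
scalar therapy offset, and any patient-level random effect on texture
beyond the therapy offset — images within a group are otherwise i.i.d.
Passing tests therefore demonstrate correctness and internal consistency of
the analysis chain under the declared generative model, not performance on
real microscope data, where between-patient texture variability would lower
all accuracies.

## Texture descriptors

Computed per channel on raw intensities (the GP map feeds only the scalar
baseline and reporting), on the full frame by default; every family also
supports restriction to the segmented cell mask.

* **First-order (6):** mean, population variance, skewness and excess
  kurtosis (defined as 0 for constant regions), plus energy Σp² and entropy
  −Σp log₂p of a 64-bin gray histogram over the observed range.
* **GLCM (5):** intensities quantized to 32 equal-width levels over the
  masked range (stable matrices at the ~10⁴–10⁵ pixels per frame);
  symmetric, normalized co-occurrence matrices restricted to in-mask pairs
  for offsets (0,1), (1,0), (1,1), (1,−1); contrast, correlation
  (defined as 1 for a single-level matrix), energy (Σp²), homogeneity
  (Σp/(1+|i−j|)) and entropy, averaged over offsets.
* **RICLBP (666):** each pixel's 8-bit LBP code compares the 8 square-ring
  neighbours at radius 1 against the centre with ≥ (ties set the bit, so
  codes are reproducible bit-exactly and invariant to adding a constant),
  canonicalised to the minimum over circular bit-shifts (36 classes).  The
  descriptor is the normalized joint histogram of unordered code pairs at
  displacement 2 px along 0°/45°/90°/135°.  Using the square ring makes the
  descriptor *exactly* invariant under 90°/180°/270° rotations: rotation
  cyclically shifts each code by two bits and permutes the four directions.

The feature set is pluggable; the classifier only sees named columns.

## Decision-support system

Per channel: per-feature standardization (descriptor families have
incommensurate scales), PCA truncated at the smallest component count whose
cumulative explained variance reaches 0.99, and a multi-class SVM (linear
kernel, C = 1, one-vs-one — the standard defaults where none are dictated
by the problem) labelling each image.  A patient's channel label is the
majority over the z-stack; the final label is the weighted vote of the two
channel decisions.

**Fusion weights** are each channel's patient-level accuracy estimated by a
class-stratified 3-fold split of the *training* patients, so weights carry
no test information.  **Tie rules**, fixed for reproducibility: a tied
stack majority in either channel is resolved by the weighted sum of both
channels' mean per-class SVM scores (a split stack must not outvote a
decisive one); between two decisive channels disagreeing, the larger weight
wins, then the lower class index.

**Evaluation** is leave-one-person-out: every fold refits standardizer,
PCA, SVMs and fusion weights on all other patients — the retained component
count may therefore differ per fold — and predicts the held-out patient.
Fold audit records (training patient sets, fitted standardizer means) let
tests prove the held-out patient contributes nothing to any fitted
component.  Results accumulate into a 3×3 confusion matrix (rows =
predicted, columns = true) from which accuracy = trace/total and per-class
precision, recall and F1 are computed; zero-denominator ratios report 0 and
are flagged.

**Scalar baselines:** a Gaussian class-conditional maximum-posterior
classifier on one scalar per patient (class sample mean and sample SD
floored at 1e−6, priors = training frequencies, ties to the lower class
index), applied under the same LOPO protocol to HbA1c and to the stack-mean
GP.

A note on null behaviour: with class-independent features, LOPO accuracy
sits *below* 1/3, because the held-out patient's class is always
under-represented in its training fold — the standard below-chance bias of
leave-one-subject-out.  The leakage control therefore checks that null
accuracy does not exceed chance.

## Cohort statistics

Welch (unequal-variance) two-sided t-tests for all group pairs, reported
without multiplicity correction and flagged at 0.05 and 0.001; coefficient
of variation = sample SD / |mean|; ordinary least squares with
R² = 1 − SS_res/SS_tot for the control-normalized duration trends and the
per-group GP-vs-lipid relations (slope sign and R² only — no causal claim).
The insulin-therapy summary reports, for a configurable line in the
(dose, GP) plane, the fraction of MDI patients above and CSII patients
below it; when no line is configured a horizontal line at the midpoint of
the two therapy means is used as a display convention.  In a mixed G1+G2
cohort the disease-stage GP gap dominates any single line, so the
separation is informative within a disease stage.

## Numerical and scale choices

Denominator tolerance 1e−9; GP values clipped to [−1, 1] against last-bit
rounding; histogram edges fixed; SD floor 1e−6 in the Bayes baseline;
population moments for image statistics, sample moments for patient-level
statistics.  Degenerate inputs (empty masks, single-class training sets,
all-zero confusion matrices, single-patient cohorts) raise typed errors
rather than returning silent defaults.  The analysis drivers and the
acceptance run use the study-sized cohort (26 patients × 10 image pairs at
256², ~25 s end-to-end per cohort on one CPU); multi-seed checks use 5
seeds at the same scale.

## Known limitations

The simulator's i.i.d. per-group images make the classification task easier
than real cohorts; the DSS's perfect LOPO accuracy on simulated data
mirrors the structure of the task, not expected clinical performance.
Absolute GP levels, fusion weights, SVM hyperparameters and the z-stack
depth are declared configuration, not measured quantities.  RICLBP is
implemented for the 8-neighbour ring only.  Features computed full-frame
include background pixels; the masked mode is available but changes the
descriptor distribution.
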