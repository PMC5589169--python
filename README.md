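# rbcfluidity

Analysis pipeline for red-blood-cell (RBC) membrane fluidity imaging in
type 1 diabetes mellitus (T1DM).

RBC plasma membranes fluidify as T1DM progresses: fluid lipid domains
(diameter 0.5–1 µm) nucleate on the membrane, growing in number from
healthy controls (G0) through uncomplicated diabetes (G1, < 15 years since
diagnosis) to diabetes with complications (G2, ≥ 15 years).  Laurdan
two-photon imaging measures this through the generalized polarization

```
GP = (I_blue − G · I_green) / (I_blue + G · I_green)
```

computed per pixel from the two emission bands (blue 400–460 nm, green
470–530 nm), with `G` an instrument calibration constant.  GP ranges from
−1 (liquid-crystalline, fluid) to +1 (gel, ordered) and, being ratiometric,
is independent of excitation intensity and probe concentration.

The package implements, for clinicians and imaging scientists evaluating
fluidity-based T1DM staging:

* **`gp_imaging`** — background subtraction, debris-filtered cell
  segmentation, per-pixel GP maps and masked summaries;
* **`synthetic_cohort`** — a seeded simulator of the study design: annular
  membrane footprints with class-dependent fluid-domain nucleation, Poisson
  photon noise, and class-conditional clinical covariates (HbA1c matched
  between G1 and G2, lipids rising with stage, the < 15 / ≥ 15 year duration
  split, MDI vs CSII insulin therapy);
* **`texture_features`** — per-channel descriptors: first-order moments,
  gray-level co-occurrence (GLCM) measures, and rotation-invariant
  co-occurrence local binary patterns (RICLBP);
* **`dss_classifier`** — the decision-support system (DSS): per channel
  standardize → PCA (99 % variance) → SVM per image, majority over the
  z-stack, weighted-voting fusion of the two channels, evaluated
  leave-one-person-out (LOPO); plus Gaussian Bayesian baselines on scalar
  HbA1c and mean GP;
* **`cohort_statistics`** — Welch group tests, coefficients of variation,
  control-normalized regressions against disease duration and lipids, and
  the insulin-therapy separation summary;
* **`cli`** — `rbcfluidity simulate | gp | features | classify | baselines |
  report | all`.

## Worked example

The numbered drivers under `analysis/` run the whole study on a simulated
26-patient cohort (8 G0 / 11 G1 / 7 G2, ten 256×256 image pairs each):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_gp_maps.py
python analysis/03_extract_features.py
python analysis/04_run_dss.py
python analysis/05_cohort_statistics.py
```

Driver 02 prints the group-level GP distribution shift (stack-mean GP per
patient, averaged within group):

```
         mean     std
group
G0     0.4581  0.0020
G1     0.2030  0.0434
G2    -0.2052  0.0404
```

Mean GP falls and its spread grows from G0 to G2 — the membrane fluidifies
and phase-separates as disease progresses.  Driver 04 then compares the
three classifiers under LOPO:

```
method           accuracy
HbA1c (Bayes)        0.69
mean GP (Bayes)      1.00
DSS                  1.00
```

HbA1c separates controls from diabetics but not G1 from G2 (the simulated
groups are matched for metabolic control), while GP-based classification
stages all three groups.  Driver 05 reports the duration trend of the
control-normalized quantities: GP/GP₀ falls at −0.053 y⁻¹ with R² = 0.85,
whereas HbA1c/HbA1c₀ shows R² = 0.14 — the fluidity readout tracks disease
duration far more tightly than glycated hemoglobin.

The same chain is available on any cohort directory through the CLI:

```sh
rbcfluidity simulate -o cohort_dir --seed 42
rbcfluidity all cohort_dir -o results_dir
```

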