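# Methods

## Overview

scintira models a quantitative bone-scintigraphy study of rheumatoid
arthritis end to end: a generative patient model produces per-joint
clinical status and true joint-to-bone uptake ratios; a phantom renderer
turns each patient into planar count images; the quantification stage
recovers uptake ratios from those images; clinical scoring computes
DAS28-ESR and activity categories; and the diagnostics stage evaluates
the imaging markers. This note documents the model, its calibration, the
numerical conventions, and what the synthetic conditions do and do not
establish about real data.

## Generative patient model

Each RA patient draws a latent severity class (low / moderate / high)
from mixture proportions 17:34:14 over 65 — the observed
disease-activity split. Conditional on class:

- **Joint status.** Every joint independently becomes tender-only,
  swollen-only, both, or non-affected. The base per-joint probabilities
  are the observed joint-status fractions among 1817 analyzable joints
  (9.58% / 2.42% / 11.01%), multiplied by a class-specific prevalence
  scale so that the expected number of active joints per class matches
  the class's summed-score target (see Calibration).
- **True uptake ratio.** Drawn from a status-conditional normal
  (non-affected 1.12 +/- 0.49, tender 1.68 +/- 0.81, swollen
  2.07 +/- 0.92, both 1.94 +/- 1.16) truncated below at 0.05 by
  rejection sampling (the smallest observed ratio was 0.10; untruncated
  normals would produce negative uptake). Class-specific mean shifts are
  solved so the *truncated* class means hit the per-stratum active and
  non-affected ratio means (1.96/1.82/1.65 and 1.38/1.12/0.99). A
  patient-level offset u ~ N(0, 0.15) is added to all of a patient's
  ratio means, modelling global between-patient uptake variability
  (tracer dose, clearance, body habitus); it widens the summed-score
  distribution without moving class means.
- **ESR and global assessment.** The latent joint burden
  z = standardized(active DAS28-joint count + mean active ratio) drives
  ESR log-linearly, ESR = clip(exp(a + shift_class + 0.25 z + eps), 2, 120)
  with eps ~ N(0, 0.22), and the 0-100 global assessment linearly,
  GH = clip(c + shift_class + 6 z + eps', 0, 100) with eps' ~ N(0, 7).
  Standardization constants are population moments computed during
  calibration.
- **Stratum label.** DAS28-ESR is computed from the drawn TJC/SJC/ESR/GH
  with the standard coefficients (0.56, 0.28, 0.70, 0.014) and the
  recorded stratum is the thresholded category (<= 3.2 / <= 5.1 / > 5.1).
  Patients are classified, not assigned — the latent class and the
  recorded stratum can disagree near the boundaries, as in a real study.

The osteoarthritis comparison cohort uses one class, affected prevalence
26/420, affected ratios 1.94 +/- 0.90 and non-affected 0.88 +/- 0.35,
with a smaller patient effect (SD 0.08) and no DAS28 scoring.

Arthroplasty exclusions flag large joints on distinct patients; the
default multiset (knee, knee, elbow) reproduces the study composition,
giving 65 x 28 - 3 = 1817 analyzable joints and the per-area
denominators 130/129/130/650/650/128.

## Calibration

All free constants live in `src/scintira/data/default_config.yaml`,
generated deterministically by `scintira.calibration`:

1. Ratio-mean shifts per class are found in closed form by inverting the
   truncated-normal mean (Brent root finding on the scipy `truncnorm`
   mean).
2. Per-class active-joint prevalence starts from the linear relation
   E[sum] = k * mu_active + (28 - k) * mu_nonaffected and is then refined
   by a fixed-seed Monte-Carlo loop (30 000 patients per class, four
   damped iterations, common random numbers) so that the **classified**
   strata — not the latent classes — hit the summed-score targets
   44.8 / 35.4 / 30.1. Targeting classified strata absorbs the small
   cross-boundary contamination (a few percent of moderate-class
   patients exceed DAS28 5.1 and would otherwise dilute the high-stratum
   mean).
3. ESR/GH intercepts per class are set so each class's expected
   DAS28-ESR sits at its center (2.5 / 4.05 / 6.4, chosen to reproduce
   the observed DAS28 median 4.02 and range 1.61-6.90 while keeping the
   classes well inside their bands); GH class centers 28 / 43 / 70
   reproduce the observed GH median 45 and range 20-90.
4. The coupling noise levels (0.22 log-ESR, 7 GH points) and the patient
   effect SD (0.15) jointly set the within-class DAS28 spread and the
   summed-score spread. They were calibrated so that (a) threshold
   classification is nearly consistent with the latent class and (b) the
   Pearson correlation between the summed score and DAS28-ESR on
   65-patient cohorts falls inside the published interval
   [0.585, 0.824] in well over 80% of seeds, centred near 0.74.

One tension is accepted deliberately: the per-stratum prevalences
implied by the stratified summed-score means give an expected active
fraction of ~22.3%, while the pooled count implies 23.0%. Both cannot
hold under this mixture; the stratified means win because they carry the
tighter downstream checks, and the active-fraction test allows +/- 1.5
percentage points.

## Phantom rendering

Views: anterior whole body (220 x 80 px, 6 mm pixels) plus four
extremity spots and a posterior pelvis spot (96 x 96 px, 2.4 mm). The
whole-body view holds a schematic stick skeleton at the bone count level
(default 100 counts/px) over soft-tissue background (10 counts/px);
only relative levels matter for ratios. For each visible, non-excluded
joint the background inside a disk of radius 2r+1 around the landmark is
cleared and a Gaussian hotspot (sigma 1.8 px) is added with its
amplitude normalized so that the mean over the nominal ROI divided by
the bone level equals the true ratio exactly. Poisson noise (default on)
replaces mean counts with counting realizations; images are 16-bit
unsigned TIFFs with JSON sidecars. Excluded joints render as plain
background. Landmarks are spaced so neighbouring search windows do not
overlap; hotspot tails at neighbouring ROIs are < 0.1%.

At the default count levels an ROI-mean ratio carries ~1-1.5% relative
noise; the noise-free render -> quantify round trip is exact to the
integer rounding of the stored counts (< 0.5%).

## Quantification conventions

- Coordinates are 0-based (row, col); pixel centers at integers; a pixel
  belongs to a circular ROI if its center is within the radius,
  inclusive. ROI radii: 3 px on the whole-body view, 4 px on spots
  (config-exposed; the study's original software did not publish its ROI
  geometry, so this is this package's choice).
- ROI centers are refined to the count-weighted centroid of the disk of
  radius 2r around the atlas landmark, falling back to the landmark when
  the neighbourhood is empty. The centroid is **snapped to the pixel
  grid**: its sub-pixel jitter under counting noise is far below half a
  pixel, and measuring at a noise-driven fractional center selects
  upward-fluctuated pixels and biases ratios high by several percent
  (measured +0.04-0.07 at default counts); snapping removes the bias
  while still recovering genuine whole-pixel landmark offsets.
- Reference uptake is the average of two 15 x 3 px rectangles centred at
  the midpoint of the hip and knee landmarks (mid-femoral shaft) on the
  whole-body view. A non-positive reference mean is an error, never a
  silent zero.
- The summed 28-joint score imputes an excluded joint with its
  contralateral partner's ratio; if both partners are excluded it uses
  the patient's mean over the remaining DAS28 joints; fewer than 14
  measurable DAS28 joints makes the profile unusable. (How the original
  study summed the three affected patients is unstated; contralateral
  imputation is this package's choice.)
- Overlapping ROIs of adjacent finger joints are measured independently;
  no count sharing or deconvolution.

## Diagnostics conventions

- Decision rule: score >= cutoff is test-positive (higher uptake =
  disease).
- The empirical ROC is traced over unique observed scores with a +inf
  sentinel; the trapezoidal AUC equals the tie-corrected Mann-Whitney
  probability (ties 1/2) — property-tested against brute-force pair
  counting.
- Youden cut-off maximizes J = sens + spec - 1; ties break toward higher
  sensitivity, then the lower threshold. Note that for continuous group
  distributions the Youden optimum sits at the density crossing of the
  two classes; for the published status-moment mixture that crossing is
  ~1.70, noticeably above the 1.07 cut-off observed on the real
  (non-normal) data — a reminder that normal-moment simulations
  reproduce AUCs well but not necessarily cut-off locations.
- Binomial proportions carry exact Clopper-Pearson 95% intervals
  (statsmodels `proportion_confint(method="beta")`); undefined PPV/NPV
  (empty denominator) are reported as undefined, never 0.
- AUC intervals: percentile bootstrap, stratified by class (B = 2000 by
  default), deterministic under a seed.
- Predictive values reconstructed from published rates round
  sens * n_pos and spec * n_neg to the nearest integer, half away from
  zero — the convention required to reproduce printed predictive values
  exactly.
- Group comparisons are gated on Levene's test at alpha = 0.05:
  homogeneous variances use one-way ANOVA with Scheffe post-hoc, else
  Kruskal-Wallis with Dunn post-hoc (hand-implemented from the standard
  formulas; pairwise p-values unadjusted beyond the tests' built-in
  handling). Groups with fewer than 3 values are rejected.
- Pearson correlations report Fisher-z 95% intervals; degenerate inputs
  (zero variance, n < 4) are errors.
- Report percentages round to 1 decimal, half away from zero.

## Problem sizes used in tests

The calibration properties run the full pipeline (generate, render with
Poisson noise, quantify the 28 DAS28 joints, score) on 100 seeds of the
default 65-patient conditions; the bootstrap-coverage check uses 200
simulations of n = 200 with B = 400; moment-level AUC simulations use
60 seeds (joint level) and 200 seeds (patient level). These sizes give
Monte-Carlo errors comfortably below the tolerances they are tested at.

## What the synthetic conditions do and do not show

The generator reproduces the published group moments, stratum structure,
correlation strength and classification mix, and the phantom guarantees
a known ground truth for the quantification contract. It does **not**
emulate: anatomical shape variation, joint deformity or overlap, scatter
/ attenuation / collimator physics, inter-camera differences, partial
volume at small joints, or non-normal heavy-tailed uptake distributions
(the real cut-off discrepancy above is one visible consequence). Passing
the suite therefore validates the *analysis machinery and its
statistical behaviour under the stated model*, not clinical performance
on real scans. The per-joint-area prevalence of tenderness/swelling is
uniform by default (only totals were published); a per-area table can be
supplied in the config.
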