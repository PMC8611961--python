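# scintira

Quantitative planar bone-scintigraphy analysis for rheumatoid arthritis
(RA), built around a fully synthetic, statistically calibrated phantom
cohort so that every stage of the pipeline is testable without patient
data.

## The problem

On a Tc-99m MDP bone scan, inflamed joints take up more tracer than
quiet ones, but visual reading of planar images is subjective.  A
quantitative alternative measures, for each joint *j*, the
**joint uptake ratio**

```
JUR_j = mean counts in the joint ROI / mean counts in a reference bone region
```

(the reference here: bilateral mid-femoral-shaft rectangles on the
anterior whole-body view).  Summing the ratios over the 28 joints of the
DAS28 set (bilateral shoulders, elbows, wrists, knees, 10 MCP, 2 thumb
IP, 8 proximal IP) gives a per-patient imaging score, the **summed
28-joint uptake ratio**, which tracks clinical disease activity measured
by

```
DAS28-ESR = 0.56*sqrt(TJC28) + 0.28*sqrt(SJC28) + 0.70*ln(ESR) + 0.014*GH
```

with activity categories low (<= 3.2), moderate (3.2, 5.1], high (> 5.1).
The package evaluates both markers the way a diagnostic-accuracy study
would: empirical ROC curves and AUC (tie-corrected Mann-Whitney),
Youden-index cut-offs, sensitivity/specificity/PPV/NPV with exact
Clopper-Pearson intervals, stratified-bootstrap AUC intervals,
Levene-gated ANOVA/Scheffe vs Kruskal-Wallis/Dunn group comparisons, and
Pearson correlations with Fisher-z intervals.

Because no public dataset of this kind exists, the package ships a
**synthetic data module**: a cohort generator whose status-conditional
uptake-ratio distributions, activity-stratum structure and ESR/global-
assessment coupling are calibrated to the group moments reported for a
65-patient RA cohort (plus a 15-patient osteoarthritis comparison
group), and a gamma-camera phantom renderer that turns each patient into
six 16-bit planar count images (anterior whole body, both hands, both
feet, posterior pelvis) with Poisson counting noise.  Rendering is
normalized so that, noise-free, quantification recovers every true ratio
exactly; that round trip is the module's ground-truth contract.

## Worked example

```python
from scintira import default_study_config, run_study

report = run_study(default_study_config().reseeded(42))
audit = report["audit"]
total = report["joint_diagnostics"]["total"]
print(audit["n_analyzed_joints"], audit["n_active_joints"])
print(total["auc"], total["cutoff"])
print(report["correlations"]["summed_vs_das28"]["r"])
```

With seed 42 this prints a cohort of **1817 analyzable joints** (65
patients x 28 joints minus 3 arthroplasty exclusions), of which 380 are
clinically active; the joint uptake ratio discriminates active from
non-affected joints with **AUC 0.754** at a Youden cut-off of 1.73, the
summed score detects high disease activity with **AUC 0.943**, and the
summed score correlates with DAS28-ESR at **r = 0.780** (95% CI
0.662-0.860).  Per-stratum summed-score means for this seed are 44.7
(high, n=16), 34.5 (moderate, n=28) and 29.9 (low, n=21), with 25.2 in
the osteoarthritis comparison group.  Exact values vary seed to seed;
the calibration tests pin their distribution across 100 seeds.

The same run is available from the shell:

```
scintira run-all --seed 42 --out out/
scintira dump-config          # the calibrated default configuration
scintira simulate --seed 1 --out phantom/   # TIFF scan sets + truth CSVs
```

`out/report.json` carries the full report (baseline summary, per-area
detection table, stratum comparisons, correlations, audit trail and
config hash); CSV siblings mirror each table.

## Layout

- `scintira.atlas` — the 64-joint / 14-area landmark map with the DAS28 subset
- `scintira.cohort`, `scintira.phantom`, `scintira.calibration` — synthetic cohorts and phantom rendering
- `scintira.quantify` — ROI localization, reference uptake, ratios, summed score
- `scintira.clinical` — active-joint labels, DAS28-ESR, activity categories
- `scintira.diagnostics` — ROC/AUC, Youden, bootstrap, predictive values, group tests, correlation
- `scintira.pipeline`, `scintira.cli` — orchestration, report export, CLI

See `docs/methods.md` for the generative model, its calibration and its
limitations.
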