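# Methods

`serumftir` implements a serum ATR-FTIR data-mining pathway for
digestive-tract cancer (DTC) triage: a forward model of serum mid-infrared
spectra, spectral conditioning with second-derivative (SD-IR) computation,
band-level feature engineering (absorbance *and* wavenumber shift), and a
chemometrics / machine-learning layer (PCA, HCA, PLS-DA with VIP, SMOTE
balancing, an eight-method classifier panel under repeated stratified
cross-validation).  Because no public serum dataset accompanies the study
design this package follows, the synthetic cohort generator is a first-class,
tested component: it defines the conditions under which every downstream
claim is evaluated.

## Forward model of a serum spectrum

A spectrum on the grid nu in [900, 4000] cm^-1 (2 cm^-1 spacing, i.e. the
4 cm^-1 instrument resolution ~2x oversampled) is

    A(nu) = sum_b  amp_b * f_b^s * G(nu; c_b + s*delta_b, sigma_b)
            + (a + b*nu)  [+ water(nu)]  + eps,   eps ~ N(0, noise_sigma^2)

where `G` is a unit-height Gaussian (a pseudo-Voigt variant is available via
config), `c_b`/`sigma_b`/`amp_b` are the control-group band parameters,
and each disease group contributes per-band effects: a signed center shift
`delta_b` (positive = blue-shift) and an amplitude factor `f_b`.  The stage
scale `s` in [0, 1] enters as `f^s` and `s*delta`, so `s = 0` reproduces the
control model *exactly* — the "control" stage of a patient is
distributionally identical to a healthy control.

Band parameters live in `data/band_table_v1.tsv`: eleven serum bands
(amide A/I/II/III, lipid CH stretches and bends, carboxylate,
nucleic-acid phosphate, carbohydrate modes) with control centers and
amide-I-anchored relative absorbances, plus four glycoprotein-linked marker
bands near 1508, 1040, 1117 and 986 cm^-1 whose control centers are derived
from the tabulated DTC positions minus their reported blue-shifts (1.8 and
~3 cm^-1).  The clinically linked C=O marker near 1638 cm^-1 is the amide I
band itself (modelled through the amide I row, with the liver-cancer
amplitude bumped by its reported +0.02%), not a separate overlapping
Gaussian — duplicating it would corrupt the amide-I anchor that defines
relative absorbance.

**Band widths.** Sigma defaults range 5–25 cm^-1: broad amide A (25) and
amide I (14), mid-width fingerprint bands (8–10), and deliberately narrow
values (5–8) for the closely spaced pairs (2925.8/2954.8, 1091.6/1116.4,
1506.3/1546.9 cm^-1).  The narrow values are required for detection
fidelity: with wider bands the SD minima of ~25 cm^-1-separated neighbors
pull each other by several tenths of a cm^-1, which would be comparable to
the 1.8–3 cm^-1 group shifts the pipeline is supposed to resolve.  All
widths are config, not constants.

**Stage effect scales** default to {1: 0.5, 2: 1.0, 3: 0.3, 4: 0.0}
(nonspecific symptom, cancer, postoperative, control).  The study design
names the stages but quantifies no stage effect sizes; these values are an
invented, documented grading and are fully tunable.

**Noise and baseline.** White noise sigma = 0.002 a.u. against an amide I
amplitude of 1, on a linear drift (0.02 + 1e-5*nu).  The water background
(O-H stretch at 3346, H-O-H bend at 1637 cm^-1) is excluded from cohort
spectra — they represent the post-differential (wet minus dry) serum
signal — and enters only through `generate_wet_dry_pair`, whose round trip
through `differential_spectrum` recovers it exactly.

**Cohort plan.** The default cohort reproduces the study head count: 252
serum samples, 210 patients (25 liver / 68 gastric / 73 colorectal cancer /
44 controls).  The published counts are mutually inconsistent (252 − 44
controls = 208 DTC samples cannot be reached with two-to-three specimens for
each of 166 DTC patients), so the default plan gives every patient one
specimen at a stage cycling 1→2→3 and a second specimen (at a distinct
stage) to the 25 LC patients and the first 17 GC patients: 210 + 42 = 252.
The plan is deterministic and recorded in the manifest.

## Spectral conditioning

Per spectrum: two-anchor linear baseline correction (line through the
minimum absorbance in the leading and trailing 2% of the grid — a documented
stand-in for the proprietary "linear automatic baseline" of instrument
software), Savitzky–Golay smoothing, clipping to the 900–3500 cm^-1 working
range, vector normalization (unit Euclidean norm; min-max optional), and the
Savitzky–Golay second derivative with respect to wavenumber.

SG windows default to 7 points (order 3) for smoothing and 9 points
(order 3) for the second derivative.  Longer windows (e.g. 11/13) were
rejected after measurement: the combined kernel support (~±22 cm^-1) lets
neighboring bands ~25 cm^-1 apart displace each other's SD minima by up to
1.3 cm^-1 on noiseless data, swamping the shifts of interest; the short
windows keep every noiseless preset band within 0.05 cm^-1 of truth while
still suppressing the default noise level.  The SG edge half-windows are
polynomial extrapolation; band search never reaches them because all
reference bands sit well inside the working range.

## Band features

Each reference band is located as the deepest interior local minimum of the
SD-IR within a per-band search window (default half-width 8 cm^-1, widened
to 25 for amide A and 12 for nu_s(PO2-), whose group shifts exceed 8), then
refined by a 3-point parabola — necessary because the tabulated shifts
(1.8–7.6 cm^-1, amide A up to 19.9) must be resolved on a 2 cm^-1 grid.
Amplitudes at off-grid positions are read through a local parabola as well
(linear interpolation under-reads a curved band top by up to f''h²/8).

* **Relative absorbance** (band reports): baseline-corrected raw amplitude
  divided by the amide I amplitude, so amide I ≡ 1 — the tabular convention.
* **Classification features**: amplitudes from the vector-normalized
  spectrum ("raw" source) or SD minimum depths ("sd" source).  Anchoring to
  amide I is *not* used here, because it would make every amide I column
  constant and leave the 1600–1700 cm^-1 subrange featureless.
* **Shifts**: detected position minus the per-band mean control position
  (blue-shift positive).  Grids are laid out so the 1000 cm^-1 reference
  point is a node, making positions comparable across samples; a config
  switch (`shift_reference="reference_point"`) measures positions from that
  anchor instead.
* **Feature sets**: `1D` (one absorbance column per band), `2D`
  (absorbance + shift), `combined` (raw and SD absorbance blocks).
  Undetected bands are imputed with the cohort median and flagged in a
  boolean companion column, so classifiers can exploit missingness and
  cohort sizes stay fixed.

Per-band one-way ANOVA across groups (scipy) yields F, p and the
conventional star codes (0.05 / 0.01 / 0.001); zero within-group variance is
flagged degenerate with no star rather than reporting an infinite F.

## Chemometrics

PLS-DA is NIPALS PLS2 on column-centered X against a centered one-hot class
matrix, with per-component X deflation, three latent variables by default,
and the argmax-of-Y-hat decision rule.  X autoscaling is on by default —
appropriate for matrices mixing absorbance and cm^-1-shift units — and off
is available for pure spectral matrices.  Constant columns are dropped with
a warning.  Reported quantities: R²Y (fit), Q² = 1 − PRESS/SS(Y) under
stratified CV, and VIP scores, which satisfy sum(VIP²) = p exactly.  At full
rank PLS-DA reproduces the least-squares fit of Y on X, which also makes the
MVLR panel member its algebraic special case.  PCA (sklearn SVD), HCA
(scipy, Euclidean, non-decreasing merge heights for standard linkages) and
one-vs-rest ROC/AUC (trapezoidal = pair-counting with half-weight ties)
round out the layer.  Subrange classification restricts features to bands
whose nominal centers fall in 2800–3300, 1600–1700, 1400–1500 or
1200–1400 cm^-1 and clamps the LV count to the surviving feature count.

## Staging machine learning

The staging task within one cancer group is 4-class (stages 1–3 of that
group plus the shared control pool as class 4) and imbalanced, so SMOTE
(in-package: k = 5 Euclidean minority neighbors, uniform interpolation on
the connecting segment, k clamped with a warning for tiny classes, singleton
classes rejected) equalizes classes to the majority size.  SMOTE and feature
standardization are fit **inside training folds only**; a deliberate
`leak_preprocessing` ablation mode fits them on the full data first and is
covered by a regression test showing it inflates accuracy on null data.

The classifier panel holds exactly eight methods: the in-package BP network
(one tanh hidden layer, default 2x-features units, softmax cross-entropy,
full-batch gradient descent at rate 0.05 for up to 2000 epochs with
plateau early-stopping, abort on non-finite loss or weights) and PLS-DA,
MVLR (least-squares one-hot + argmax), and KNN / random forest / decision
tree / logistic regression / SVM delegated to scikit-learn behind the same
fit/predict contract.  Evaluation is repeated stratified 10-fold CV
(5 repeats by default; accuracy averaged over folds and repeats, sd over
repeat means, confusion matrices accumulated over all held-out
predictions); the fold count drops with a warning when the smallest class
is smaller than the fold count.  An optional PCA pre-reduction
(retained variance 0.99) is available but off by default.  A 70/30 holdout
is not separately implemented; repeated stratified k-fold is the single
evaluation protocol.

## What the generator does and does not emulate

The synthetic cohort reproduces band positions, group shifts, relative
absorbances, stage grading, cohort size, baseline drift, water background
and white noise.  It does **not** emulate: non-Gaussian/asymmetric line
shapes and overlapping sub-band structure (no Fourier self-deconvolution is
attempted), correlated (pink) noise, scattering artifacts, atmospheric CO2
/ water-vapor lines, batch effects, biological within-group covariance
beyond i.i.d. noise, or ATR penetration-depth physics.  Consequently,
passing classification tests demonstrates that the pipeline extracts and
uses the engineered band-level signal correctly — not that comparable
accuracies would be reached on real serum data, where group effects are
entangled with far richer variability.  The published real-data figures
(e.g. R²Y 0.991/0.977/0.997, AUC ~0.97–0.99, Table-style accuracy grids)
are therefore *not* reproduction targets; the synthetic analogs are.

## Numerical choices and degenerate inputs

* Parabolic refinement offsets are clipped to ±1 grid step; flat SD
  segments yield `detected = False`.
* Baseline correction is idempotent by construction (anchor minima of a
  corrected spectrum are the anchors themselves).
* All-zero spectra are rejected by normalization; empty cohorts, missing
  control groups (when shifts are requested), unknown methods/modes raise
  `ValueError` before any computation.
* PLS-DA ties in the argmax resolve to the first class in class order.
* Every stochastic component (generator, SMOTE, CV shuffling, BP init)
  draws from an explicit seed; cohorts are a pure function of their config.

## Problem sizes used by the test suite

The full 252-sample cohort backs the acceptance-style checks (staging
accuracy, group separation, VIP ranking); property checks that need many
replicates run on reduced cohorts (9–12 patients per group), 3-fold CV,
2–3 seeds per setting, and shortened BP training, sizes chosen to keep the
default `pytest` run under a minute while leaving every assertion
scale-honest (no threshold was loosened to accommodate a smaller run).
`scripts/acceptance.py` runs the full-size protocol (10-fold, 5 repeats).
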