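# Methods

## The model system

`epom` simulates how acute myocardial ischemia reshapes the ECG, one
virtual patient at a time.  A "patient" is a variant of the ten
Tusscher–Panfilov 2006 (TP06) human ventricular myocyte model, epicardial
parameterization, obtained by scaling its twelve maximal conductances and
peak currents (G_Na, G_CaL, G_Kr, G_Ks, G_K1, G_to, G_pK, G_pCa, G_bNa,
G_bCa, P_NaK, k_NaCa) by independent multipliers in [0, 2].  The all-ones
multiplier set reproduces the published baseline; we verified the
implementation against the published epicardial action-potential duration
at a 1000 ms cycle length (≈301 ms; we measure 303 ms at our solver
settings) and cross-checked the fixed-step kernel against an adaptive
stiff integration (LSODA, rtol 1e-3 / atol 1e-6) — the two agree on
APD90 within 1 ms.

### Ischemia overlay

Acute ischemia enters the cell model through three graded components:

* **hyperkalemia** — extracellular potassium `Ko` is raised; it enters
  every K-dependent reversal potential and current, including the
  `sqrt(Ko/5.4)` conductance factor of I_K1 and I_Kr inherited from the
  2004 parent formulation (the 2006 reference source hard-codes
  Ko = 5.4 mM, which hides this factor);
* **acidosis** — I_Na and I_CaL are multiplied by `f_inhib` ≤ 1;
* **hypoxia** — an ATP-sensitive potassium current
  `I_KATP = f_katp · G_KATP · (Ko/Ko_n)^0.24 · (V − E_K)` with
  G_KATP = 0.064 mS/µF and Ko_n = 5.4 mM.

Severity presets: control (0, 1, 5.4 mM), mild (0.1, 0.875, 6.25 mM),
severe (0.2, 0.75, 9.0 mM); mild is the midpoint between control and
severe in all three parameters.

## Numerical schemes

Two integration paths share one set of model equations:

* **reference** — the full right-hand side in NumPy, integrated by LSODA
  at rtol 1e-3 / atol 1e-6 (used for validation and available through
  `pace_cell(..., solver="lsoda")`);
* **fast default** — a fixed-step Rush–Larsen scheme (numba): the eleven
  voltage gates advance exactly for frozen V with pre-tabulated steady
  states and decay factors on a 0.02 mV grid; V, concentrations and the
  calcium subsystem use forward Euler; the RyR adaptation variable and
  the Ca-dependent gate use exact exponential updates.  Pre-pacing runs
  at dt = 0.1 ms and the saved beat at dt = 0.02 ms, resampled to a
  uniform 0.1 ms output grid.  Calcium buffering uses the
  rapid-buffering derivative form, the ODE-limit equivalent of the
  analytic-buffer stepping of the original source.

The 1D fiber solves the monodomain cable equation by the method of
lines: second-order central differences, no-flux boundaries, Lie
splitting of reaction (Rush–Larsen) and explicit diffusion, dt = 0.02 ms
by default (CFL-checked), field saved every 0.5 ms.  Geometry: 2 cm, 101
nodes at 0.02 cm.  The diffusivity is 1.171e-3 **cm²/ms** — stated in
per-millisecond units deliberately; the same digits in cm²/s would give
~2 cm/s conduction, thirty-fold below the ~60 cm/s of healthy human
ventricular tissue.  Refining the grid to 0.01 cm changes the baseline
conduction velocity by under 5%.

Single-cell pacing can optionally verify convergence after pre-pacing
(`check_alternans`): five further beats are recorded and a beat-to-beat
APD90 swing above 1 ms marks the trace non-convergent in its metadata —
flagged, never fatal, since APD alternans at short cycle lengths is a
real behavior of the model, not a solver failure.

The stimulus is −52 A/F for 1 ms (the conventional TP06 suprathreshold
current), applied to the cell or to the first three cable nodes each
cycle.  It is configurable; stimulated-footprint width matters when the
node spacing changes (the tests hold the physical footprint at 0.06 cm).

## Populations

The control population follows the calibration recipe: Latin Hypercube
Sampling of the twelve multipliers on [0, 2] (via `scipy.stats.qmc`, one
sample per marginal stratum), 200 pre-pacing beats at cycle lengths 430
and 600 ms, last beat saved; a model is excluded if APA < 0,
RMP > −64 mV or upstroke time > 10 ms (reasons reported in that order),
and calibrated if APD90 falls inside the closed windows [170, 240] ms at
CL 430 and [195, 290] ms at CL 600.  The slower cycle length is paced
first and failing models skip the second — acceptance is unchanged, only
cost.  At 300–2100 samples we measure acceptance fractions of 0.16–0.21
(convention-dependent: ~0.20 under `apa_fraction`, ~0.16–0.21 under
`repol90`).

### APD90 convention

The source description — "the time when the transmembrane potential was
at 10% of the APA" — admits two readings, and they differ by ~80 ms on
this model because the TP06 terminal repolarization is slow:

* `repol90` (default): V has recovered 90% of the peak-to-rest
  excursion.  Under this reading the calibrated population statistics
  and the pseudo-ECG QT interval are mutually consistent, so it is the
  default everywhere.
* `apa_fraction`: V crosses 10% of the zero-referenced amplitude.  Under
  this reading (and only this one) the baseline model itself sits inside
  both calibration windows.  Available via `convention="apa_fraction"`.

Both are exposed; the choice is a genuine ambiguity of the source
description and the package pins one while keeping the other testable.

## Pseudo-ECG and biomarkers

The extracellular potential at a point probe 2 cm beyond the fiber end
(l′ = 4 cm) is `phi_e = A ∫ (−∂V/∂l) ∂/∂l[1/|l−l′|] dl` over nodes 15–85
(0-based, inclusive), central differences plus trapezoidal quadrature,
A = 1.  The sign convention makes a depolarization front travelling
toward the probe deflect phi_e upward (positive QRS).  Because the fiber
is homogeneous, repolarization follows the activation direction and the
T wave is **negative** at the probe — the homogeneous-fiber result of
the classical pseudo-ECG literature.  Ischemia gradings therefore track
the T-wave *magnitude*.

Biomarkers: QRS duration, QT interval, ST deviation (phi_e at the
midpoint between QRS end and T onset, raw, no DC correction), T
duration, and the signed QRS/T extremum amplitudes.  QRS boundaries are
the 10%-of-peak crossings of |phi_e|; the QRS search window ends 20 ms
after the last windowed cell activates (slow severe fibers have QRS
complexes well beyond 100 ms).  T-wave boundaries default to the tangent
method — steepest flank extrapolated to the local baseline — because the
slow plateau-decline drift under the T wave makes a fixed 10% threshold
date the onset tens of milliseconds early on long-plateau models; the
literal threshold rule remains available (`t_method="threshold"`).  All
boundaries are amplitude-scale invariant; the two amplitude biomarkers
scale linearly.

Conduction velocity is (1.6 − 0.4) cm over the difference in activation
times (first crossing of 0 mV) at those positions.

Ratios of change divide each ischemic biomarker by the same model's
control value; a control biomarker whose magnitude is below 1e-6 of the
control QRS amplitude is a degenerate denominator and the signed
difference is substituted (recorded per model).

Under severe ischemia some calibrated models genuinely block (sodium
availability h·j ≈ 0.07 at the hyperkalemic resting potential, times
f_inhib, times a weak G_Na multiplier).  Blocked or undelineatable
models are dropped from the feature table with a logged reason and
replaced by the next calibrated model, so each class keeps its full
complement; roughly half the calibrated models conduct under the severe
preset.

## Classifiers

Three fully-connected perceptrons with ReLU hidden units and sigmoid
outputs, written from scratch (NumPy):

* ANN1 — six biomarker magnitudes → 3-class one-hot (control/mild/severe);
* ANN21 — magnitudes → binary control vs ischemic;
* ANN22 — six ratio features → binary mild vs severe.

Training: full-batch gradient descent on binary cross-entropy (summed
over outputs, averaged over examples) plus an L2 weight-decay penalty
(default 1e-4), fixed learning rates 0.005 / 0.01 / 0.1 for
ANN1 / ANN21 / ANN22 (the multi-class rate 20× below the grader's, and
half the detector's), early stop on a relative cost plateau of 1e-8 over
500 epochs.  Protocol: stratified 75/25 train/evaluation split, 10-fold
cross-validation on the training split with per-fold re-initialization,
selection by mean validation F1 (ties toward fewer parameters).  The
weights carried to the evaluation split are the full-training-split
refit of the selected architecture, guarded by a training-split F1
comparison against the best fold's weights (full-batch refits at the
severity grader's high learning rate occasionally diverge; the guard
falls back to the best fold's weights in that case, and no evaluation
example ever influences the choice).  Feature z-scoring is fitted on
the training split only.  The default architecture grid is
1–6 hidden layers × 2–10 units; the `"best"` grid trains only the three
known optima (5/7, 5/8, 4/4).

Weights initialize Glorot-scaled uniform with zero biases.  A fixed
small range (e.g. ±0.1) was tried first and collapses the forward signal
through the 4–6-layer stacks of the grid (per-layer gain ≈ 0.15), leaving
the networks at the class prior indefinitely; fan-scaled initialization
is the minimal change that keeps every grid depth trainable.

Evaluation: decisions at 0.5 (binary) or arg-max (multi-class);
Se = TP/(TP+FN), PPV = TP/(TP+FP), F1 their harmonic mean, multi-class
metrics macro-averaged.  The cascade feeds evaluation rows through ANN21
and routes ischemic-flagged rows to ANN22.  A regularized logistic
regression (scikit-learn) on the same splits provides the linear
baseline.  Garson importance column-normalizes each layer's |W|,
multiplies through the stack, sums over outputs and renormalizes; for
one hidden layer this is the classic tableau, and it always returns a
nonnegative vector summing to 1.

## Scaled study conditions

The full study conditions are 10000 LHS samples, cold-start 30-beat
cables at dt = 0.02 ms, and the full architecture grid.  The package's
reduced study — used by the test suite and `scripts/acceptance.py` —
runs 2000–2100 samples (~350 calibrated models), carries 150 models per
class into 3-beat warm-started cables at dt = 0.05 ms (warm start =
cable nodes seeded with the single-cell steady state of the matching
severity), and trains the three known-best architectures for 8000
epochs.  Warm-started 3-beat cables reproduce the cold 30-beat reference
biomarkers to within a few percent on the baseline model (CV 64.8 vs
66.8 cm/s control; identical severity orderings), and the population
statistics at this scale match the full-scale means well inside one
population SD.

## What the generator does and does not emulate

The synthetic data are *model-generated patients*: conductance
variability spans more-than-physiological ranges and is then clipped by
the experimental calibration windows, which is the point of the
calibrated-population method.  Real ECGs add torso geometry, noise,
heterogeneous (endo/M/epi) wall structure, 3D wavefronts and dynamic
ischemia progression — all deliberately out of scope (the homogeneous
fiber isolates the cellular-level effect).  Passing tests therefore show
that the pipeline reproduces the study's in-silico findings, not that
the classifiers would transfer to clinical recordings.

## Known limitations

* T-wave polarity at the distal probe is negative (homogeneous fiber);
  upright clinical T waves require transmural heterogeneity.
* The printed T-duration statistic of the source is not reproducible
  from its stated threshold rule under either APD convention; our
  tangent-method durations are internally consistent but larger.
* The severe preset blocks conduction in roughly half the calibrated
  models; the severe class is thereby a conducting subset (a selection
  effect the source does not discuss).
* The linear (logistic) baseline is only marginally worse than the
  detector network here: the six delineated biomarkers make
  control-vs-ischemic nearly linearly separable (the QT shift
  dominates), so the advantage of the nonlinear detector shows up in
  single misclassifications, not in a large margin.
* Single cell type (epicardial), single fiber, no ORd model; the cell
  interface is pluggable for future variants.
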