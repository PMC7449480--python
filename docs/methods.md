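# Methods

This note documents the models, conventions and numerical choices
behind `anespk`, in the spirit of a package methods appendix.  It
states no empirical result beyond what the test suite and
`scripts/acceptance.py` compute themselves.

## Problem setting

A depth-of-anesthesia index maps a short EEG/AEP segment to a number
that separates consciousness from unconsciousness.  The pipeline
operates on *data points*: one per (patient, transition event, state),
where a transition event is a loss or return of consciousness (LOC/ROC)
operationalized as failure/resumption of responding to a command.  A
conscious epoch is taken immediately before the last response (for LOC;
mirrored for ROC), an unconscious epoch immediately after the first
failure, and the uncertain interval between the two requests is never
sampled.  With four events per patient this yields at most 8 data
points per patient, e.g. 320 for a 40-patient cohort.

## Synthetic cohort model

The generator exists so every downstream stage has a realistic, fully
labeled input without patient recordings.  It emulates the statistical
structure the analysis assumes — not the biophysics of any particular
device or drug.

**EEG.** Each 10 s, 1 kHz epoch is Gaussian noise spectrally shaped by
a convex mixture of two fixed unit-power shapes: an "unconscious" shape
dominated by delta/theta power with negligible gamma, and a "conscious"
shape with residual delta, an alpha peak near 10 Hz and a beta/gamma
plateau to ~70 Hz.  The mixing weight is

    w = 0.5 ± s_eeg · eeg_effect/2 + patient offset + epoch jitter,

(+ for conscious epochs), clipped to [0, 1].  Amplitude follows the
clinical direction (slow-wave dominated epochs are larger): target SD
is 10 + 5·(1−w) µV.  The band is restricted to 0.5–400 Hz, matching a
typical acquisition band-pass.

**AEP.** Each data point carries a train of stimulus-locked sweeps
(default 256) over a 0–256 ms post-stimulus window: a mid-latency
template of two Gabor-like deflections (positive near 30 ms, negative
near 45 ms; Pa/Nb analogues, ~1.5 µV scale) plus EEG-shaped background
noise of 12 µV SD per sweep.  Unconsciousness attenuates the template
by `aep_amplitude_effect` (default 0.25) and delays it by
`aep_latency_effect` (default 4 ms), scaled by the patient's AEP
sensitivity.

**Between-patient structure.**  Patients receive (i) small additive
offsets on the mixing weight and log AEP amplitude
(`between_patient_sd`, default 0.08) and (ii) independent multiplicative
*sensitivities* of the EEG and AEP state effects
(`patient_sensitivity_sd`, default 0.45, truncated at 0).  The
sensitivities are the deliberate mechanism behind two emulation
targets: patient-wise P_K dispersion of realistic size (±0.1–0.2
around ~0.85–0.9 for good single parameters), and modality
complementarity — because the EEG and AEP sensitivities are drawn
independently, some patients separate well in only one modality, which
is precisely the situation in which a combined index beats either
single-modality index.  Large additive offsets alone would produce the
dispersion but destroy pooled threshold separability (a global
information-gain split cannot undo per-patient shifts), which is not
how usable monitoring parameters behave.

**Defaults as study conditions.**  The default effect sizes
(`eeg_effect` 0.15, AEP effects above) were chosen once so that, on
default cohorts, a good single EEG parameter reaches a patient-wise
P_K around 0.85–0.9 with SD ≈ 0.1–0.2 and the combined index sits a
few points higher — the regime reported by transition studies of this
design.  They were fixed before the acceptance checks were frozen and
are not tuned per test.

**Artifacts.** `inject_artifacts` corrupts a Bernoulli fraction of
epochs with exactly one of: whole-epoch constant replacement (flat
line), a rectangular excursion of 260–400 µV (range), or a triangular
±90 µV swing with 0.5 s ramps (180 µV within any 1 s window — a pure
rate violation that stays inside the measuring range).  The true class
is recorded so detector sensitivity is auditable.

**Reproducibility.** The root seed expands via `SeedSequence.spawn`
into one substream per patient; identical configs give bit-identical
cohorts and any patient prefix is stable under the same seed.

What the generator does **not** emulate: pharmacokinetics, drug- or
device-specific spectra, burst suppression, realistic EMG/ECG/ocular
artifact morphology, non-stationarity within an epoch, correlated sweep
noise, or variable AEP segment lengths (fixed-length windows were
chosen for deterministic testability).  Green tests on synthetic
cohorts therefore demonstrate correctness and sane statistical behavior
of the pipeline, not clinical performance.

## Preprocessing

* **Filtering**: zero-phase forward-backward Butterworth band-pass
  (order 4 per direction), chosen so entropy and latency features are
  not phase-distorted.  Padding is extended to 3 time constants of the
  low cut (the 0.5 Hz edge otherwise leaves multi-second transients).
  The f_high variants {30, 49, 90} Hz reuse the same structure.
* **Artifact rules** (per epoch): constant-amplitude if ≥ 0.1 s of
  bit-identical samples; range if any |x| > 250 µV (peak convention);
  slope if the peak-to-peak excursion within any sliding 1 s window
  exceeds 140 µV.  The window convention makes the stated µV/s unit
  concrete and is robust to sampling jitter.  An epoch with any reason
  is excluded, and the exclusion removes the whole data point.
* **AEP pre-averaging**: optional 25 Hz zero-phase high-pass per sweep
  (order 2) before the pointwise mean.

## EEG measures

All measures operate on plain arrays; catalog entries bind them to
filter variants.

* **WSMF**: smallest frequency at which cumulative (optionally
  weighted) Welch power reaches 50% of the band total, linear
  interpolation inside the crossing bin.  Uniform weights by default —
  the literature's weighting schemes vary, so the weight vector is an
  explicit parameter.
* **qWSMF**: WSMF(8–30 Hz) / WSMF(0.5–f_high) by default; both bands
  configurable.
* **SEn**: Shannon entropy of the bin-normalized band power, divided by
  log(#bins).
* **HEx**: slope of log mean(R/S) vs log window over dyadic windows
  from 16 to n/4.  The plain R/S estimator carries a small positive
  bias for white noise at these lengths; tests use ±0.1 tolerances
  calibrated by simulation.
* **ApEn**: Pincus ApEn(m=2, r=0.2·SD), Chebyshev distance,
  self-matches included.  Inside the catalog the epoch is decimated to
  250 Hz first: the O(n²) template matching is otherwise prohibitive at
  10⁴ samples, and the regularity contrast survives decimation.  The
  implementation computes the |xᵢ−xⱼ| ≤ r matrix once and forms higher
  embeddings by ANDing shifted diagonals.
* **LZc**: LZ76 exhaustive-history word count of the median-binarized
  signal, normalized as c(n)·log₂(n)/n (→ 1 for i.i.d. binary noise).
* **PeEn**: normalized ordinal-pattern entropy, order 3, lag 1, stable
  argsort tie-breaking.

**Catalog.** The default 23 columns are the 7 measures × the 3 f_high
variants plus two band-restricted spectral columns (WSMF and SEn over
8–30 Hz under the widest filter).  The catalog is data: a list of named
specs, freely replaceable.

## AEP parameters

Averaged responses are decomposed with an orthogonal Daubechies-4 DWT,
periodized boundaries, depth 5 at 1 kHz (D1…D5, A5; D4/D5 cover the
16–62 Hz band where the mid-latency oscillation lives, D3 62–125 Hz).
Per level: max |coefficient| (amplitude), its time position mapped to
the center of the coefficient support (latency, ms; reported missing —
never 0 — for an all-zero level), Σc² (energy), max |single-level
reconstruction| ("retransformed" response), and the variance of the
second difference of the coefficient sequence.  With the 50 leading raw
coefficients of A5/D5/D4/D3 this enumerates 80 named parameters.  The
exact identity of a clinical 80-parameter catalog is not recoverable
from the literature; this one is an explicit, documented construction.

## Feature selection

Information gain of a single binary threshold split, entropy base 2,
candidate thresholds at midpoints between consecutive distinct sorted
values; ranking is stable (ties keep column order).  Selection is
recomputed on the training patients of every cross-validation fold; a
whole-working-set ranking is used only for the final holdout model.

## Classifiers

One contract: `train(spec, table, labels) -> model`,
`score(model, rows) -> graded indicator + hard labels`.  Features are
z-scored by training-fold statistics inside `train`.  Class 1 codes
"unconscious"; higher indicator = more unconscious (P_K's reversal
symmetry makes the choice conventional).  SVMs report the decision
value; probabilistic models report the class-1 log-posterior odds —
a monotone transform of the probability that remains graded where
posteriors saturate at 0/1 in floating point.  Hard-leaf trees still
produce ties, which P_K counts half.

Conventions: C ∈ {0.01, 0.1, 1, 10, 100} (grid enforced unless
explicitly relaxed), γ = 1/n_features, polynomial degree 3;
`best_over_C` scans ascending and keeps the lowest C on ties.  The MLP
uses one hidden layer of (n_features+2)/2 units with the lbfgs solver
(deterministic and reliable at a few hundred rows).  The decision tree
uses the entropy criterion (C4.5-style splits).  The Bayes net is a
tree-augmented naive Bayes implemented in-package: features binarized
at their information-gain thresholds, Chow–Liu tree over
class-conditional mutual information, Laplace-smoothed CPTs.

## Evaluation

* **P_K** is computed by rank counts (searchsorted over the sorted
  per-state indicators), equivalent to exhaustive pair counting and to
  ROC area with half ties; both equivalences are asserted against
  independent oracles in the tests.
* **Patient-wise evaluation**: per-patient P_K over within-patient
  cross-state pairs, then unweighted mean and sample SD (n−1) across
  patients; patients retaining only one state are excluded and listed.
* **LOPO-CV**: per fold, ranking and standardization use training
  patients only; the excluded patient's points are scored exactly once;
  an audit log records fold memberships for mechanical leakage checks.
* **Holdout**: a seeded random patient split (default 10 held back);
  the compound indicator (default RBF-SVM over the top 20 working-set
  features) is fit on all working patients and scored once on the
  holdout, next to single-parameter comparators (two best EEG, one best
  AEP by working-set P_K; a parameter with working-set P_K < 0.5 is
  used sign-inverted, the orientation frozen before touching holdout
  data).
* **Bootstrap CI**: patients resampled with replacement, B = 2000 by
  default, pooled P_K per resample, 2.5/97.5 percentiles.  Patient-level
  resampling respects the clustering of data points within patients.
  Degenerate single-state resamples are skipped.

## Problem sizes in the test suite

Replicate-heavy checks (effect recovery, permutation nulls, trend
assertions) run on 8–12 patient cohorts with a reduced 4-measure EEG
catalog, 20 replicates where a sign test is involved and 5 where only a
mean trend is asserted; the full 23+80 catalog runs on small fixtures.
These sizes were chosen as the smallest at which the Monte-Carlo
tolerances stated in the tests are comfortably non-vacuous.

## Known limitations

* The generator's realism gaps listed above; in particular, absolute
  P_K levels on synthetic cohorts say nothing about clinical data.
* The RBF-SVM decision value can saturate for patients far from the
  global decision boundary, costing within-patient resolution on
  strongly offset cohorts; the linear kernel is more robust in that
  regime here.
* Binary states only (conscious/unconscious); no ordinal multi-level
  P_K, no jackknife P_K variance.
* The 23- and 80-parameter catalogs are documented constructions, not
  reverse-engineered clinical catalogs.
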