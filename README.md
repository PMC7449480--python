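# anespk

Construction and evaluation of combined EEG/AEP indices of
(un)consciousness under general anesthesia.

Depth-of-anesthesia monitors reduce the spontaneous
electroencephalogram (EEG) and the mid-latency auditory evoked
potential (AEP) to numerical signal parameters and combine them into a
single index that should separate consciousness from unconsciousness.
`anespk` implements that pipeline end to end for researchers evaluating
candidate indices:

* **Signal parameters** — seven EEG measures (weighted spectral median
  frequency WSMF, its band quotient qWSMF, spectral entropy SEn, Hurst
  exponent HEx, approximate entropy ApEn, Lempel-Ziv complexity LZc,
  permutation entropy PeEn) computed under configurable low-pass
  variants f_high ∈ {30, 49, 90} Hz, and five wavelet-derived AEP
  parameter families (coefficients, amplitudes, latencies, level
  energies, maxima of single-level "retransformed" responses, curvature
  variance), 23 + 80 named parameters in the default catalogs.
* **Artifact rejection** — automatic rules for flat-line segments,
  excursions beyond the ±250 µV measuring range, and amplitude changes
  exceeding 140 µV/s.
* **Feature selection** — information-gain ranking over a single
  threshold split (C4.5 midpoint convention), recomputed inside each
  cross-validation fold.
* **Classifier harness** — SVMs (linear/polynomial/RBF/sigmoid kernels,
  C grid 0.01–100, γ = 1/n), Gaussian and kernel-density naive Bayes,
  logistic regression, a single-hidden-layer perceptron, an
  entropy-criterion decision tree, and a tree-augmented naive Bayes
  network, all behind one train/score contract that yields a graded
  indicator.
* **Evaluation** — the prediction probability

  P_K = (C + T/2) / (C + D + T)

  over all cross-state pairs (C concordant, D discordant, T tied;
  P_K = 1 perfect concordance, 0.5 chance), patient-wise leave-one-out
  cross-validation, held-back patient splits, and patient-level
  bootstrap confidence intervals.
* **Synthetic cohort generator** — a tested, first-class module that
  emulates the transition protocol (LOC/ROC events, one conscious and
  one unconscious data point each, 8 data points per patient; a
  40-patient cohort gives 320 labeled points) with state-dependent
  spectral slowing of the EEG, amplitude/latency modulation of the AEP,
  between-patient variability and artifact contamination, so the whole
  pipeline is testable without access to patient recordings.

## Worked example

`examples/03_rank_and_classify.py` simulates an 8-patient cohort,
builds the 103-column feature table, ranks parameters by information
gain and cross-validates three classifiers patient-wise:

```
top 5 parameters by information gain (whole working set):
 rank       feature  gain_bits  threshold
    1 aep_coef_D4_1   0.575757   1.146521
    2 aep_energy_D4   0.265821  29.164054
    3  aep_d2var_D4   0.265821   9.874571
    4 aep_coef_A5_1   0.243435  -0.037775
    5      WSMF_f90   0.218995   7.557005
naive_bayes        patient-wise P_K 0.805 +- 0.27 (pooled 0.805)
svm_linear_C0.1    patient-wise P_K 0.906 +- 0.15 (pooled 0.906)
logistic           patient-wise P_K 0.930 +- 0.10 (pooled 0.930)
```

Each line is the mean ± SD over patients of the per-patient P_K of the
cross-validated indicator: 1.0 would order every conscious/unconscious
pair correctly within every patient, 0.5 is chance.  The other examples
cover cohort simulation and artifact detection (`01`), feature
extraction (`02`) and the final held-back evaluation with bootstrap
CIs (`04`).

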