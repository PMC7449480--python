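"""Simulate a synthetic anesthesia cohort and inspect its structure.

Generates EEG epochs and AEP sweep trains for a small cohort following
the transition protocol (LOC1/ROC1/LOC2/ROC2, one conscious and one
unconscious data point per transition), injects artifacts, and shows
what the automatic detector flags.
"""

import numpy as np

from anespk import CohortConfig, detect_artifacts, generate_cohort, inject_artifacts

cfg = CohortConfig(n_patients=4, artifact_rate=0.15, seed=7)
epochs, sweeps = generate_cohort(cfg)
print(f"cohort: {cfg.n_patients} patients -> {len(epochs)} labeled data points "
      f"({cfg.events_per_patient} transitions x 2 states each)")

ep = epochs[0]
print(f"first epoch: patient {ep.patient_id}, event {ep.event_label}, "
      f"state {ep.state}, {len(ep.samples)} samples at {ep.sampling_rate:g} Hz, "
      f"SD {ep.samples.std():.1f} uV")
sw = sweeps[0]
print(f"matching AEP train: {sw.sweeps.shape[0]} sweeps of "
      f"{sw.sweeps.shape[1]} samples, window {sw.window} ms post-stimulus")

corrupted = inject_artifacts(epochs, cfg)
n_true = sum(e.artifact_truth is not None for e in corrupted)
n_flagged = sum(detect_artifacts(e).flagged for e in corrupted)
reasons = [sorted(detect_artifacts(e).reasons) for e in corrupted
           if e.artifact_truth is not None][:3]
print(f"artifact injection at rate {cfg.artifact_rate}: {n_true} epochs "
      f"corrupted, detector flags {n_flagged}")
print("example detector reasons:", reasons)
# n_flagged should equal n_true on this clean synthetic data: the three
# corruption classes are exactly the three detector rules.
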