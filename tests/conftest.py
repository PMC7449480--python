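"""Shared fixtures: small synthetic cohorts and feature tables.

Everything is generated at test time from seeds; the expensive fixtures
are session-scoped so the classifier/evaluation/experiment tests share
one cohort.
"""

from __future__ import annotations

import numpy as np
import pytest

from anespk.cohort import CohortConfig, generate_cohort
from anespk.eeg_features import EEGFeatureSpec
from anespk.experiment import build_feature_table
from anespk.preprocess import FilterSpec


def fast_eeg_specs(f_highs=(49.0,)):
    """A reduced EEG catalog (fast measures only) for replicate-heavy tests."""
    return [EEGFeatureSpec(name=f"{m}_f{int(fh)}", measure=m,
                           filter=FilterSpec(0.5, fh))
            for fh in f_highs for m in ("WSMF", "SEn", "PeEn", "LZc")]


@pytest.fixture(scope="session")
def small_cohort():
    cfg = CohortConfig(n_patients=6, artifact_rate=0.0, seed=11)
    epochs, sweeps = generate_cohort(cfg)
    return cfg, epochs, sweeps


@pytest.fixture(scope="session")
def small_table(small_cohort):
    """Feature table of the 6-patient cohort: 48 rows, 4 EEG + 80 AEP columns."""
    _, epochs, sweeps = small_cohort
    return build_feature_table(epochs, sweeps, eeg_specs=fast_eeg_specs())


@pytest.fixture(scope="session")
def small_xy(small_table):
    tab = small_table
    features = tab.drop(columns=["patient_id", "event", "state"])
    labels = (tab["state"] == "unconscious").astype(int).to_numpy()
    patients = tab["patient_id"].to_numpy()
    return features, labels, patients


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
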