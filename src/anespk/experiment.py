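"""End-to-end experiment matrices: modality sets, f_high sweeps, n-best
feature curves, classifier grids, and the final held-back evaluation.

The unit of work is a *cell*: one (classifier, C, n_features, modality,
f_high) combination evaluated by patient-wise leave-one-out
cross-validation on the working set.  :func:`run_matrix` emits one tidy
ledger row per cell plus a "best" row per classifier (max over n and,
for SVMs, over C), which is the numeric analogue of the result tables
and performance curves a monitoring study reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .aep_features import aep_feature_matrix, default_aep_catalog
from .classification import (C_GRID, SVM_FAMILIES, ClassifierSpec, score,
                             train)
from .cohort import AEPSweepSet, CohortConfig, EpochedSignal, generate_cohort
from .eeg_features import EEG_FEATURE_FHIGH, eeg_feature_matrix
from .evaluation import (PKResult, SplitPlan, bootstrap_ci,
                         leave_one_patient_out, make_split, patientwise_pk,
                         prediction_probability)
from .feature_selection import rank_features, top_n

log = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "build_feature_table",
    "feature_modality",
    "filter_columns",
    "run_matrix",
    "final_holdout_evaluation",
]

META_COLUMNS = ["patient_id", "event", "state"]


def feature_modality(name: str) -> str:
    return "AEP" if name.startswith("aep_") else "EEG"


def build_feature_table(
    epochs: Sequence[EpochedSignal],
    sweep_sets: Sequence[AEPSweepSet],
    eeg_specs=None,
    reject_artifacts: bool = True,
) -> pd.DataFrame:
    """Assemble the combined EEG + AEP feature table.

    One row per data point (patient x event x state).  A data point
    whose EEG epoch is flagged by the artifact detector is dropped
    entirely (its AEP columns too), as is any row left with missing
    values; removals are logged.
    """
    eeg = eeg_feature_matrix(epochs, specs=eeg_specs,
                             reject_artifacts=reject_artifacts)
    aep = aep_feature_matrix(sweep_sets)
    merged = eeg.merge(aep, on=META_COLUMNS, how="inner")
    n_dropped = len(merged) - len(merged.dropna())
    if n_dropped:
        log.info("dropping %d rows with missing feature values", n_dropped)
    return merged.dropna().reset_index(drop=True)


def filter_columns(columns: Sequence[str], modality: str,
                   f_high: Optional[float] = None) -> List[str]:
    """Select feature columns by modality set and optional f_high variant.

    ``modality`` is "EEG", "AEP" or "combined".  ``f_high`` restricts the
    EEG columns to one low-pass variant; AEP columns are unaffected.
    """
    out = []
    for c in columns:
        if c in META_COLUMNS:
            continue
        mod = feature_modality(c)
        if modality != "combined" and mod != modality:
            continue
        if f_high is not None and mod == "EEG":
            if EEG_FEATURE_FHIGH.get(c) != float(f_high):
                continue
        out.append(c)
    return out


@dataclass
class ExperimentConfig:
    """Declarative description of one experiment matrix."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    modalities: Tuple[str, ...] = ("combined",)
    f_high_list: Tuple[Optional[float], ...] = (None,)   # None = all variants
    classifiers: Tuple[ClassifierSpec, ...] = (
        ClassifierSpec(family="svm_rbf", C=1.0),)
    n_features_range: Tuple[int, ...] = tuple(range(1, 21))
    n_heldback: int = 10
    final_n_features: int = 20
    bootstrap_B: int = 2000
    seed: int = 0

    def validate(self) -> None:
        if not self.modalities:
            raise ValueError("empty modality set")
        for m in self.modalities:
            if m not in ("EEG", "AEP", "combined"):
                raise ValueError(f"unknown modality {m!r}")


def _expand_specs(specs: Sequence[ClassifierSpec]) -> List[ClassifierSpec]:
    """Expand SVM specs with C=None into the full C grid."""
    out: List[ClassifierSpec] = []
    for s in specs:
        if s.family in SVM_FAMILIES and s.C is None:
            out.extend(ClassifierSpec(family=s.family, C=c, degree=s.degree,
                                      seed=s.seed) for c in C_GRID)
        else:
            out.append(s)
    return out


def _evaluate_cell(table: pd.DataFrame, labels, patients, spec, n: int):
    preds, _ = leave_one_patient_out(table, labels, patients, spec, n)
    return patientwise_pk(preds["state"], preds["indicator"],
                          preds["patient_id"])


def run_matrix(config: ExperimentConfig,
               table: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Evaluate every (classifier, n, modality, f_high) cell on the
    working set and append per-classifier "best" rows.

    ``table`` may pass a precomputed feature table; otherwise the
    synthetic cohort in the config is generated and featurized.  A cell
    whose evaluation raises is marked failed and the run continues.
    """
    config.validate()
    if table is None:
        epochs, sweeps = generate_cohort(config.cohort)
        table = build_feature_table(epochs, sweeps)
    labels = (table["state"] == "unconscious").astype(int).to_numpy()
    patients = table["patient_id"].to_numpy()
    split = make_split(patients, config.n_heldback, seed=config.seed)
    working = table["patient_id"].isin(split.working).to_numpy()
    wtab, wlab, wpat = table[working], labels[working], patients[working]

    specs = _expand_specs(config.classifiers)
    rows = []
    for modality in config.modalities:
        for fh in config.f_high_list:
            cols = filter_columns(table.columns, modality, fh)
            if not cols:
                log.warning("no columns for modality=%s f_high=%s; skipped",
                            modality, fh)
                continue
            for spec in specs:
                for n in config.n_features_range:
                    if n > len(cols):
                        continue
                    base = {"classifier": spec.label, "family": spec.family,
                            "C": spec.C, "n_features": n,
                            "modality": modality, "f_high": fh, "best": False}
                    try:
                        res = _evaluate_cell(wtab[cols], wlab, wpat, spec, n)
                        rows.append({**base, "pk_mean": res.mean_sd[0],
                                     "pk_sd": res.mean_sd[1],
                                     "pk_pooled": res.pk, "failed": False})
                    except Exception as exc:   # cell isolation by design
                        log.error("cell %s failed: %s", base, exc)
                        rows.append({**base, "pk_mean": np.nan,
                                     "pk_sd": np.nan, "pk_pooled": np.nan,
                                     "failed": True})
    ledger = pd.DataFrame(rows)

    best_rows = []
    if len(ledger):
        ok = ledger[~ledger["failed"]]
        for (modality, fh, family), grp in ok.groupby(
                ["modality", "f_high", "family"], dropna=False):
            i = grp["pk_mean"].idxmax()
            best = ledger.loc[i].copy()
            best["best"] = True
            best_rows.append(best)
    if best_rows:
        ledger = pd.concat([ledger, pd.DataFrame(best_rows)],
                           ignore_index=True)
    return ledger


def final_holdout_evaluation(
    config: ExperimentConfig,
    table: Optional[pd.DataFrame] = None,
    split: Optional[SplitPlan] = None,
    final_spec: ClassifierSpec = ClassifierSpec(family="svm_rbf", C=1.0),
) -> pd.DataFrame:
    """Train the compound indicator on all working patients and score the
    held-back patients, alongside single-parameter comparators.

    The compound indicator uses the ``final_n_features`` top-ranked
    features (ranking on the working set only).  Comparators are the two
    EEG parameters and the one AEP parameter with the highest
    working-set P_K; a raw feature whose working-set P_K is below 0.5 is
    used with inverted sign, and that orientation is frozen before
    touching the held-back data.  Reports pooled P_K with a
    patient-level bootstrap CI per indicator.
    """
    config.validate()
    if table is None:
        epochs, sweeps = generate_cohort(config.cohort)
        table = build_feature_table(epochs, sweeps)
    labels = (table["state"] == "unconscious").astype(int).to_numpy()
    patients = table["patient_id"].to_numpy()
    if split is None:
        split = make_split(patients, config.n_heldback, seed=config.seed)
    if not split.held_back:
        raise ValueError("empty held-back set")
    work = table["patient_id"].isin(split.working).to_numpy()
    hold = table["patient_id"].isin(split.held_back).to_numpy()
    if not hold.any():
        raise ValueError("no data points from held-back patients")
    feat_cols = [c for c in table.columns if c not in META_COLUMNS]
    wtab, wlab = table.loc[work, feat_cols], labels[work]
    htab, hlab = table.loc[hold, feat_cols], labels[hold]
    hpat = patients[hold]

    results = []

    def add_row(name: str, indicator: np.ndarray) -> None:
        res = prediction_probability(hlab, indicator)
        ci = bootstrap_ci(hlab, indicator, hpat, B=config.bootstrap_B,
                          seed=config.seed)
        results.append({"indicator": name, "pk": res.pk,
                        "ci_low": ci[0], "ci_high": ci[1],
                        "n_points": len(indicator)})

    # compound indicator
    ranking = rank_features(wtab, wlab, computed_on="working")
    feats = top_n(ranking, min(config.final_n_features, len(ranking)))
    model = train(final_spec, wtab[feats], wlab)
    add_row(f"compound_{final_spec.label}_{len(feats)}feat",
            score(model, htab[feats]).indicator)

    # single-parameter comparators: 2 best EEG + 1 best AEP by working P_K
    def working_pk(col: str) -> Tuple[float, float]:
        pk = prediction_probability(wlab, wtab[col].to_numpy()).pk
        return (pk, 1.0) if pk >= 0.5 else (1.0 - pk, -1.0)

    oriented = {c: working_pk(c) for c in feat_cols}
    eeg_cols = sorted((c for c in feat_cols if feature_modality(c) == "EEG"),
                      key=lambda c: -oriented[c][0])
    aep_cols = sorted((c for c in feat_cols if feature_modality(c) == "AEP"),
                      key=lambda c: -oriented[c][0])
    for col in eeg_cols[:2] + aep_cols[:1]:
        sign = oriented[col][1]
        add_row(col, sign * htab[col].to_numpy())
    return pd.DataFrame(results)
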