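"""Prediction probability (P_K), patient-wise cross-validation and splits.

P_K is the pairwise concordance between a graded indicator and the
binary clinical state: over all pairs of data points with different true
states, a pair is concordant if the indicator orders it as the states
do, discordant if it orders it oppositely, and tied if the indicator
values are equal.  With ties counted half,

    P_K = (C + T/2) / (C + D + T),

so P_K = 1 is perfect concordance, 0.5 is chance and 0 perfect
discordance.  For binary states this equals the area under the ROC
curve with ties counted half.  The package convention codes
"unconscious" as the *higher* indicator value (state 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .feature_selection import rank_features, top_n

log = logging.getLogger(__name__)

__all__ = [
    "PKResult",
    "SplitPlan",
    "prediction_probability",
    "patientwise_pk",
    "leave_one_patient_out",
    "bootstrap_ci",
    "make_split",
]


@dataclass
class PKResult:
    """A P_K value with pair counts and optional per-patient breakdown."""

    pk: float
    n_pairs: Tuple[int, int, int]                    # (concordant, discordant, tied)
    per_patient: Optional[Dict[str, float]] = None
    mean_sd: Optional[Tuple[float, float]] = None    # over patients
    ci: Optional[Tuple[float, float]] = None
    excluded_patients: List[str] = field(default_factory=list)


def _as_binary_states(states: Sequence) -> np.ndarray:
    s = np.asarray(states)
    if s.dtype.kind in "USO":
        return (s == "unconscious").astype(int)
    return s.astype(int)


def _pair_counts(y: np.ndarray, ind: np.ndarray) -> Tuple[int, int, int]:
    """Concordant / discordant / tied counts over all cross-state pairs."""
    hi = np.sort(ind[y == 1])      # unconscious: should score high
    lo = np.sort(ind[y == 0])
    # for each unconscious value u: #conscious strictly below u -> concordant
    below = np.searchsorted(lo, hi, side="left")
    below_or_eq = np.searchsorted(lo, hi, side="right")
    c = int(below.sum())
    t = int((below_or_eq - below).sum())
    d = len(hi) * len(lo) - c - t
    return c, d, t


def prediction_probability(states: Sequence,
                           indicator: Sequence[float]) -> PKResult:
    """Pooled P_K of a graded indicator against the binary state.

    ``states`` may be 0/1 integers (1 = unconscious) or the strings
    "conscious"/"unconscious".  Raises if only one state is present.
    """
    y = _as_binary_states(states)
    ind = np.asarray(indicator, dtype=float)
    if len(y) != len(ind):
        raise ValueError("states and indicator must have equal length")
    if not np.all(np.isfinite(ind)):
        raise ValueError("indicator contains non-finite values")
    if len(np.unique(y)) < 2:
        raise ValueError("P_K undefined: only one state present")
    c, d, t = _pair_counts(y, ind)
    pk = (c + t / 2.0) / (c + d + t)
    return PKResult(pk=float(pk), n_pairs=(c, d, t))


def patientwise_pk(states: Sequence, indicator: Sequence[float],
                   patient_ids: Sequence) -> PKResult:
    """Per-patient P_K with unweighted mean and sample SD across patients.

    Patients lacking a cross-state pair (only one state retained) are
    excluded and listed in ``excluded_patients``.
    """
    y = _as_binary_states(states)
    ind = np.asarray(indicator, dtype=float)
    pid = np.asarray(patient_ids)
    per: Dict[str, float] = {}
    excluded: List[str] = []
    totals = np.zeros(3, dtype=int)
    for p in pd.unique(pid):
        sel = pid == p
        if len(np.unique(y[sel])) < 2:
            excluded.append(str(p))
            log.info("patient %s excluded from per-patient P_K: single state", p)
            continue
        c, d, t = _pair_counts(y[sel], ind[sel])
        totals += (c, d, t)
        per[str(p)] = (c + t / 2.0) / (c + d + t)
    if not per:
        raise ValueError("no patient has both states; patient-wise P_K undefined")
    vals = np.array(list(per.values()))
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    pooled = (totals[0] + totals[2] / 2.0) / max(totals.sum(), 1)
    return PKResult(pk=float(pooled), n_pairs=tuple(int(v) for v in totals),
                    per_patient=per, mean_sd=(float(vals.mean()), sd),
                    excluded_patients=excluded)


def leave_one_patient_out(
    table: pd.DataFrame,
    labels: Sequence,
    patient_ids: Sequence,
    spec,
    n_features: int,
    rank_per_fold: bool = True,
) -> Tuple[pd.DataFrame, List[Dict[str, object]]]:
    """Patient-wise leave-one-out cross-validation.

    Per fold: rank features on the training patients only (no leakage),
    keep the top ``n_features``, train the classifier spec, and score
    every data point of the excluded patient.  Returns a predictions
    frame (patient_id, state, indicator, fold) covering every data point
    exactly once, plus an audit log of fold memberships.

    ``table`` must contain feature columns only.  ``spec`` is a
    :class:`~anespk.classification.ClassifierSpec`.
    """
    from .classification import score, train   # local import: avoid cycle

    y = _as_binary_states(labels)
    pid = np.asarray(patient_ids)
    patients = list(pd.unique(pid))
    if len(patients) < 2:
        raise ValueError("need at least 2 patients for leave-one-patient-out")

    global_ranking = None
    if not rank_per_fold:
        global_ranking = rank_features(table, y, computed_on="all")

    preds = []
    audit: List[Dict[str, object]] = []
    for fold, p in enumerate(patients):
        test_mask = pid == p
        train_mask = ~test_mask
        y_tr = y[train_mask]
        if len(np.unique(y_tr)) < 2:
            log.warning("fold %d (patient %s) skipped: single-class training "
                        "data", fold, p)
            continue
        ranking = (global_ranking if global_ranking is not None
                   else rank_features(table[train_mask], y_tr,
                                      computed_on=f"fold_{fold}"))
        feats = top_n(ranking, min(n_features, len(ranking)))
        model = train(spec, table.loc[train_mask, feats], y_tr)
        ind = score(model, table.loc[test_mask, feats]).indicator
        for i, idx in enumerate(np.flatnonzero(test_mask)):
            preds.append({"patient_id": pid[idx], "state": int(y[idx]),
                          "indicator": float(ind[i]), "fold": fold})
        audit.append({"fold": fold, "test_patient": str(p),
                      "train_patients": sorted(str(q) for q in patients
                                               if q != p),
                      "features": feats})
    return pd.DataFrame(preds), audit


def bootstrap_ci(states: Sequence, indicator: Sequence[float],
                 patient_ids: Sequence, B: int = 2000,
                 seed: int = 0) -> Tuple[float, float]:
    """Percentile bootstrap CI for the pooled P_K, resampling patients.

    Draws ``B`` resamples of whole patients with replacement, recomputes
    the pooled P_K on each, and returns the 2.5/97.5 percentiles.
    Resamples containing a single state carry no information and are
    skipped; if every resample is degenerate an error is raised.
    """
    if B < 100:
        raise ValueError("need at least 100 bootstrap resamples")
    y = _as_binary_states(states)
    ind = np.asarray(indicator, dtype=float)
    pid = np.asarray(patient_ids)
    patients = pd.unique(pid)
    groups = {p: np.flatnonzero(pid == p) for p in patients}
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(B):
        chosen = rng.choice(patients, size=len(patients), replace=True)
        idx = np.concatenate([groups[p] for p in chosen])
        if len(np.unique(y[idx])) < 2:
            continue
        c, d, t = _pair_counts(y[idx], ind[idx])
        vals.append((c + t / 2.0) / (c + d + t))
    if not vals:
        raise ValueError("all bootstrap resamples degenerate")
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)


@dataclass
class SplitPlan:
    """A held-back patient split plus leave-one-out fold assignments."""

    working: List[str]
    held_back: List[str]

    def __post_init__(self) -> None:
        if set(self.working) & set(self.held_back):
            raise ValueError("working and held-back sets overlap")

    @property
    def folds(self) -> List[Tuple[str, List[str]]]:
        """(test patient, training patients) per leave-one-out cycle."""
        return [(p, [q for q in self.working if q != p]) for p in self.working]


def make_split(patient_ids: Sequence, n_heldback: int = 10,
               seed: int = 0) -> SplitPlan:
    """Random patient-level split into working and held-back sets."""
    patients = [str(p) for p in pd.unique(np.asarray(patient_ids))]
    if n_heldback < 0 or n_heldback >= len(patients):
        raise ValueError("n_heldback must be in [0, n_patients)")
    rng = np.random.default_rng(seed)
    held = sorted(rng.choice(patients, size=n_heldback, replace=False).tolist())
    working = [p for p in patients if p not in held]
    return SplitPlan(working=working, held_back=held)
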