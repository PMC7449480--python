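"""P_K statistic against exact pairwise and ROC oracles; CV machinery."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from anespk.classification import ClassifierSpec
from anespk.evaluation import (bootstrap_ci, leave_one_patient_out,
                               make_split, patientwise_pk,
                               prediction_probability)


def pk_oracle(states, indicator):
    """Exhaustive O(n^2) pairwise count in exact rational arithmetic."""
    y = np.asarray(states, int)
    x = list(indicator)
    c = d = t = 0
    for i in range(len(y)):
        for j in range(i + 1, len(y)):
            if y[i] == y[j]:
                continue
            hi, lo = (x[i], x[j]) if y[i] == 1 else (x[j], x[i])
            if hi > lo:
                c += 1
            elif hi < lo:
                d += 1
            else:
                t += 1
    return Fraction(2 * c + t, 2 * (c + d + t))


class TestPredictionProbability:
    def test_perfect_concordance(self):
        res = prediction_probability([1, 1, 0, 0], [0.9, 0.6, 0.4, 0.1])
        assert res.pk == 1.0 and res.n_pairs == (4, 0, 0)

    def test_perfect_discordance(self):
        res = prediction_probability([1, 1, 0, 0], [0.1, 0.2, 0.8, 0.9])
        assert res.pk == 0.0 and res.n_pairs == (0, 4, 0)

    def test_all_ties_chance(self):
        res = prediction_probability([1, 1, 0, 0], [0.5] * 4)
        assert res.pk == 0.5 and res.n_pairs == (0, 0, 4)

    def test_mixed_example_hand_count(self):
        # cross pairs: (0.1,0.4)t... states (u,u,c,c), ind (0.1,0.4,0.4,0.9)
        res = prediction_probability([1, 1, 0, 0], [0.1, 0.4, 0.4, 0.9])
        assert res.n_pairs == (0, 3, 1)
        assert res.pk == pytest.approx(0.125)

    def test_string_states_accepted(self):
        res = prediction_probability(
            ["unconscious", "unconscious", "conscious", "conscious"],
            [0.9, 0.6, 0.4, 0.1])
        assert res.pk == 1.0

    def test_single_state_rejected(self):
        with pytest.raises(ValueError):
            prediction_probability([1, 1, 1], [0.1, 0.2, 0.3])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exact_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 200))
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            y[:2] = [0, 1]
        x = rng.choice(np.round(rng.standard_normal(max(n // 3, 2)), 2), n)
        res = prediction_probability(y, x)
        oracle = pk_oracle(y, x)
        assert res.pk == pytest.approx(float(oracle), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_roc_auc_with_half_ties(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = 80
        y = np.r_[np.zeros(40, int), np.ones(40, int)]
        x = rng.choice(np.linspace(0, 1, 25), n)    # forces ties
        res = prediction_probability(y, x)
        assert res.pk == pytest.approx(roc_auc_score(y, x), abs=1e-12)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_reversal_and_monotone_invariance(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            y[:2] = [0, 1]
        x = rng.standard_normal(n)
        pk = prediction_probability(y, x).pk
        assert prediction_probability(y, -x).pk == pytest.approx(1 - pk)
        assert prediction_probability(y, np.exp(x)).pk == pytest.approx(pk)


class TestPatientwise:
    def test_two_perfect_patients(self):
        y = [0, 1, 0, 1]
        x = [0.1, 0.9, 0.2, 0.8]
        res = patientwise_pk(y, x, ["A", "A", "B", "B"])
        assert res.mean_sd == (1.0, 0.0)
        assert res.per_patient == {"A": 1.0, "B": 1.0}

    def test_opposite_patients_mean_and_sd(self):
        y = [0, 1, 0, 1]
        x = [0.1, 0.9, 0.8, 0.2]      # B perfectly discordant
        res = patientwise_pk(y, x, ["A", "A", "B", "B"])
        mean, sd = res.mean_sd
        assert mean == pytest.approx(0.5)
        assert sd == pytest.approx(np.std([1.0, 0.0], ddof=1))

    def test_single_state_patient_excluded(self):
        y = [0, 1, 1, 1]
        x = [0.1, 0.9, 0.5, 0.6]
        res = patientwise_pk(y, x, ["A", "A", "B", "B"])
        assert res.excluded_patients == ["B"]
        assert set(res.per_patient) == {"A"}

    def test_no_valid_patient_rejected(self):
        with pytest.raises(ValueError):
            patientwise_pk([0, 0, 1, 1], [1, 2, 3, 4], ["A", "A", "B", "B"])


class TestLeaveOnePatientOut:
    def test_every_point_scored_once(self, small_xy):
        feats, labels, patients = small_xy
        spec = ClassifierSpec(family="naive_bayes")
        preds, audit = leave_one_patient_out(feats, labels, patients, spec, 3)
        assert len(preds) == len(feats)
        assert len(audit) == len(np.unique(patients))
        counts = preds.groupby("patient_id").size()
        assert (counts == 8).all()

    def test_no_test_patient_in_training(self, small_xy):
        feats, labels, patients = small_xy
        spec = ClassifierSpec(family="naive_bayes")
        _, audit = leave_one_patient_out(feats, labels, patients, spec, 3)
        for fold in audit:
            assert fold["test_patient"] not in fold["train_patients"]

    def test_needs_two_patients(self, small_xy):
        feats, labels, patients = small_xy
        one = patients == patients[0]
        with pytest.raises(ValueError):
            leave_one_patient_out(feats[one], labels[one], patients[one],
                                  ClassifierSpec(family="naive_bayes"), 2)

    def test_within_patient_permutation_is_chance(self, small_xy):
        """Shuffling labels within each patient destroys the signal: the
        cross-validated patient-mean P_K falls in the chance band."""
        feats, labels, patients = small_xy
        rng = np.random.default_rng(5)
        spec = ClassifierSpec(family="naive_bayes")
        means = []
        for _ in range(4):
            perm = labels.copy()
            for p in np.unique(patients):
                sel = np.flatnonzero(patients == p)
                perm[sel] = rng.permutation(perm[sel])
            preds, _ = leave_one_patient_out(feats, perm, patients, spec, 3)
            res = patientwise_pk(preds["state"], preds["indicator"],
                                 preds["patient_id"])
            means.append(res.mean_sd[0])
        assert 0.3 < np.mean(means) < 0.7


class TestBootstrap:
    def test_perfect_data_degenerate_interval(self):
        y = [0, 1] * 10
        x = [0.1, 0.9] * 10
        pats = [f"P{i // 2}" for i in range(20)]
        assert bootstrap_ci(y, x, pats, B=200, seed=0) == (1.0, 1.0)

    def test_deterministic_given_seed(self, rng):
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        x = rng.standard_normal(40) + y
        pats = np.repeat([f"P{i}" for i in range(10)], 4)
        ci1 = bootstrap_ci(y, x, pats, B=300, seed=7)
        ci2 = bootstrap_ci(y, x, pats, B=300, seed=7)
        assert ci1 == ci2

    def test_point_estimate_inside_interval(self, rng):
        y = np.tile([0, 1], 20)
        x = rng.standard_normal(40) + 1.2 * y
        pats = np.repeat([f"P{i}" for i in range(10)], 4)
        lo, hi = bootstrap_ci(y, x, pats, B=500, seed=3)
        pk = prediction_probability(y, x).pk
        assert lo <= pk <= hi

    def test_minimum_resamples(self):
        with pytest.raises(ValueError):
            bootstrap_ci([0, 1], [0.1, 0.9], ["A", "A"], B=10)


class TestSplit:
    def test_study_sized_split(self):
        pats = [f"P{i:03d}" for i in range(39)]
        plan = make_split(pats, n_heldback=10, seed=1)
        assert len(plan.working) == 29 and len(plan.held_back) == 10
        assert not set(plan.working) & set(plan.held_back)
        # every working patient is the test patient of exactly one fold
        assert [f[0] for f in plan.folds] == plan.working

    def test_different_seeds_differ(self):
        pats = [f"P{i:03d}" for i in range(39)]
        a = make_split(pats, 10, seed=1)
        b = make_split(pats, 10, seed=2)
        assert a.held_back != b.held_back

    def test_zero_heldback(self):
        plan = make_split(["A", "B", "C"], 0, seed=0)
        assert plan.working == ["A", "B", "C"] and plan.held_back == []

    def test_too_many_heldback_rejected(self):
        with pytest.raises(ValueError):
            make_split(["A", "B"], 2, seed=0)
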