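"""Uniform train/score harness over the classifier families.

Families: SVMs with linear, polynomial (degree 3), RBF and sigmoid
kernels (C grid 0.01-100, gamma = 1/n_features), Gaussian naive Bayes
with and without per-feature kernel density estimation, logistic
regression, a single-hidden-layer perceptron, an entropy-based decision
tree (C4.5 style), and a tree-augmented naive Bayes network over
threshold-discretized features.

Standard fits delegate to scikit-learn; the kernel-density naive Bayes
and the tree-augmented network are implemented here.  Features are
z-scored by training-fold statistics inside :func:`train`, and every
model exposes a continuous indicator (decision value or class-1
probability) through :func:`score` so that P_K can consume a graded
output: class 1 is "unconscious" and higher indicator values mean more
unconscious.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .feature_selection import information_gain

__all__ = [
    "C_GRID",
    "FAMILIES",
    "SVM_FAMILIES",
    "ClassifierSpec",
    "IndicatorScore",
    "FittedModel",
    "train",
    "score",
    "best_over_C",
]

C_GRID: Tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)

SVM_FAMILIES = ("svm_linear", "svm_poly", "svm_rbf", "svm_sigmoid")
FAMILIES = SVM_FAMILIES + ("naive_bayes", "naive_bayes_kernel", "logistic",
                           "mlp", "tree_c45", "bayes_net")

_SVM_KERNELS = {"svm_linear": "linear", "svm_poly": "poly",
                "svm_rbf": "rbf", "svm_sigmoid": "sigmoid"}


@dataclass(frozen=True)
class ClassifierSpec:
    """Algorithm family plus hyperparameters.

    ``C`` applies to SVM families only; the kernel coefficient follows
    the 1/n_features rule and polynomial kernels have degree 3 unless
    overridden.  ``enforce_grid`` restricts C to the canonical grid.
    """

    family: str
    C: Optional[float] = None
    degree: int = 3
    seed: int = 0
    enforce_grid: bool = True

    def validate(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family in SVM_FAMILIES:
            if self.C is None or self.C <= 0:
                raise ValueError("SVM specs need a positive C")
            if self.enforce_grid and self.C not in C_GRID:
                raise ValueError(f"C={self.C} not in the grid {C_GRID}")
        if self.degree < 1:
            raise ValueError("degree must be >= 1")

    @property
    def label(self) -> str:
        if self.family in SVM_FAMILIES:
            return f"{self.family}_C{self.C:g}"
        return self.family


@dataclass
class IndicatorScore:
    """Continuous indicator plus hard labels for a set of rows."""

    indicator: np.ndarray
    labels: np.ndarray


# ---------------------------------------------------------------------------
# Naive Bayes with per-feature kernel densities
# ---------------------------------------------------------------------------

class _KernelNB:
    """Naive Bayes with Gaussian-KDE class-conditional densities."""

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_KernelNB":
        self.classes_ = np.unique(y)
        self._priors = {c: np.mean(y == c) for c in self.classes_}
        self._kdes: Dict[int, List] = {}
        for c in self.classes_:
            Xc = X[y == c]
            feats = []
            for j in range(X.shape[1]):
                col = Xc[:, j]
                if np.ptp(col) < 1e-12 or len(col) < 2:
                    # degenerate column: narrow Gaussian at the mean
                    feats.append(("gauss", float(col.mean()), 1e-3))
                else:
                    feats.append(("kde", gaussian_kde(col), None))
            self._kdes[c] = feats
        return self

    def _log_post(self, X: np.ndarray) -> np.ndarray:
        lp = np.zeros((len(X), len(self.classes_)))
        for ci, c in enumerate(self.classes_):
            lp[:, ci] = np.log(self._priors[c])
            for j, (kind, a, b) in enumerate(self._kdes[c]):
                if kind == "kde":
                    dens = a.evaluate(X[:, j])
                else:
                    dens = np.exp(-0.5 * ((X[:, j] - a) / b) ** 2) / b
                lp[:, ci] += np.log(np.maximum(dens, 1e-300))
        return lp

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        lp = self._log_post(X)
        lp -= lp.max(axis=1, keepdims=True)
        p = np.exp(lp)
        return p / p.sum(axis=1, keepdims=True)

    def predict_log_odds(self, X: np.ndarray) -> np.ndarray:
        lp = self._log_post(X)
        return lp[:, 1] - lp[:, 0]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self._log_post(X), axis=1)]


# ---------------------------------------------------------------------------
# Tree-augmented naive Bayes over threshold-discretized features
# ---------------------------------------------------------------------------

class _TANBayesNet:
    """Tree-augmented naive Bayes network.

    Features are binarized at their best information-gain threshold
    (median fallback), a Chow-Liu tree is built from class-conditional
    mutual information, and conditional probability tables use Laplace
    smoothing.
    """

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_TANBayesNet":
        self.classes_ = np.unique(y)
        n, d = X.shape
        self._thr = np.empty(d)
        for j in range(d):
            _, thr = information_gain(X[:, j], y)
            self._thr[j] = thr if np.isfinite(thr) else np.median(X[:, j])
        B = (X > self._thr).astype(int)
        self._priors = {c: (np.sum(y == c) + 1.0) / (n + len(self.classes_))
                        for c in self.classes_}

        # class-conditional mutual information between feature pairs
        g = nx.Graph()
        g.add_nodes_from(range(d))
        for a in range(d):
            for b in range(a + 1, d):
                mi = 0.0
                for c in self.classes_:
                    sel = y == c
                    mi += np.mean(sel) * self._mi(B[sel, a], B[sel, b])
                g.add_edge(a, b, weight=mi)
        tree = nx.maximum_spanning_tree(g) if d > 1 else g
        self._parent = {0: None}
        if d > 1:
            for u, v in nx.bfs_edges(tree, 0):
                self._parent[v] = u

        # CPTs: P(x_j | parent value, class), Laplace-smoothed
        self._cpt: Dict[Tuple[int, int, int, int], float] = {}
        for j in range(d):
            pj = self._parent.get(j)
            for c in self.classes_:
                sel = y == c
                for pv in (0, 1) if pj is not None else (0,):
                    rows = sel if pj is None else sel & (B[:, pj] == pv)
                    n1 = np.sum(B[rows, j] == 1)
                    tot = np.sum(rows)
                    p1 = (n1 + 1.0) / (tot + 2.0)
                    self._cpt[(j, pv, int(c), 1)] = p1
                    self._cpt[(j, pv, int(c), 0)] = 1.0 - p1
        return self

    @staticmethod
    def _mi(a: np.ndarray, b: np.ndarray) -> float:
        if len(a) == 0:
            return 0.0
        mi = 0.0
        n = len(a)
        for va in (0, 1):
            for vb in (0, 1):
                pab = np.sum((a == va) & (b == vb)) / n
                pa = np.sum(a == va) / n
                pb = np.sum(b == vb) / n
                if pab > 0 and pa > 0 and pb > 0:
                    mi += pab * np.log(pab / (pa * pb))
        return mi

    def _log_post(self, X: np.ndarray) -> np.ndarray:
        B = (X > self._thr).astype(int)
        lp = np.zeros((len(X), len(self.classes_)))
        for ci, c in enumerate(self.classes_):
            lp[:, ci] = np.log(self._priors[c])
            for j in range(X.shape[1]):
                pj = self._parent.get(j)
                pv = np.zeros(len(X), int) if pj is None else B[:, pj]
                probs = np.array([self._cpt[(j, int(v), int(c), int(bj))]
                                  for v, bj in zip(pv, B[:, j])])
                lp[:, ci] += np.log(probs)
        return lp

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        lp = self._log_post(X)
        lp -= lp.max(axis=1, keepdims=True)
        p = np.exp(lp)
        return p / p.sum(axis=1, keepdims=True)

    def predict_log_odds(self, X: np.ndarray) -> np.ndarray:
        lp = self._log_post(X)
        return lp[:, 1] - lp[:, 0]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self._log_post(X), axis=1)]


# ---------------------------------------------------------------------------
# Harness
# ---------------------------------------------------------------------------

@dataclass
class FittedModel:
    """Opaque handle: fitted estimator plus fold standardization."""

    spec: ClassifierSpec
    columns: List[str]
    mean: np.ndarray
    sd: np.ndarray
    estimator: object
    uses_decision_function: bool

    def transform(self, rows: pd.DataFrame) -> np.ndarray:
        if list(rows.columns) != self.columns:
            raise ValueError(
                f"column mismatch: model trained on {self.columns}, "
                f"got {list(rows.columns)}")
        X = rows.to_numpy(dtype=float)
        return (X - self.mean) / self.sd


def _build_estimator(spec: ClassifierSpec, n_features: int):
    if spec.family in SVM_FAMILIES:
        return SVC(kernel=_SVM_KERNELS[spec.family], C=spec.C,
                   gamma=1.0 / n_features, degree=spec.degree,
                   random_state=spec.seed), True
    if spec.family == "naive_bayes":
        return GaussianNB(), False
    if spec.family == "naive_bayes_kernel":
        return _KernelNB(), False
    if spec.family == "logistic":
        return LogisticRegression(max_iter=1000, random_state=spec.seed), False
    if spec.family == "mlp":
        hidden = max((n_features + 2) // 2, 2)
        # lbfgs: deterministic and reliable at monitoring-study sample sizes
        return MLPClassifier(hidden_layer_sizes=(hidden,), solver="lbfgs",
                             max_iter=1000, random_state=spec.seed), False
    if spec.family == "tree_c45":
        return DecisionTreeClassifier(criterion="entropy",
                                      random_state=spec.seed), False
    if spec.family == "bayes_net":
        return _TANBayesNet(), False
    raise ValueError(f"unknown family {spec.family!r}")


def train(spec: ClassifierSpec, table: pd.DataFrame,
          labels: Sequence[int]) -> FittedModel:
    """Fit a classifier on a feature table.

    Features are z-scored by the training statistics (constant columns
    pass through unscaled).  Deterministic given ``spec.seed``.
    """
    spec.validate()
    y = np.asarray(labels).astype(int)
    if len(table) < 2:
        raise ValueError("need at least 2 training rows")
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate single-class training data")
    X = table.to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    est, uses_df = _build_estimator(spec, X.shape[1])
    est.fit((X - mean) / sd, y)
    return FittedModel(spec=spec, columns=list(table.columns), mean=mean,
                       sd=sd, estimator=est, uses_decision_function=uses_df)


def score(model: FittedModel, rows: pd.DataFrame) -> IndicatorScore:
    """Continuous indicator per row: SVM decision value, or the class-1
    log-posterior odds for probabilistic models.

    Log odds rather than the raw probability keeps the indicator graded
    where posteriors saturate at 0/1 in floating point (a monotone
    transform, so P_K is unchanged whenever the probability itself is
    not degenerate).  Hard-leaf models (the decision tree) still produce
    ties; P_K counts them half.
    """
    Z = model.transform(rows)
    est = model.estimator
    if model.uses_decision_function:
        ind = np.asarray(est.decision_function(Z), dtype=float)
    elif hasattr(est, "predict_log_odds"):
        ind = np.asarray(est.predict_log_odds(Z), dtype=float)
    elif hasattr(est, "predict_log_proba"):
        cls = list(getattr(est, "classes_"))
        lp = np.asarray(est.predict_log_proba(Z), dtype=float)
        ind = lp[:, cls.index(1)] - lp[:, cls.index(0)]
    else:
        proba = est.predict_proba(Z)
        cls = list(getattr(est, "classes_"))
        p1 = np.clip(proba[:, cls.index(1)], 1e-300, 1.0 - 1e-16)
        ind = np.log(p1) - np.log1p(-p1)
    ind = np.clip(ind, -1e6, 1e6)
    np.nan_to_num(ind, copy=False, nan=0.0)
    labels = np.asarray(est.predict(Z)).astype(int)
    return IndicatorScore(indicator=ind, labels=labels)


def best_over_C(family: str, table: pd.DataFrame, labels: Sequence[int],
                evaluation: Callable[..., float],
                grid: Sequence[float] = C_GRID,
                **spec_kwargs) -> Tuple[ClassifierSpec, float]:
    """Run the full C grid and return the maximizing spec and its value.

    ``evaluation(spec, table, labels)`` maps a spec to a scalar
    performance (e.g. a cross-validated mean P_K).  Ties keep the lowest
    C (the grid is scanned in ascending order with a strict improvement
    rule).
    """
    if family not in SVM_FAMILIES:
        raise ValueError(f"best_over_C applies to SVM families, got {family!r}")
    if len(grid) == 0:
        raise ValueError("empty C grid")
    best_spec, best_val = None, -np.inf
    for C in sorted(grid):
        spec = ClassifierSpec(family=family, C=C,
                              enforce_grid=tuple(sorted(grid)) == tuple(sorted(C_GRID)),
                              **spec_kwargs)
        val = evaluation(spec, table, labels)
        if val > best_val:
            best_spec, best_val = spec, val
    return best_spec, float(best_val)
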