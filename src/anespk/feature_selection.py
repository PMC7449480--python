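"""Information-gain feature ranking over a single threshold split.

The utility of a feature is the expected reduction of class entropy
(base 2) obtained by splitting the data at the best threshold on that
feature; candidate thresholds are the midpoints between consecutive
distinct sorted values (the C4.5 convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = ["FeatureRanking", "information_gain", "rank_features", "top_n"]


@dataclass
class FeatureRanking:
    """Features ordered by information gain (non-increasing)."""

    table: pd.DataFrame        # columns: rank, feature, gain_bits, threshold
    computed_on: str = ""

    def __len__(self) -> int:
        return len(self.table)

    @property
    def features(self) -> List[str]:
        return list(self.table["feature"])


def _entropy2(counts: np.ndarray) -> np.ndarray:
    """Binary class entropy in bits; ``counts`` is (..., 2)."""
    total = counts.sum(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(total > 0, counts / np.maximum(total, 1), 0.0)
        term = np.where(p > 0, -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return term.sum(axis=-1)


def information_gain(values: Sequence[float],
                     labels: Sequence[int]) -> Tuple[float, float]:
    """Best information gain of a threshold split and its threshold.

    Returns ``(gain_bits, threshold)``; the split is values <= threshold
    versus values > threshold, maximized over all midpoints between
    consecutive distinct sorted values.  A constant feature or
    single-class labels yield gain 0 (the latter with a warning).
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(v) != len(y) or len(v) < 2:
        raise ValueError("values and labels must have equal length >= 2")
    classes = np.unique(y)
    if len(classes) < 2:
        warnings.warn("single-class labels: information gain is 0")
        return 0.0, float("nan")
    y01 = (y == classes.max()).astype(int)

    order = np.argsort(v, kind="stable")
    vs, ys = v[order], y01[order]
    distinct = np.flatnonzero(np.diff(vs) > 0)
    if len(distinct) == 0:
        return 0.0, float("nan")

    n = len(vs)
    ones = np.cumsum(ys)
    total_ones = ones[-1]
    h_parent = _entropy2(np.array([n - total_ones, total_ones], float))

    # split after position i (0-based): left = first i+1 samples
    i = distinct
    n_left = i + 1.0
    ones_left = ones[i].astype(float)
    left = np.stack([n_left - ones_left, ones_left], axis=-1)
    right = np.stack([(n - n_left) - (total_ones - ones_left),
                      total_ones - ones_left], axis=-1)
    h_split = (n_left / n) * _entropy2(left) + ((n - n_left) / n) * _entropy2(right)
    gains = h_parent - h_split
    best = int(np.argmax(gains))
    thr = 0.5 * (vs[i[best]] + vs[i[best] + 1])
    return float(max(gains[best], 0.0)), float(thr)


def rank_features(table: pd.DataFrame, labels: Sequence[int],
                  computed_on: str = "") -> FeatureRanking:
    """Score every column by information gain and sort descending.

    Ties are broken by original column order (stable sort).  ``table``
    must contain feature columns only.
    """
    if table.shape[1] < 1:
        raise ValueError("table has no feature columns")
    rows = []
    for col in table.columns:
        gain, thr = information_gain(table[col].to_numpy(), labels)
        rows.append({"feature": col, "gain_bits": gain, "threshold": thr})
    df = pd.DataFrame(rows)
    df = df.sort_values("gain_bits", ascending=False, kind="stable")
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return FeatureRanking(table=df.reset_index(drop=True),
                          computed_on=computed_on)


def top_n(ranking: FeatureRanking, n: int) -> List[str]:
    """The ``n`` highest-utility feature names, in rank order."""
    if not 1 <= n <= len(ranking):
        raise ValueError(f"n must be in [1, {len(ranking)}]")
    return ranking.features[:n]
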