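"""Objective functions for coarse-weight regression.

All three metrics are linearly invariant: rescaling the score vector
``X @ beta`` by any positive constant leaves them unchanged, so only the
direction of the weight vector matters.  That invariance is what makes
±1 weights sufficient.

* ``pval`` — two-sided Welch (unequal variance) t-test p-value of case vs
  control scores; improves downward from a default of 1.
* ``auc`` — Mann–Whitney area under the ROC curve, ties counted 1/2;
  improves upward from a default of 0.5.
* ``corr`` — Pearson correlation with a continuous response; improves
  upward from a default of 0.

Each metric has a scalar form and a vectorized form operating on the
columns of a score matrix; the greedy engine uses the latter to evaluate
every candidate weight update in one pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

MetricName = Literal["pval", "auc", "corr"]

#: smallest positive double, returned when two zero-variance groups have
#: different means (infinitely strong separation)
_MIN_P = np.nextafter(0.0, 1.0)

__all__ = [
    "MetricSpec",
    "welch_p",
    "auc",
    "pearson",
    "metric_value",
    "is_better",
    "welch_p_columns",
    "auc_columns",
    "pearson_columns",
    "metric_columns",
]


@dataclass(frozen=True)
class MetricSpec:
    """Which metric is optimized and its direction of improvement."""

    name: MetricName
    tie_tolerance: float = 1e-12

    def __post_init__(self) -> None:
        if self.name not in ("pval", "auc", "corr"):
            raise ValueError(f"unknown metric {self.name!r}")
        if self.tie_tolerance < 0:
            raise ValueError("tie_tolerance must be >= 0")

    @property
    def default_value(self) -> float:
        return {"pval": 1.0, "auc": 0.5, "corr": 0.0}[self.name]

    @property
    def better_direction(self) -> str:
        return "lower" if self.name == "pval" else "higher"

    @property
    def requires_binary(self) -> bool:
        return self.name in ("pval", "auc")


def _check_binary(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels, dtype=float)
    case = labels == 1.0
    ctrl = labels == 0.0
    if not np.all(case | ctrl):
        raise ValueError("labels must be 0/1")
    if case.sum() == 0 or ctrl.sum() == 0:
        raise ValueError("both classes must be present")
    return ctrl, case


def welch_p_columns(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Two-sided Welch p-value for each column of ``scores``."""
    S = np.atleast_2d(np.asarray(scores, dtype=float).T).T
    ctrl, case = _check_binary(labels)
    n0, n1 = int(ctrl.sum()), int(case.sum())
    if n0 < 2 or n1 < 2:
        raise ValueError("each class needs at least 2 members")
    m0 = S[ctrl].mean(axis=0)
    m1 = S[case].mean(axis=0)
    v0 = S[ctrl].var(axis=0, ddof=1)
    v1 = S[case].var(axis=0, ddof=1)
    se2 = v0 / n0 + v1 / n1
    out = np.ones(S.shape[1])
    degenerate = se2 == 0.0
    # both groups constant: equal means -> no evidence (p=1); unequal
    # means -> perfect separation, smallest positive p
    out[degenerate & (m0 != m1)] = _MIN_P
    ok = ~degenerate
    if np.any(ok):
        t = (m1[ok] - m0[ok]) / np.sqrt(se2[ok])
        df = se2[ok] ** 2 / (
            (v0[ok] / n0) ** 2 / (n0 - 1) + (v1[ok] / n1) ** 2 / (n1 - 1)
        )
        out[ok] = 2.0 * stats.t.sf(np.abs(t), df)
    return out


def auc_columns(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Mann–Whitney AUC (P[case score > control score], ties 1/2) per column."""
    S = np.atleast_2d(np.asarray(scores, dtype=float).T).T
    ctrl, case = _check_binary(labels)
    n0, n1 = int(ctrl.sum()), int(case.sum())
    ranks = stats.rankdata(S, axis=0, method="average")
    u1 = ranks[case].sum(axis=0) - n1 * (n1 + 1) / 2.0
    return u1 / (n0 * n1)


def pearson_columns(scores: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each column with ``y``.

    Zero-variance columns yield 0.0 here (a degenerate candidate score is
    as uninformative as the default model); the scalar :func:`pearson`
    raises instead.
    """
    S = np.atleast_2d(np.asarray(scores, dtype=float).T).T
    y = np.asarray(y, dtype=float)
    yc = y - y.mean()
    ny = np.sqrt(yc @ yc)
    if ny == 0.0:
        raise ValueError("response has zero variance")
    Sc = S - S.mean(axis=0)
    ns = np.sqrt(np.einsum("ij,ij->j", Sc, Sc))
    out = np.zeros(S.shape[1])
    ok = ns > 0.0
    out[ok] = (Sc[:, ok].T @ yc) / (ns[ok] * ny)
    return np.clip(out, -1.0, 1.0)


def welch_p(scores: np.ndarray, labels: np.ndarray) -> float:
    """Two-sided Welch t-test p-value, case (label 1) vs control (label 0)."""
    return float(welch_p_columns(np.asarray(scores, float)[:, None], labels)[0])


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC area: probability a random case outscores a random control."""
    return float(auc_columns(np.asarray(scores, float)[:, None], labels)[0])


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation; raises on zero-variance input."""
    x = np.asarray(x, dtype=float)
    if np.std(x) == 0.0:
        raise ValueError("zero-variance input, correlation undefined")
    return float(pearson_columns(x[:, None], y)[0])


def metric_columns(spec: MetricSpec, scores: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized dispatch: metric of each score-matrix column against ``y``."""
    if spec.name == "pval":
        return welch_p_columns(scores, y)
    if spec.name == "auc":
        return auc_columns(scores, y)
    return pearson_columns(scores, y)


def metric_value(spec: MetricSpec, scores: np.ndarray, y: np.ndarray) -> float:
    """Metric of a single score vector; an all-zero score vector (the empty
    model) returns the metric's default value exactly."""
    scores = np.asarray(scores, dtype=float)
    if not np.any(scores):
        return spec.default_value
    return float(metric_columns(spec, scores[:, None], y)[0])


def is_better(spec: MetricSpec, a: float, b: float) -> bool:
    """True iff ``a`` improves on ``b`` by more than the tie tolerance."""
    if spec.better_direction == "lower":
        return a < b - spec.tie_tolerance
    return a > b + spec.tie_tolerance
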