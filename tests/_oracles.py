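"""Independent reference implementations used only by the test suite.

These deliberately avoid the package's vectorized metric code paths:
metrics come from scipy (or brute-force pair counting for AUC) and the
greedy reference re-derives every step by building each tentative weight
vector explicitly and scanning candidates with plain Python loops.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

TIE_TOL = 1e-12


def ref_metric(name: str, scores: np.ndarray, y: np.ndarray) -> float:
    scores = np.asarray(scores, float)
    y = np.asarray(y, float)
    if name == "pval":
        a, b = scores[y == 1.0], scores[y == 0.0]
        if np.var(a) == 0.0 and np.var(b) == 0.0:
            return 1.0 if a.mean() == b.mean() else np.nextafter(0.0, 1.0)
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    if name == "auc":
        cases = scores[y == 1.0]
        ctrls = scores[y == 0.0]
        wins = 0.0
        for c in cases:
            for d in ctrls:
                if c > d:
                    wins += 1.0
                elif c == d:
                    wins += 0.5
        return wins / (len(cases) * len(ctrls))
    if name == "corr":
        if np.std(scores) == 0.0:
            return 0.0
        return float(stats.pearsonr(scores, y).statistic)
    raise ValueError(name)


def _better(name: str, a: float, b: float) -> bool:
    if name == "pval":
        return a < b - TIE_TOL
    return a > b + TIE_TOL


def greedy_reference(
    X: np.ndarray, y: np.ndarray, name: str, limit: int
) -> list[tuple[int, int, float]]:
    """Exhaustive per-step reference: returns [(index, sign, metric), ...].

    Each step rebuilds every candidate weight vector, scores it with the
    scipy-based metrics above, and keeps the earliest candidate (column
    order, +1 before -1) that no other candidate beats beyond tolerance
    and that (after the first step) strictly improves the incumbent.
    Columns nearly perfectly correlated (either sign) with an already
    selected column are ineligible, checked here with scipy's pearsonr.
    """
    p = X.shape[1]
    default = {"pval": 1.0, "auc": 0.5, "corr": 0.0}[name]
    weights = np.zeros(p)
    chosen: list[tuple[int, int, float]] = []
    incumbent = default
    while len(chosen) < limit:
        first = not chosen
        signs = (1,) if (first and name in ("pval", "auc")) else (1, -1)
        candidates = []
        for k in range(p):
            if weights[k] != 0:
                continue
            if any(
                abs(stats.pearsonr(X[:, k], X[:, j]).statistic) >= 1 - 1e-4
                for j, _, _ in chosen
            ):
                continue
            for s in signs:
                w = weights.copy()
                w[k] = s
                candidates.append((k, s, ref_metric(name, X @ w, y)))
        if not candidates:
            break
        values = [v for _, _, v in candidates]
        best = min(values) if name == "pval" else max(values)
        pick = None
        for k, s, v in candidates:
            if _better(name, best, v):
                continue
            if not first and not _better(name, v, incumbent):
                continue
            pick = (k, s, v)
            break
        if pick is None or (first and best == default):
            break
        weights[pick[0]] = pick[1]
        incumbent = pick[2]
        chosen.append(pick)
    return chosen


def ols_reference(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Intercept and slope of y on x via the normal equations, solved with
    a dense linear solve rather than closed-form moments."""
    A = np.column_stack([np.ones_like(x), x])
    coef = np.linalg.solve(A.T @ A, A.T @ y)
    return float(coef[0]), float(coef[1])


def log_ray_ratio(n: int) -> float:
    return math.log(3**n - 1) - math.log(n) - n * math.log(2.0)
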