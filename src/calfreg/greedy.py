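"""The coarse-weight greedy forward-selection engine.

Starting from the all-zero weight vector, each iteration tentatively flips
one remaining zero weight to +1 or -1, evaluates the chosen metric of the
tentative score vector ``X @ beta`` against the response, and keeps the
earliest candidate (column order, +1 before -1 at a tie) that no later
candidate beats beyond the tie tolerance.  After the first step a candidate
must also strictly improve on the incumbent metric.  Fitting stops when no
candidate improves, when the number of nonzero weights reaches the limit L,
or when no unselected predictors remain.

The fit is fully deterministic; ties are broken by input column order.
Candidates whose column is exactly or nearly parallel to an already
selected column are ineligible: a (near) duplicate of a used predictor
carries no new direction, only a disguised integer reweighting, and
skipping it is what makes the fit invariant to duplicated columns and
keeps at most one member of any near-collinear pair in the model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .metrics import MetricSpec, is_better, metric_columns, metric_value
from .preprocess import Dataset

DEFAULT_LIMIT = 20

#: a free column whose absolute correlation with any already-selected
#: column is within this distance of 1 is treated as a duplicate of it
COLLINEAR_TOL = 1e-4

__all__ = ["CalfModel", "candidate_metric", "select_step", "calf_fit", "predict_scores"]


@dataclass(frozen=True)
class CalfModel:
    """A fitted coarse linear model.

    ``weights`` is a p-vector over {-1, 0, +1}; ``selection_order`` records
    (predictor index, sign) in the order chosen, and ``metric_trace`` the
    metric value after each accepted step.
    """

    weights: np.ndarray
    selection_order: list[tuple[int, int]]
    metric_trace: list[float]
    metric_spec: MetricSpec
    limit: int
    predictor_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=int)
        object.__setattr__(self, "weights", w)
        if not np.all(np.isin(w, (-1, 0, 1))):
            raise ValueError("weights must be in {-1, 0, +1}")
        nz = {int(i) for i in np.flatnonzero(w)}
        if nz != {i for i, _ in self.selection_order}:
            raise ValueError("selection_order inconsistent with weights")
        for i, s in self.selection_order:
            if w[i] != s:
                raise ValueError("selection_order signs inconsistent with weights")
        if len(self.selection_order) > self.limit:
            raise ValueError("more selections than the limit allows")

    @property
    def n_selected(self) -> int:
        return len(self.selection_order)

    @property
    def final_metric(self) -> float:
        if not self.metric_trace:
            return self.metric_spec.default_value
        return self.metric_trace[-1]

    def selected_names(self) -> list[str]:
        return [self.predictor_names[i] for i, _ in self.selection_order]

    def flipped(self) -> "CalfModel":
        """The same fit reported under the opposite class orientation
        (control and case labels exchanged): every weight sign reverses.
        Flipping both labels and weights leaves the p-value and the AUC
        unchanged; for a correlation fit (weights only) the trace negates.
        """
        if self.metric_spec.name == "corr":
            trace = [-v for v in self.metric_trace]
        else:
            trace = list(self.metric_trace)
        return CalfModel(
            weights=-self.weights,
            selection_order=[(i, -s) for i, s in self.selection_order],
            metric_trace=trace,
            metric_spec=self.metric_spec,
            limit=self.limit,
            predictor_names=self.predictor_names,
        )

    def summary(self) -> str:
        """Signed-sum notation, e.g. ``+ MMP7 - MMP1 + TSHB``."""
        if not self.selection_order:
            return "(no predictors selected)"
        parts = []
        for i, s in self.selection_order:
            name = self.predictor_names[i] if self.predictor_names else f"x{i}"
            parts.append(f"{'+' if s > 0 else '-'} {name}")
        return " ".join(parts)

    def to_dict(self) -> dict:
        return {
            "metric": self.metric_spec.name,
            "limit": self.limit,
            "n_selected": self.n_selected,
            "final_metric": self.final_metric,
            "selection": [
                {
                    "index": int(i),
                    "name": self.predictor_names[i] if self.predictor_names else None,
                    "sign": int(s),
                    "metric_after": self.metric_trace[rank],
                }
                for rank, (i, s) in enumerate(self.selection_order)
            ],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def candidate_metric(
    dataset: Dataset, weights: np.ndarray, k: int, sign: int, spec: MetricSpec
) -> float:
    """Metric of the tentative score vector ``X @ (weights + sign * e_k)``."""
    if weights[k] != 0:
        raise ValueError(f"predictor {k} already has a nonzero weight")
    w = np.asarray(weights, dtype=float).copy()
    w[k] = sign
    return metric_value(spec, dataset.X @ w, dataset.Y)


def select_step(
    dataset: Dataset,
    weights: np.ndarray,
    spec: MetricSpec,
    first_step: bool,
    incumbent: float | None = None,
    collinear_tol: float = COLLINEAR_TOL,
) -> tuple[int, int, float] | None:
    """One greedy step: the earliest unbeaten candidate, or None.

    Candidates are scanned in column order with +1 tried before -1.  On the
    first step only +1 is considered for the binary metrics (their p-value
    and AUC orderings are sign-symmetric, so the leading sign is a pure
    convention); for correlation both signs are tried since -1 may be
    needed to make the correlation positive.  After the first step the
    winning candidate must strictly improve on the incumbent metric.

    A free column (nearly) parallel to an already-selected column — an
    exact copy or a perturbed twin — is excluded: it offers no new
    direction, only an effective non-unit weight on a used predictor.
    """
    w = np.asarray(weights, dtype=float)
    free = np.flatnonzero(w == 0)
    if free.size == 0:
        return None
    free = free[~_duplicates_of_selected(dataset.X, w, free, collinear_tol)]
    if free.size == 0:
        return None
    base = dataset.X @ w
    both_signs = (not first_step) or spec.name == "corr"

    cols = dataset.X[:, free]
    plus = metric_columns(spec, base[:, None] + cols, dataset.Y)
    if both_signs:
        minus = metric_columns(spec, base[:, None] - cols, dataset.Y)
        # candidate order: ascending column, +1 before -1
        values = np.empty(2 * free.size)
        values[0::2] = plus
        values[1::2] = minus
        cand_index = np.repeat(free, 2)
        cand_sign = np.tile((1, -1), free.size)
    else:
        values = plus
        cand_index = free
        cand_sign = np.ones(free.size, dtype=int)

    best = values.min() if spec.better_direction == "lower" else values.max()
    if first_step:
        # degenerate: nothing distinguishes any candidate from the empty model
        if best == spec.default_value:
            return None
        threshold = None
    else:
        threshold = incumbent if incumbent is not None else metric_value(
            spec, base, dataset.Y
        )
    for c in range(values.size):
        v = float(values[c])
        if is_better(spec, best, v):
            continue  # beaten beyond tolerance by the best candidate
        if threshold is not None and not is_better(spec, v, threshold):
            continue
        return int(cand_index[c]), int(cand_sign[c]), v
    return None


def _duplicates_of_selected(
    X: np.ndarray, weights: np.ndarray, free: np.ndarray, tol: float
) -> np.ndarray:
    """Mask over ``free``: True where the column is within ``tol`` of being
    perfectly correlated (either sign) with some selected column."""
    sel = np.flatnonzero(weights != 0)
    if sel.size == 0 or tol <= 0:
        return np.zeros(free.size, dtype=bool)
    A = X[:, free]
    B = X[:, sel]
    norm_a = np.linalg.norm(A, axis=0)
    norm_b = np.linalg.norm(B, axis=0)
    denom = np.outer(norm_a, np.where(norm_b == 0, 1.0, norm_b))
    denom[denom == 0] = 1.0
    r = np.abs(A.T @ B) / denom
    return np.any(r >= 1.0 - tol, axis=1)


def calf_fit(
    dataset: Dataset,
    spec: MetricSpec,
    limit: int = DEFAULT_LIMIT,
    collinear_tol: float = COLLINEAR_TOL,
) -> CalfModel:
    """Fit the greedy ±1-weight model with at most ``limit`` nonzero weights."""
    p = dataset.n_predictors
    if not 1 <= limit <= p:
        raise ValueError(f"limit must be in [1, {p}], got {limit}")
    if spec.requires_binary and dataset.response_kind != "binary":
        raise ValueError(f"metric {spec.name!r} requires a binary response")
    if spec.name == "corr" and dataset.response_kind != "continuous":
        raise ValueError("metric 'corr' requires a continuous response")

    weights = np.zeros(p, dtype=int)
    order: list[tuple[int, int]] = []
    trace: list[float] = []
    incumbent = spec.default_value
    while len(order) < limit:
        step = select_step(
            dataset,
            weights,
            spec,
            first_step=not order,
            incumbent=incumbent,
            collinear_tol=collinear_tol,
        )
        if step is None:
            break
        k, sign, value = step
        weights[k] = sign
        order.append((k, sign))
        trace.append(value)
        incumbent = value
    return CalfModel(
        weights=weights,
        selection_order=order,
        metric_trace=trace,
        metric_spec=spec,
        limit=limit,
        predictor_names=list(dataset.predictor_names),
    )


def predict_scores(model: CalfModel, X_new: np.ndarray) -> np.ndarray:
    """Apply the fitted weights to new rows: ``X_new @ weights``.

    Columns must be in training order (and on the training z-score scale
    for the score to be comparable)."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.weights.size:
        raise ValueError(
            f"expected {model.weights.size} columns, got {X_new.shape[1]}"
        )
    return X_new @ model.weights.astype(float)
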