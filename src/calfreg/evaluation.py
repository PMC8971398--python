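"""Model assessment: permutation empirical p-values, predictor popularity
over random subject subsets, cross-validation (plain and permuted-target),
the limit sweep, and OLS rescaling of the coarse score.

Four complementary checks guard against overfitting a greedy coarse model:

* a *permutation test* refits the model D times on response vectors with
  their entries randomly permuted and reports the empirical p-value
  (E + 1)/(D + 1), E being the number of permuted fits whose final metric
  is at least as good as the true fit's;
* *popularity* refits on many random subject subsets (stratified per class
  for a binary response) and counts how often each predictor is selected —
  informative predictors should form a "cliff" above the rest;
* *cross-validation* fits on a kept fraction of subjects and scores the
  weights on the complementary holdout, optionally permuting the response
  first to provide the matching null distribution;
* a *limit sweep* repeats the permutation test over L = 1, 2, ... and
  recommends the smallest L whose empirical p-value is about minimal.

Each kept subset is re-z-scored before fitting, and the kept subset's
column means/sds are applied to the holdout rows, so no holdout
information leaks into the fit.  A column that is constant within a kept
subset is zeroed for that trial; a zero column can never improve the
metric and is therefore never selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .greedy import CalfModel, calf_fit, predict_scores
from .metrics import MetricSpec, auc, is_better, pearson
from .preprocess import Dataset

__all__ = [
    "PermutationResult",
    "PopularityTable",
    "CrossValResult",
    "AdjustedModel",
    "SweepResult",
    "permutation_test",
    "popularity",
    "sorted_popularity_curve",
    "cross_validate",
    "adjust_model",
    "limit_sweep",
]


# ---------------------------------------------------------------------------
# result containers

@dataclass(frozen=True)
class PermutationResult:
    true_metric: float
    permuted_metrics: np.ndarray
    E: int
    D: int

    @property
    def empirical_p(self) -> float:
        return (self.E + 1) / (self.D + 1)


@dataclass(frozen=True)
class PopularityTable:
    names: list[str]
    counts: np.ndarray
    trials: int
    keep_fraction: float
    limit: int
    stratified: bool
    seed: int


@dataclass(frozen=True)
class CrossValResult:
    """Per-trial holdout and training metrics; NaN marks a trial whose
    holdout could not be scored (single-class holdout or a degenerate
    score vector)."""

    holdout_metrics: np.ndarray
    train_metrics: np.ndarray
    trials: int
    keep_fraction: float
    seed: int
    permuted_target: bool

    @property
    def n_invalid(self) -> int:
        return int(np.isnan(self.holdout_metrics).sum())

    @property
    def mean_holdout(self) -> float:
        return float(np.nanmean(self.holdout_metrics))

    @property
    def mean_train(self) -> float:
        return float(np.nanmean(self.train_metrics))


@dataclass(frozen=True)
class AdjustedModel:
    """Affine rescaling ``b + m * (X @ beta)`` of a coarse score by simple
    OLS of the response on the score; permits MSE comparison without
    changing any linearly invariant metric (when m > 0)."""

    base: CalfModel
    intercept: float
    multiplier: float
    mse: float


@dataclass(frozen=True)
class SweepResult:
    limits: list[int]
    final_metrics: list[float]
    empirical_ps: list[float]
    n_selected: list[int]
    recommended_limit: int
    rel_tol: float = 0.25


# ---------------------------------------------------------------------------
# subset machinery

def _kept_indices(
    rng: np.random.Generator, dataset: Dataset, keep_fraction: float
) -> np.ndarray:
    """Rows kept for one trial, without replacement; stratified per class
    for a binary response (about keep_fraction of each group)."""
    if not 0.0 < keep_fraction < 1.0:
        raise ValueError("keep_fraction must be in (0, 1)")
    if dataset.response_kind == "binary":
        kept: list[np.ndarray] = []
        for label in (0.0, 1.0):
            members = np.flatnonzero(dataset.Y == label)
            k = int(round(keep_fraction * members.size))
            k = max(k, 2)
            if k >= members.size:
                raise ValueError(
                    f"keep_fraction {keep_fraction} leaves no holdout for "
                    f"class {int(label)} (size {members.size})"
                )
            kept.append(rng.choice(members, size=k, replace=False))
        return np.sort(np.concatenate(kept))
    n = dataset.n_samples
    k = max(int(round(keep_fraction * n)), 3)
    if k >= n:
        raise ValueError("kept subset leaves no holdout rows")
    return np.sort(rng.choice(n, size=k, replace=False))


def _rezscore(X_kept: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Z-score a kept submatrix column-wise; zero-variance columns are
    zeroed (they cannot inform the fit) and their sd flagged as 0."""
    mean = X_kept.mean(axis=0)
    sd = np.std(X_kept, axis=0, ddof=1)
    Z = np.zeros_like(X_kept)
    ok = sd > 0.0
    Z[:, ok] = (X_kept[:, ok] - mean[ok]) / sd[ok]
    return Z, mean, sd


def _subset_dataset(dataset: Dataset, rows: np.ndarray, Y: np.ndarray) -> tuple[
    Dataset, np.ndarray, np.ndarray
]:
    Z, mean, sd = _rezscore(dataset.X[rows])
    sub = Dataset(
        X=Z,
        predictor_names=dataset.predictor_names,
        Y=Y[rows],
        response_kind=dataset.response_kind,
    )
    return sub, mean, sd


def _apply_scaling(
    X_rows: np.ndarray, mean: np.ndarray, sd: np.ndarray
) -> np.ndarray:
    Z = np.zeros_like(X_rows)
    ok = sd > 0.0
    Z[:, ok] = (X_rows[:, ok] - mean[ok]) / sd[ok]
    return Z


# ---------------------------------------------------------------------------
# operations

def permutation_test(
    dataset: Dataset,
    spec: MetricSpec,
    limit: int,
    reps: int,
    seed: int | np.random.Generator,
) -> PermutationResult:
    """Empirical p-value of the fit: refit on ``reps`` permuted responses.

    A permuted fit counts toward E when its final metric is at least as
    good as the true metric (ties count, the conservative convention).
    """
    if reps < 1:
        raise ValueError("need at least one permutation")
    rng = np.random.default_rng(seed)
    true_model = calf_fit(dataset, spec, limit)
    true_metric = true_model.final_metric
    permuted = np.empty(reps)
    for d in range(reps):
        y_perm = rng.permutation(dataset.Y)
        perm_data = Dataset(
            X=dataset.X,
            predictor_names=dataset.predictor_names,
            Y=y_perm,
            response_kind=dataset.response_kind,
        )
        permuted[d] = calf_fit(perm_data, spec, limit).final_metric
    E = int(sum(1 for v in permuted if not is_better(spec, true_metric, float(v))))
    return PermutationResult(
        true_metric=true_metric, permuted_metrics=permuted, E=E, D=reps
    )


def popularity(
    dataset: Dataset,
    spec: MetricSpec,
    limit: int,
    trials: int,
    keep_fraction: float = 0.9,
    seed: int = 0,
) -> PopularityTable:
    """Selection counts of every predictor over refits on random subsets."""
    if trials < 1:
        raise ValueError("need at least one trial")
    rng = np.random.default_rng(seed)
    counts = np.zeros(dataset.n_predictors, dtype=int)
    for _ in range(trials):
        rows = _kept_indices(rng, dataset, keep_fraction)
        sub, _, _ = _subset_dataset(dataset, rows, dataset.Y)
        model = calf_fit(sub, spec, limit)
        for i, _sign in model.selection_order:
            counts[i] += 1
    return PopularityTable(
        names=list(dataset.predictor_names),
        counts=counts,
        trials=trials,
        keep_fraction=keep_fraction,
        limit=limit,
        stratified=dataset.response_kind == "binary",
        seed=seed if isinstance(seed, int) else -1,
    )


def sorted_popularity_curve(
    table: PopularityTable,
) -> tuple[list[tuple[str, int]], int]:
    """Counts sorted descending (stable at ties) plus an advisory cliff rank.

    The cliff rank is the number of predictors before the largest drop in
    consecutive sorted counts — a suggestion for the size of the
    informative pool, not a decision.
    """
    order = np.argsort(-table.counts, kind="stable")
    curve = [(table.names[i], int(table.counts[i])) for i in order]
    sorted_counts = np.array([c for _, c in curve])
    if sorted_counts.size < 2:
        return curve, sorted_counts.size
    drops = sorted_counts[:-1] - sorted_counts[1:]
    cliff_rank = int(np.argmax(drops)) + 1
    return curve, cliff_rank


def cross_validate(
    dataset: Dataset,
    spec: MetricSpec,
    limit: int,
    trials: int,
    keep_fraction: float = 0.9,
    seed: int | np.random.Generator = 0,
    permute_target: bool = False,
) -> CrossValResult:
    """Fit on kept subsets, score the weights on the complementary rows.

    The holdout metric is the Pearson correlation for a continuous
    response and the AUC for a binary one.  With ``permute_target`` the
    whole response vector is freshly permuted at the start of every trial,
    giving the matching null distribution of holdout metrics.
    """
    if trials < 1:
        raise ValueError("need at least one trial")
    rng = np.random.default_rng(seed)
    holdout = np.full(trials, np.nan)
    train = np.full(trials, np.nan)
    all_rows = np.arange(dataset.n_samples)
    for t in range(trials):
        Y = rng.permutation(dataset.Y) if permute_target else dataset.Y
        work = (
            dataset
            if not permute_target
            else Dataset(
                X=dataset.X,
                predictor_names=dataset.predictor_names,
                Y=Y,
                response_kind=dataset.response_kind,
            )
        )
        rows = _kept_indices(rng, work, keep_fraction)
        sub, mean, sd = _subset_dataset(work, rows, Y)
        model = calf_fit(sub, spec, limit)
        train[t] = model.final_metric
        out_rows = np.setdiff1d(all_rows, rows, assume_unique=True)
        scores = predict_scores(model, _apply_scaling(work.X[out_rows], mean, sd))
        y_out = Y[out_rows]
        if dataset.response_kind == "binary":
            if len(set(y_out.tolist())) < 2:
                continue  # single-class holdout cannot be scored
            holdout[t] = auc(scores, y_out)
        else:
            if np.std(scores) == 0.0 or np.std(y_out) == 0.0:
                continue
            holdout[t] = pearson(scores, y_out)
    return CrossValResult(
        holdout_metrics=holdout,
        train_metrics=train,
        trials=trials,
        keep_fraction=keep_fraction,
        seed=seed if isinstance(seed, int) else -1,
        permuted_target=permute_target,
    )


def adjust_model(model: CalfModel, dataset: Dataset) -> AdjustedModel:
    """Closed-form OLS of Y on the coarse score ``s = X @ beta``.

    Returns intercept b, slope m and the mean squared residual of
    ``b + m * s``; m is positive exactly when the score correlates
    positively with the response, and an affine map with m > 0 leaves the
    p-value, AUC and correlation of the score unchanged.
    """
    if model.n_selected == 0:
        raise ValueError("model has no nonzero weights")
    s = predict_scores(model, dataset.X)
    sc = s - s.mean()
    var = sc @ sc
    if var == 0.0:
        raise ValueError("score vector has zero variance")
    y = dataset.Y
    m = float(sc @ (y - y.mean()) / var)
    b = float(y.mean() - m * s.mean())
    resid = y - (b + m * s)
    return AdjustedModel(
        base=model, intercept=b, multiplier=m, mse=float(resid @ resid / len(y))
    )


def limit_sweep(
    dataset: Dataset,
    spec: MetricSpec,
    limits: list[int] | range,
    reps: int,
    seed: int,
    rel_tol: float = 0.25,
) -> SweepResult:
    """One permutation test per limit L; recommend the smallest L whose
    empirical p-value is within ``rel_tol`` (relative) of the minimum."""
    limits = list(limits)
    if not limits:
        raise ValueError("empty limit range")
    streams = np.random.SeedSequence(seed).spawn(len(limits))
    metrics, ps, nsel = [], [], []
    for L, stream in zip(limits, streams):
        res = permutation_test(dataset, spec, L, reps, np.random.default_rng(stream))
        model = calf_fit(dataset, spec, L)
        metrics.append(res.true_metric)
        ps.append(res.empirical_p)
        nsel.append(model.n_selected)
    p_min = min(ps)
    recommended = min(
        L for L, p in zip(limits, ps) if p <= p_min * (1.0 + rel_tol)
    )
    return SweepResult(
        limits=limits,
        final_metrics=metrics,
        empirical_ps=ps,
        n_selected=nsel,
        recommended_limit=recommended,
        rel_tol=rel_tol,
    )
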