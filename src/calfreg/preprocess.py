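"""Input validation and normalization.

CALF assumes predictors have already been corrected for confounders and are
supplied as plain numeric columns; here they are converted to z-scores
(sample, n-1 denominator).  A binary response is kept as 0/1; a continuous
response is itself z-scored.  Missing or non-finite values are rejected
outright — imputation is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

ResponseKind = Literal["binary", "continuous"]

__all__ = [
    "Dataset",
    "zscore_columns",
    "encode_response",
    "build_dataset",
    "read_csv",
    "write_csv",
]


@dataclass(frozen=True)
class Dataset:
    """A normalized regression problem.

    Attributes
    ----------
    X : (N, p) float array
        Predictor matrix, every column z-scored (mean 0, sample sd 1).
    predictor_names : list of str
        Column labels, in the original input order.  Order matters: the
        greedy fit breaks metric ties in favor of the earliest column.
    Y : (N,) float array
        Response — 0/1 for binary, z-scores for continuous.
    response_kind : {"binary", "continuous"}
    """

    X: np.ndarray
    predictor_names: list[str]
    Y: np.ndarray
    response_kind: ResponseKind
    group_sizes: tuple[int, int] | None = field(default=None)

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        Y = np.asarray(self.Y, dtype=float)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Y", Y)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if Y.shape != (X.shape[0],):
            raise ValueError("Y length must match the number of rows of X")
        if len(self.predictor_names) != X.shape[1]:
            raise ValueError("predictor_names length must match columns of X")
        if self.response_kind == "binary" and self.group_sizes is None:
            n1 = int(np.sum(Y == 1.0))
            object.__setattr__(self, "group_sizes", (len(Y) - n1, n1))

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_predictors(self) -> int:
        return self.X.shape[1]


def _sample_sd(values: np.ndarray, axis: int = 0) -> np.ndarray:
    return np.std(values, axis=axis, ddof=1)


def zscore_columns(
    values: np.ndarray, names: Sequence[str] | None = None
) -> np.ndarray:
    """Z-score every column of ``values`` using the sample (n-1) sd.

    Raises ``ValueError`` naming the offending column if any column has
    zero variance — a constant predictor carries no direction.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite values in predictor matrix")
    if values.shape[0] < 3:
        raise ValueError("need at least 3 rows to z-score")
    sd = _sample_sd(values)
    # ptp catches exactly-constant columns whose accumulated mean is inexact
    constant = (sd == 0.0) | (np.ptp(values, axis=0) == 0.0)
    if np.any(constant):
        bad = int(np.flatnonzero(constant)[0])
        label = names[bad] if names is not None else f"column {bad}"
        raise ValueError(f"zero variance in predictor {label!r}")
    return (values - values.mean(axis=0)) / sd


def encode_response(values: np.ndarray, kind: ResponseKind) -> np.ndarray:
    """Return the response in the form the fit expects.

    Binary responses must already be coded 0/1 with both classes present
    and are returned verbatim; continuous responses are z-scored.
    """
    y = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in response")
    if kind == "binary":
        uniq = np.unique(y)
        if not np.all(np.isin(uniq, (0.0, 1.0))):
            raise ValueError("binary response must contain only 0 and 1")
        if uniq.size < 2:
            raise ValueError("binary response must contain both classes")
        if np.sum(y == 0.0) < 2 or np.sum(y == 1.0) < 2:
            raise ValueError("each class needs at least 2 members")
        return y
    if kind == "continuous":
        sd = _sample_sd(y)
        if sd == 0.0:
            raise ValueError("continuous response has zero variance")
        return (y - y.mean()) / sd
    raise ValueError(f"unknown response kind {kind!r}")


def build_dataset(
    values: np.ndarray,
    column_names: Sequence[str],
    kind: ResponseKind,
    target_index: int = 0,
) -> Dataset:
    """Split a raw table into a z-scored :class:`Dataset`.

    ``target_index`` names the response column; the remaining columns keep
    their original relative order as predictors.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValueError("table needs a response column and >= 1 predictor")
    n_cols = values.shape[1]
    if not -n_cols <= target_index < n_cols:
        raise ValueError(f"target_index {target_index} out of range")
    target_index %= n_cols
    keep = [j for j in range(n_cols) if j != target_index]
    names = [str(column_names[j]) for j in keep]
    X = zscore_columns(values[:, keep], names)
    Y = encode_response(values[:, target_index], kind)
    return Dataset(X=X, predictor_names=names, Y=Y, response_kind=kind)


def read_csv(
    path: str | Path, kind: ResponseKind, target_column: int | str = 0
) -> Dataset:
    """Read a headered CSV with the response in the first column by default."""
    frame = pd.read_csv(path)
    if frame.isna().any().any():
        raise ValueError(f"missing values in {path}; imputation is not supported")
    if isinstance(target_column, str):
        if target_column not in frame.columns:
            raise ValueError(f"no column named {target_column!r} in {path}")
        target_index = int(frame.columns.get_loc(target_column))
    else:
        target_index = int(target_column)
    return build_dataset(
        frame.to_numpy(dtype=float), list(frame.columns), kind, target_index
    )


def write_csv(dataset: Dataset, path: str | Path, target_name: str = "target") -> None:
    """Write a Dataset back out in the standard dialect (response first)."""
    frame = pd.DataFrame(dataset.X, columns=dataset.predictor_names)
    frame.insert(0, target_name, dataset.Y)
    frame.to_csv(path, index=False)
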