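"""Synthetic cohort generator.

Produces datasets with the statistical structure the coarse-regression
claims assume: z-scored Gaussian predictors with a small planted set of
informative columns (a case/control mean shift for binary responses, a
linear signal for continuous ones), optional exact-copy columns (perfect
collinearity) and optional perturbed-copy columns with refreshed z-scores
(near collinearity).  An allele-coding mode mimics SNP matrices by
discretizing each column to {-1, 0, +1} before z-scoring.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .geometry import TERTILE_THRESHOLD, coarsen
from .preprocess import Dataset, encode_response, write_csv, zscore_columns

__all__ = [
    "SyntheticSpec",
    "make_binary_dataset",
    "make_continuous_dataset",
    "add_copies",
    "save_synthetic",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic cohort.

    ``informative`` maps column index -> effect size: for a binary
    response, the case-group mean shift (in raw sd units, before
    z-scoring); for a continuous response, the linear coefficient of that
    column in the signal.  ``copies`` lists (source column, perturbation
    sd) pairs appended after generation; sd 0 is an exact duplicate.
    """

    p: int
    n_control: int = 0
    n_case: int = 0
    n: int = 0
    informative: dict[int, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    allele_coding: bool = False
    copies: list[tuple[int, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError("need at least one predictor")
        for j in self.informative:
            if not 0 <= j < self.p:
                raise ValueError(f"informative index {j} out of range")
        for j, _sd in self.copies:
            if not 0 <= j < self.p:
                raise ValueError(f"copy source {j} out of range")
        if not all(np.isfinite(list(self.informative.values()) or [0.0])):
            raise ValueError("effect sizes must be finite")


def _names(p: int) -> list[str]:
    return [f"x{j:03d}" for j in range(p)]


def make_binary_dataset(spec: SyntheticSpec) -> Dataset:
    """Case/control cohort: standard-normal noise columns, with each
    informative column's case-group mean shifted by its effect size before
    the final z-scoring."""
    if spec.n_control < 4 or spec.n_case < 4:
        raise ValueError("each class needs at least 4 subjects")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_control + spec.n_case
    X = rng.standard_normal((n, spec.p))
    y = np.concatenate([np.zeros(spec.n_control), np.ones(spec.n_case)])
    for j, delta in spec.informative.items():
        X[y == 1.0, j] += delta
    dataset = Dataset(
        X=zscore_columns(X),
        predictor_names=_names(spec.p),
        Y=encode_response(y, "binary"),
        response_kind="binary",
    )
    return _with_copies(dataset, spec, rng)


def make_continuous_dataset(spec: SyntheticSpec) -> Dataset:
    """Continuous-response cohort: ``Y = sum_j c_j X_j + noise``, z-scored.

    In allele-coding mode the raw columns are first discretized to
    {-1, 0, +1} at the standard-normal tertile points (emulating
    minor/heterozygous/major genotype coding) and then z-scored.
    """
    if spec.n < 8:
        raise ValueError("need at least 8 subjects")
    rng = np.random.default_rng(spec.seed)
    X = rng.standard_normal((spec.n, spec.p))
    if spec.allele_coding:
        X = coarsen(X, TERTILE_THRESHOLD).astype(float)
    Xz = zscore_columns(X)
    y = np.zeros(spec.n)
    for j, coef in spec.informative.items():
        y += coef * Xz[:, j]
    if spec.noise_sd > 0:
        y += spec.noise_sd * rng.standard_normal(spec.n)
    dataset = Dataset(
        X=Xz,
        predictor_names=_names(spec.p),
        Y=encode_response(y, "continuous"),
        response_kind="continuous",
    )
    return _with_copies(dataset, spec, rng)


def add_copies(
    dataset: Dataset,
    copies: list[tuple[int, float]],
    seed: int | np.random.Generator = 0,
) -> Dataset:
    """Append twin columns: exact duplicates (perturbation sd 0, perfect
    collinearity) or noisy twins re-z-scored (near collinearity)."""
    rng = np.random.default_rng(seed)
    new_cols, new_names = [], []
    for j, sd in copies:
        col = dataset.X[:, j].copy()
        if sd > 0:
            col = col + sd * rng.standard_normal(col.size)
            col = zscore_columns(col[:, None])[:, 0]
        new_cols.append(col)
        new_names.append(f"{dataset.predictor_names[j]}_copy{sd:g}")
    if not new_cols:
        return dataset
    return Dataset(
        X=np.column_stack([dataset.X] + new_cols),
        predictor_names=dataset.predictor_names + new_names,
        Y=dataset.Y,
        response_kind=dataset.response_kind,
    )


def _with_copies(
    dataset: Dataset, spec: SyntheticSpec, rng: np.random.Generator
) -> Dataset:
    if spec.copies:
        return add_copies(dataset, spec.copies, rng)
    return dataset


def save_synthetic(
    spec: SyntheticSpec, csv_path: str | Path, spec_path: str | Path | None = None
) -> Dataset:
    """Generate per the spec and write the standard headered CSV (response
    first) plus, optionally, the spec itself as JSON."""
    dataset = (
        make_binary_dataset(spec)
        if spec.n_control or spec.n_case
        else make_continuous_dataset(spec)
    )
    write_csv(dataset, csv_path)
    if spec_path is not None:
        payload = asdict(spec)
        payload["informative"] = {str(k): v for k, v in payload["informative"].items()}
        Path(spec_path).write_text(json.dumps(payload, indent=2) + "\n")
    return dataset
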