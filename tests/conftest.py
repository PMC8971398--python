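import numpy as np
import pytest

from calfreg import Dataset, MetricSpec, SyntheticSpec, make_binary_dataset
from calfreg.preprocess import encode_response, zscore_columns


@pytest.fixture
def binary_dataset() -> Dataset:
    """Small case/control cohort with two planted predictors."""
    return make_binary_dataset(
        SyntheticSpec(
            p=8, n_control=20, n_case=16, informative={0: 2.0, 3: 1.2}, seed=11
        )
    )


@pytest.fixture
def continuous_dataset() -> Dataset:
    from calfreg import make_continuous_dataset

    return make_continuous_dataset(
        SyntheticSpec(p=10, n=60, informative={2: 1.0, 5: 0.7}, noise_sd=1.0, seed=7)
    )


@pytest.fixture(params=["pval", "auc", "corr"])
def any_spec(request) -> MetricSpec:
    return MetricSpec(request.param)


def random_dataset(rng: np.random.Generator, n: int, p: int, kind: str) -> Dataset:
    """Unstructured random dataset (used by oracle/property tests)."""
    X = zscore_columns(rng.standard_normal((n, p)))
    if kind == "binary":
        y = np.zeros(n)
        y[: n // 2] = 1.0
        y = rng.permutation(y)
    else:
        y = encode_response(rng.standard_normal(n), "continuous")
    return Dataset(
        X=X,
        predictor_names=[f"v{j}" for j in range(p)],
        Y=y,
        response_kind=kind,
    )
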