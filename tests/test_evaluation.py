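import numpy as np
import pytest

from _oracles import ols_reference
from calfreg import (
    MetricSpec,
    SyntheticSpec,
    adjust_model,
    auc,
    calf_fit,
    cross_validate,
    limit_sweep,
    make_binary_dataset,
    make_continuous_dataset,
    permutation_test,
    popularity,
    predict_scores,
    sorted_popularity_curve,
    welch_p,
)
from calfreg.evaluation import PopularityTable, _kept_indices
from calfreg.preprocess import Dataset


class TestPermutationTest:
    def test_strong_signal_gets_minimal_empirical_p(self, binary_dataset):
        res = permutation_test(binary_dataset, MetricSpec("pval"), 2, reps=99, seed=0)
        assert res.E == 0
        assert res.empirical_p == pytest.approx(1 / 100)

    def test_formula_and_bounds(self, continuous_dataset):
        res = permutation_test(
            continuous_dataset, MetricSpec("corr"), 2, reps=25, seed=3
        )
        assert res.empirical_p == (res.E + 1) / (res.D + 1)
        assert 1 / 26 <= res.empirical_p <= 1.0
        assert len(res.permuted_metrics) == 25

    def test_reproducible_given_seed(self, continuous_dataset):
        a = permutation_test(continuous_dataset, MetricSpec("corr"), 2, 20, seed=5)
        b = permutation_test(continuous_dataset, MetricSpec("corr"), 2, 20, seed=5)
        np.testing.assert_array_equal(a.permuted_metrics, b.permuted_metrics)
        assert a.E == b.E


class TestPopularity:
    def test_planted_predictor_dominates(self):
        ds = make_binary_dataset(
            SyntheticSpec(p=10, n_control=25, n_case=25, informative={4: 2.0}, seed=2)
        )
        table = popularity(ds, MetricSpec("pval"), limit=2, trials=60, seed=1)
        assert np.argmax(table.counts) == 4
        assert table.counts[4] > max(
            c for j, c in enumerate(table.counts) if j != 4
        )

    def test_counts_bounded_by_trials_times_limit(self, binary_dataset):
        table = popularity(binary_dataset, MetricSpec("auc"), 1, trials=25, seed=9)
        assert table.counts.max() <= 25
        assert table.counts.sum() <= 25 * 1

    def test_same_seed_same_table(self, continuous_dataset):
        a = popularity(continuous_dataset, MetricSpec("corr"), 2, 15, seed=4)
        b = popularity(continuous_dataset, MetricSpec("corr"), 2, 15, seed=4)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_stratified_subsets_preserve_class_balance(self, binary_dataset):
        rng = np.random.default_rng(0)
        n0, n1 = binary_dataset.group_sizes
        for _ in range(20):
            rows = _kept_indices(rng, binary_dataset, 0.9)
            y = binary_dataset.Y[rows]
            assert abs(np.sum(y == 0) - round(0.9 * n0)) <= 1
            assert abs(np.sum(y == 1) - round(0.9 * n1)) <= 1


class TestPopularityCurve:
    def test_cliff_after_rank_three(self):
        table = PopularityTable(
            names=list("abcde"),
            counts=np.array([900, 850, 820, 100, 40]),
            trials=1000, keep_fraction=0.9, limit=5, stratified=False, seed=0,
        )
        curve, cliff = sorted_popularity_curve(table)
        assert cliff == 3
        assert [n for n, _ in curve] == list("abcde")

    def test_tied_counts_keep_stable_name_order(self):
        table = PopularityTable(
            names=["z_first", "a_second"],
            counts=np.array([10, 10]),
            trials=10, keep_fraction=0.9, limit=2, stratified=False, seed=0,
        )
        curve, _ = sorted_popularity_curve(table)
        assert [n for n, _ in curve] == ["z_first", "a_second"]


class TestCrossValidate:
    def test_single_trial_shape(self, continuous_dataset):
        res = cross_validate(
            continuous_dataset, MetricSpec("corr"), 2, trials=1, seed=0
        )
        assert res.holdout_metrics.shape == (1,)
        assert np.isfinite(res.holdout_metrics[0])

    def test_permuted_target_centers_near_zero(self):
        ds = make_continuous_dataset(
            SyntheticSpec(p=15, n=80, informative={0: 1.0}, noise_sd=1.0, seed=6)
        )
        null = cross_validate(
            ds, MetricSpec("corr"), 2, trials=60, seed=7, permute_target=True
        )
        assert abs(null.mean_holdout) < 0.15

    def test_signal_separates_true_from_permuted(self):
        ds = make_continuous_dataset(
            SyntheticSpec(p=15, n=80, informative={0: 1.0, 3: 0.8}, seed=8)
        )
        spec = MetricSpec("corr")
        true = cross_validate(ds, spec, 2, trials=40, seed=1)
        null = cross_validate(ds, spec, 2, trials=40, seed=2, permute_target=True)
        assert true.mean_holdout > null.mean_holdout + 0.2

    def test_binary_holdout_uses_auc(self, binary_dataset):
        res = cross_validate(binary_dataset, MetricSpec("pval"), 2, trials=10, seed=3)
        valid = res.holdout_metrics[~np.isnan(res.holdout_metrics)]
        assert np.all((valid >= 0) & (valid <= 1))
        assert valid.mean() > 0.6  # planted signal generalizes


class TestAdjustModel:
    def test_exact_affine_recovery(self, continuous_dataset):
        model = calf_fit(continuous_dataset, MetricSpec("corr"), 3)
        s = predict_scores(model, continuous_dataset.X)
        rigged = Dataset(
            X=continuous_dataset.X,
            predictor_names=continuous_dataset.predictor_names,
            Y=2.0 + 3.0 * s,
            response_kind="continuous",
        )
        adj = adjust_model(model, rigged)
        assert adj.intercept == pytest.approx(2.0, abs=1e-10)
        assert adj.multiplier == pytest.approx(3.0, abs=1e-10)
        assert adj.mse == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, continuous_dataset):
        model = calf_fit(continuous_dataset, MetricSpec("corr"), 3)
        adj = adjust_model(model, continuous_dataset)
        s = predict_scores(model, continuous_dataset.X)
        b_ref, m_ref = ols_reference(s, continuous_dataset.Y)
        assert adj.intercept == pytest.approx(b_ref, abs=1e-10)
        assert adj.multiplier == pytest.approx(m_ref, abs=1e-10)

    def test_positive_multiplier_preserves_metrics(self, binary_dataset):
        model = calf_fit(binary_dataset, MetricSpec("pval"), 3)
        adj = adjust_model(model, binary_dataset)
        s = predict_scores(model, binary_dataset.X)
        adjusted = adj.intercept + adj.multiplier * s
        assert adj.multiplier > 0
        assert welch_p(adjusted, binary_dataset.Y) == pytest.approx(
            welch_p(s, binary_dataset.Y), abs=1e-12
        )
        assert auc(adjusted, binary_dataset.Y) == pytest.approx(
            auc(s, binary_dataset.Y), abs=1e-12
        )

    def test_empty_model_rejected(self, continuous_dataset):
        from calfreg.greedy import CalfModel

        empty = CalfModel(
            weights=np.zeros(continuous_dataset.n_predictors, dtype=int),
            selection_order=[], metric_trace=[],
            metric_spec=MetricSpec("corr"), limit=3,
        )
        with pytest.raises(ValueError):
            adjust_model(empty, continuous_dataset)


class TestLimitSweep:
    def test_saturation_freezes_n_selected(self):
        # two informative columns among pure noise: selection saturates
        ds = make_continuous_dataset(
            SyntheticSpec(p=6, n=50, informative={0: 1.5, 1: 1.0}, noise_sd=0.2, seed=5)
        )
        res = limit_sweep(ds, MetricSpec("corr"), range(1, 7), reps=9, seed=1)
        assert res.n_selected == sorted(res.n_selected)
        assert res.n_selected[-1] < 6  # stops before exhausting predictors

    def test_recommends_small_limit_for_planted_signal(self):
        ds = make_continuous_dataset(
            SyntheticSpec(
                p=12, n=90, informative={0: 0.8, 1: 0.8, 2: 0.8}, noise_sd=0.8, seed=3
            )
        )
        res = limit_sweep(ds, MetricSpec("corr"), range(1, 9), reps=49, seed=2)
        assert res.recommended_limit <= 5
        assert min(res.empirical_ps) <= 0.05
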