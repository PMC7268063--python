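import numpy as np
import pytest

from stableconn import (
    BootstrapConfig,
    SyntheticSpec,
    default_validation_configs,
    enumerate_grid,
    evaluate,
    external_validate,
    feature_dimension_report,
    generate,
    grid_search,
    run_cv,
    run_cv_multi,
    sorted_partition,
)

from conftest import brute_pearson


class TestSortedPartition:
    def test_hand_enumerable_alternation(self):
        # sorted values 1,2,3,4,5 -> folds alternate 0,1,0,1,0
        fa = sorted_partition(np.array([5.0, 1.0, 3.0, 2.0, 4.0]), k=2)
        by_fold = {
            f: sorted([5.0, 1.0, 3.0, 2.0, 4.0][i] for i in fa.test_indices(f))
            for f in range(2)
        }
        assert by_fold[0] == [1.0, 3.0, 5.0]
        assert by_fold[1] == [2.0, 4.0]

    def test_equal_fold_sizes_when_divisible(self, rng):
        fa = sorted_partition(rng.normal(size=20), k=10)
        sizes = [fa.test_indices(f).size for f in range(10)]
        assert sizes == [2] * 10

    def test_constant_trait_round_robin_over_input_order(self):
        fa = sorted_partition(np.zeros(7), k=3)
        np.testing.assert_array_equal(fa.fold_of, [0, 1, 2, 0, 1, 2, 0])

    def test_fold_balance_invariant(self, rng):
        for n, k in [(17, 5), (100, 10), (23, 10), (9, 2)]:
            fa = sorted_partition(rng.normal(size=n), k)
            sizes = [fa.test_indices(f).size for f in range(k)]
            assert max(sizes) - min(sizes) <= 1

    def test_each_fold_spans_trait_range(self, rng):
        """Round-robin over sorted order gives every fold the full spread."""
        y = rng.normal(size=100)
        fa = sorted_partition(y, 10)
        for f in range(10):
            vals = y[fa.test_indices(f)]
            assert vals.min() <= np.quantile(y, 0.15)
            assert vals.max() >= np.quantile(y, 0.85)


class TestEvaluate:
    def test_perfect_and_anti_prediction(self, rng):
        y = rng.normal(size=20)
        r, mse = evaluate(y, y)
        assert r == pytest.approx(1.0) and mse == 0.0
        r, _ = evaluate(-(y - y.mean()), y)
        assert r == pytest.approx(-1.0)

    def test_hand_summed_oracle(self):
        pred, actual = [1.0, 2.0, 3.0], [2.0, 4.0, 9.0]
        r, mse = evaluate(np.array(pred), np.array(actual))
        assert r == pytest.approx(brute_pearson(pred, actual), abs=1e-12)
        assert mse == pytest.approx(((1 - 2) ** 2 + (2 - 4) ** 2 + (3 - 9) ** 2) / 3)

    def test_constant_prediction_scores_zero(self):
        r, mse = evaluate(np.ones(5), np.arange(5.0))
        assert r == 0.0 and mse > 0


class TestGridEnumeration:
    def test_without_replacement_has_180_configs(self):
        assert len(enumerate_grid("without_replacement")) == 180

    def test_with_replacement_has_36_configs(self):
        assert len(enumerate_grid("with_replacement")) == 36

    def test_both_schemes_total_216(self):
        total = len(enumerate_grid("without_replacement")) + len(
            enumerate_grid("with_replacement")
        )
        assert total == 216

    def test_validation_protocol_has_8_configs(self):
        assert len(default_validation_configs()) == 8


class TestRunCv:
    def test_noiseless_linear_trait_near_perfect(self):
        spec = SyntheticSpec(
            n_subjects=120, n_nodes=30, n_signal_edges=5, noise_sd=0.0, seed=3
        )
        ds, _ = generate(spec)
        res = run_cv(ds, "score", "baseline", "ridge", k=5)
        assert res.mean_R > 0.99

    def test_null_trait_centered_near_zero(self):
        means = []
        for seed in (3, 4, 5):
            spec = SyntheticSpec(n_subjects=150, n_nodes=40, n_signal_edges=0, seed=seed)
            ds, _ = generate(spec)
            means.append(run_cv(ds, "score", "baseline", "ridge").mean_R)
        assert abs(float(np.mean(means))) < 0.15

    def test_same_seed_bit_identical(self, small_cohort):
        ds, _ = small_cohort
        cfg = BootstrapConfig("without_replacement", nb=20, fp=0.6, bp=0.7, seed=9)
        r1 = run_cv(ds, "score", cfg, "cpm_p", k=5)
        r2 = run_cv(ds, "score", cfg, "cpm_p", k=5)
        np.testing.assert_array_equal(r1.per_fold_R, r2.per_fold_R)
        np.testing.assert_array_equal(r1.per_fold_MSE, r2.per_fold_MSE)
        assert r1.hyperparams_chosen == r2.hyperparams_chosen

    def test_multi_shares_selection_across_models(self, small_cohort):
        ds, _ = small_cohort
        multi = run_cv_multi(ds, "score", "baseline", ["cpm_p", "ridge"], k=5)
        solo = run_cv(ds, "score", "baseline", "ridge", k=5)
        np.testing.assert_array_equal(multi["ridge"].per_fold_R, solo.per_fold_R)

    def test_mean_excludes_failed_folds(self, small_cohort):
        ds, _ = small_cohort
        # a very strict config empties some folds' negative set
        cfg = BootstrapConfig("without_replacement", nb=20, fp=1.0, bp=0.5, seed=2)
        res = run_cv(ds, "score", cfg, "cpm_n", k=5)
        ok = ~np.isnan(res.per_fold_R)
        assert res.mean_R == pytest.approx(float(res.per_fold_R[ok].mean()))


class TestGridSearch:
    def test_matches_per_config_run_cv(self, small_cohort):
        ds, _ = small_cohort
        gr = grid_search(
            ds, "score", "without_replacement", "ridge",
            nb_grid=(10, 20), bp_grid=(0.7,), fp_grid=(0.6, 0.8), seed=4, k=5,
        )
        assert len(gr.results) + len(gr.failed) == 4
        for cfg, per_kind in gr.results.items():
            solo = run_cv(ds, "score", cfg, "ridge", k=5)
            np.testing.assert_allclose(
                per_kind["ridge"].per_fold_R, solo.per_fold_R, atol=1e-12
            )

    def test_best_attains_max_mean_r(self, small_cohort):
        ds, _ = small_cohort
        gr = grid_search(
            ds, "score", "without_replacement", "cpm_p",
            nb_grid=(10, 20), bp_grid=(0.7,), fp_grid=(0.6, 0.8), seed=4, k=5,
        )
        best_r = gr.best_result("cpm_p").mean_R
        assert best_r == max(res["cpm_p"].mean_R for res in gr.results.values())


class TestFeatureDimensionReport:
    def _fake_result(self, counts):
        from stableconn.cv import PredictionResult

        k = len(counts)
        return PredictionResult(
            model_kind="ridge", config="baseline",
            per_fold_R=np.zeros(k), per_fold_MSE=np.zeros(k),
            per_fold_feature_count={
                "positive": np.asarray(counts, float),
                "negative": np.asarray(counts, float),
                "combined": np.asarray(counts, float),
            },
            hyperparams_chosen=[None] * k,
        )

    def test_fold_average_and_cross_trait_mean(self):
        table = feature_dimension_report(
            {
                "traitA": {"baseline": self._fake_result([10, 20])},
                "traitB": {"baseline": self._fake_result([15, 15])},
            }
        )
        assert table.loc["traitA", "baseline"] == 15.0
        assert table.loc["mean", "baseline"] == 15.0

    def test_identical_counts_mean_is_that_count(self):
        table = feature_dimension_report(
            {t: {"m": self._fake_result([7, 7, 7])} for t in ("a", "b", "c")}
        )
        assert table.loc["mean", "m"] == 7.0


class TestExternalValidate:
    def test_train_copy_noiseless_near_perfect(self):
        spec = SyntheticSpec(
            n_subjects=100, n_nodes=25, n_signal_edges=5, noise_sd=0.0, seed=6
        )
        ds, _ = generate(spec)
        df = external_validate(ds, ds, "score", configs=["baseline"], model_kind="ridge")
        assert df.loc["baseline", "R"] > 0.99

    def test_generalizes_to_fresh_cohort_from_same_process(self):
        diffs = []
        for seed in (1, 2, 3):
            spec = SyntheticSpec(seed=seed)
            train, truth = generate(spec)
            # fresh subjects, same planted signal
            test, _ = generate(SyntheticSpec(seed=seed + 100), truth=truth)
            cfg = BootstrapConfig("without_replacement", nb=50, fp=0.8, bp=0.7, seed=seed)
            cv_r = run_cv(train, "score", cfg, "ridge").mean_R
            val = external_validate(train, test, "score", configs=[cfg], model_kind="ridge")
            diffs.append(abs(val.iloc[0]["R"] - cv_r))
        assert float(np.mean(diffs)) < 0.1

    def test_dimension_mismatch_rejected(self):
        a, _ = generate(SyntheticSpec(n_subjects=30, n_nodes=10, n_signal_edges=3, seed=0))
        b, _ = generate(SyntheticSpec(n_subjects=30, n_nodes=12, n_signal_edges=3, seed=0))
        with pytest.raises(ValueError, match="mismatch"):
            external_validate(a, b, "score")
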