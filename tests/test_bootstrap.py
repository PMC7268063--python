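import numpy as np
import pytest
from scipy import stats

from stableconn import (
    BootstrapConfig,
    SyntheticSpec,
    draw_bootstrap,
    draw_subsample,
    generate,
    screen,
    select_features,
    stability_frequencies,
    stability_frequency_path,
    threshold_stability,
)
from stableconn.bootstrap import FP_GRID, _SubsampleScreener
from stableconn.screen import spearman_rho_matrix


def wor_config(nb=100, bp=0.7, fp=0.8, alpha=0.05, seed=0):
    return BootstrapConfig("without_replacement", nb=nb, fp=fp, bp=bp, alpha=alpha, seed=seed)


class TestDrawing:
    def test_subsample_size_and_distinctness(self, rng):
        for n, bp, expect in [(10, 0.5, 5), (812, 0.25, 203), (10, 1.0, 10)]:
            idx = draw_subsample(n, bp, rng)
            assert idx.size == expect
            assert np.unique(idx).size == idx.size
            assert idx.min() >= 0 and idx.max() < n

    def test_full_fraction_returns_whole_index_set(self, rng):
        idx = draw_subsample(10, 1.0, rng)
        np.testing.assert_array_equal(np.sort(idx), np.arange(10))

    def test_too_small_subsample_rejected(self, rng):
        with pytest.raises(ValueError, match="too small"):
            draw_subsample(10, 0.3, rng)

    def test_bootstrap_draws_exactly_n(self, rng):
        assert draw_bootstrap(812, rng).size == 812
        assert draw_bootstrap(1, rng).tolist() == [0]

    def test_bootstrap_distinct_fraction_near_632(self, rng):
        n, draws = 812, 1000
        fracs = [np.unique(draw_bootstrap(n, rng)).size / n for _ in range(draws)]
        assert abs(np.mean(fracs) - (1 - (1 - 1 / n) ** n)) < 0.01


class TestStabilityFrequencies:
    def test_trait_equal_to_edge_always_selected(self, rng):
        X = rng.normal(size=(40, 20))
        y = X[:, 4].copy()
        freqs = stability_frequencies(X, y, wor_config(nb=10))
        assert freqs.pos_freq[4] == 1.0

    def test_null_selection_rate_matches_alpha(self, rng):
        X = rng.normal(size=(100, 500))
        y = rng.normal(size=100)
        freqs = stability_frequencies(X, y, wor_config(nb=100, bp=0.7))
        rate = np.mean(freqs.pos_freq + freqs.neg_freq)
        assert abs(rate - 0.05) < 0.01

    def test_same_seed_reproduces_bitwise(self, rng):
        X = rng.normal(size=(50, 30))
        y = rng.normal(size=50)
        cfg = wor_config(nb=25, seed=42)
        f1 = stability_frequencies(X, y, cfg)
        f2 = stability_frequencies(X, y, cfg)
        np.testing.assert_array_equal(f1.pos_freq, f2.pos_freq)
        np.testing.assert_array_equal(f1.neg_freq, f2.neg_freq)

    def test_frequencies_are_count_multiples_and_sign_exclusive(self, rng):
        X = rng.normal(size=(60, 100))
        y = X[:, 0] - X[:, 1] + rng.normal(size=60)
        cfg = wor_config(nb=20)
        freqs = stability_frequencies(X, y, cfg)
        for f in (freqs.pos_freq, freqs.neg_freq):
            np.testing.assert_allclose(f * cfg.nb, np.round(f * cfg.nb), atol=1e-9)
        assert np.all(freqs.pos_freq + freqs.neg_freq <= 1.0 + 1e-12)

    def test_nb_path_prefix_consistency(self, rng):
        """NB=10 counts are exactly the first 10 resamples of an NB=30 run."""
        X = rng.normal(size=(50, 40))
        y = X[:, 3] + rng.normal(size=50)
        path = stability_frequency_path(
            X, y, "without_replacement", (10, 30), bp=0.6, seed=7
        )
        solo = stability_frequencies(X, y, wor_config(nb=10, bp=0.6, seed=7))
        np.testing.assert_array_equal(path[10].pos_freq, solo.pos_freq)
        np.testing.assert_array_equal(path[10].neg_freq, solo.neg_freq)

    def test_with_replacement_duplicates_enter_as_repeats(self, rng):
        """Resampled screens treat duplicated subjects as repeated rows."""
        X = rng.normal(size=(25, 10))
        y = rng.normal(size=25)
        cfg = BootstrapConfig("with_replacement", nb=5, fp=0.5, seed=11)
        freqs = stability_frequencies(X, y, cfg)
        # oracle: replay the identical streams with scipy's spearman on the
        # duplicated rows (midranks handle the induced ties)
        root = np.random.SeedSequence(11)
        pos = np.zeros(10)
        neg = np.zeros(10)
        for child in root.spawn(5):
            idx = np.random.default_rng(child).integers(0, 25, size=25)
            for j in range(10):
                r, p = stats.spearmanr(X[idx, j], y[idx])
                if p < 0.05:
                    pos[j] += r > 0
                    neg[j] += r < 0
        np.testing.assert_allclose(freqs.pos_freq, pos / 5)
        np.testing.assert_allclose(freqs.neg_freq, neg / 5)

    def test_fast_subsample_screen_equals_general_path(self, rng):
        X = rng.normal(size=(80, 60))
        X[:, 0] = 1.5  # constant
        X[:, 1] = np.round(X[:, 1] * 2)  # ties
        y = rng.normal(size=80)
        scr = _SubsampleScreener(X, y)
        for m in (40, 56):
            idx = rng.choice(80, m, replace=False)
            np.testing.assert_allclose(
                scr.rho(idx), spearman_rho_matrix(X[idx], y[idx]), atol=1e-12
            )


class TestThresholding:
    def test_simple_threshold(self):
        from stableconn import StabilityFrequencies

        freqs = StabilityFrequencies(
            pos_freq=np.array([1.0, 0.4]), neg_freq=np.array([0.0, 0.0]), nb=10
        )
        fs = threshold_stability(freqs, 0.5)
        assert fs.positive.tolist() == [0] and fs.negative.size == 0

    def test_full_stability_attainable_at_unit_threshold(self):
        from stableconn import StabilityFrequencies

        freqs = StabilityFrequencies(
            pos_freq=np.array([1.0]), neg_freq=np.array([0.0]), nb=50
        )
        assert threshold_stability(freqs, 1.0).positive.tolist() == [0]

    def test_sets_nest_as_threshold_rises(self, rng):
        from stableconn import StabilityFrequencies

        nb = 20
        freqs = StabilityFrequencies(
            pos_freq=rng.integers(0, nb + 1, size=200) / nb,
            neg_freq=np.zeros(200),
            nb=nb,
        )
        prev = None
        for fp in FP_GRID:
            cur = set(threshold_stability(freqs, fp).positive.tolist())
            if prev is not None:
                assert cur <= prev
            prev = cur


class TestSelectionQuality:
    """Statistical behaviour of stability selection on planted-signal data."""

    def test_precision_beats_baseline_under_contamination(self):
        wins = 0
        for seed in range(10):
            ds, truth = generate(SyntheticSpec(seed=seed).contaminated())
            X, y = ds.features, ds.traits["score"]
            signal = set(truth.signal_edges.tolist())
            _, base = screen(X, y)
            boot = select_features(X, y, wor_config(nb=100, bp=0.7, fp=0.8, seed=seed))
            def precision(sel):
                sel = set(sel.tolist())
                return len(sel & signal) / len(sel) if sel else 0.0
            if precision(boot.combined) > precision(base.combined):
                wins += 1
        assert wins >= 9

    def test_stable_set_overlaps_baseline_set(self):
        """Stability-selected edges are almost all baseline-significant too."""
        ds, _ = generate(SyntheticSpec(seed=2).contaminated())
        X, y = ds.features, ds.traits["score"]
        _, base = screen(X, y)
        boot = select_features(X, y, wor_config(nb=100, bp=0.7, fp=0.8, seed=2))
        overlap = np.intersect1d(boot.combined, base.combined).size
        assert overlap / max(1, boot.combined.size) > 0.9


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(scheme="bogus", nb=10, fp=0.5, bp=0.5),
            dict(scheme="without_replacement", nb=0, fp=0.5, bp=0.5),
            dict(scheme="without_replacement", nb=10, fp=1.5, bp=0.5),
            dict(scheme="without_replacement", nb=10, fp=0.5, bp=None),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BootstrapConfig(**kwargs)

    def test_with_replacement_ignores_bp(self):
        cfg = BootstrapConfig("with_replacement", nb=10, fp=0.5)
        assert cfg.bp is None
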