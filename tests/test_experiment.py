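import numpy as np
import pandas as pd
import pytest

from sabrrad.experiment import (
    BootstrapForestExperiment,
    ExperimentConfig,
    bootstrap_split,
    decimate_test,
    inter_corr_filter,
    oob_operating_point,
    train_rf,
    volume_corr_filter,
)


def toy_table(n=60, p=10, signal=2.0, seed=0):
    """Feature table with the first column carrying a class shift."""
    rng = np.random.default_rng(seed)
    y = np.arange(n) % 2
    X = rng.normal(size=(n, p))
    X[:, 0] += signal * y
    return X, y


class TestBootstrapSplit:
    def test_n1_rejected(self, rng):
        with pytest.raises(ValueError, match="n >= 2"):
            bootstrap_split(1, rng)

    def test_train_is_multiset_test_is_complement(self, rng):
        for _ in range(50):
            train, test = bootstrap_split(20, rng)
            assert len(train) == 20
            assert np.intersect1d(np.unique(train), test).size == 0
            assert test.size > 0
            assert set(np.unique(train)) | set(test) == set(range(20))

    def test_mean_unique_fraction_matches_closed_form(self, rng):
        # E[unique] = n * (1 - (1 - 1/n)^n) ~ 0.635 n at n = 68
        n = 68
        uniques = [len(np.unique(bootstrap_split(n, rng)[0])) for _ in range(500)]
        expected = n * (1.0 - (1.0 - 1.0 / n) ** n)
        assert np.mean(uniques) == pytest.approx(expected, rel=0.02)
        assert round(np.mean(uniques)) == 43  # 63.2% of 68


class TestInterCorrFilter:
    def test_duplicate_column_removed_once(self, rng):
        X, y = toy_table()
        X2 = np.column_stack([X, X[:, 0]])
        keep = inter_corr_filter(X2, y)
        # exactly one of the duplicated pair (0, last) survives
        assert keep[0] != keep[-1]
        assert keep[1:-1].all()

    def test_independent_features_untouched(self, rng):
        X = rng.normal(size=(500, 8))
        y = rng.integers(0, 2, size=500)
        assert inter_corr_filter(X, y).all()

    def test_three_feature_crafted_table(self, rng):
        # f0 and f1 nearly identical (r > 0.8); f1 more label-correlated;
        # f2 independent. Hand-executed rule: drop f0, keep f1 and f2.
        n = 400
        y = np.arange(n) % 2
        base = rng.normal(size=n) + 0.8 * y
        f0 = base + rng.normal(scale=0.1, size=n)
        f1 = base + 0.7 * y
        f2 = rng.normal(size=n)
        X = np.column_stack([f0, f1, f2])
        keep = inter_corr_filter(X, y.astype(float))
        assert list(keep) == [False, True, True]

    def test_constant_feature_correlation_defined_zero(self, rng):
        X = np.column_stack([np.ones(50), rng.normal(size=50)])
        y = rng.integers(0, 2, size=50).astype(float)
        assert inter_corr_filter(X, y).all()


class TestVolumeCorrFilter:
    def test_volume_itself_removed(self, rng):
        vol = rng.uniform(10, 100, size=200)
        X = np.column_stack([vol, rng.normal(size=200)])
        keep = volume_corr_filter(X, vol)
        assert list(keep) == [False, True]

    def test_independent_feature_kept(self, rng):
        vol = rng.uniform(10, 100, size=500)
        X = rng.normal(size=(500, 3))
        assert volume_corr_filter(X, vol).all()

    def test_controlled_r_matches_direct_computation(self, rng):
        from scipy import stats as sps

        vol = rng.normal(size=300)
        for noise in (0.5, 1.0, 2.0, 4.0):
            x = vol + rng.normal(scale=noise, size=300)
            keep = volume_corr_filter(x[:, None], vol)
            r, p = sps.pearsonr(x, vol)
            assert keep[0] == (not (p < 0.05 and abs(r) > 0.5))


class TestTrainRf:
    def test_separable_toy_table_high_oob_auc(self):
        from sklearn.metrics import roc_auc_score

        X, y = toy_table(n=80, signal=4.0)
        _, oob, imp = train_rf(X, y, random_state=0)
        assert roc_auc_score(y, oob) > 0.9
        assert imp.argmax() == 0  # the planted feature dominates

    def test_permuted_labels_near_chance(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        aucs = []
        for s in range(5):
            X, y = toy_table(n=80, signal=0.0, seed=s)
            _, oob, _ = train_rf(X, rng.permutation(y), random_state=s)
            aucs.append(roc_auc_score(y, oob))
        assert abs(np.mean(aucs) - 0.5) < 0.15

    def test_fixed_seed_reproducible(self):
        X, y = toy_table()
        _, oob1, imp1 = train_rf(X, y, random_state=7)
        _, oob2, imp2 = train_rf(X, y, random_state=7)
        np.testing.assert_array_equal(oob1, oob2)
        np.testing.assert_array_equal(imp1, imp2)

    def test_single_class_rejected(self):
        X, _ = toy_table(n=20)
        with pytest.raises(ValueError, match="single class"):
            train_rf(X, np.zeros(20, dtype=int), random_state=0)


class TestOperatingPoint:
    def test_perfect_separation_attains_sens_spec_one(self):
        y = np.array([0] * 10 + [1] * 10)
        probs = np.concatenate([np.linspace(0.0, 0.3, 10), np.linspace(0.7, 1.0, 10)])
        t = oob_operating_point(probs, y)
        pred = probs >= t
        assert pred[y == 1].all() and not pred[y == 0].any()

    def test_symmetric_overlap_threshold_near_half(self, rng):
        y = np.array([0, 1] * 500)
        probs = np.clip(rng.normal(loc=np.where(y, 0.6, 0.4), scale=0.1), 0, 1)
        assert abs(oob_operating_point(probs, y) - 0.5) < 0.1

    def test_degenerate_fallback(self):
        assert oob_operating_point(np.full(10, 0.3), np.array([0, 1] * 5)) == 0.5
        assert oob_operating_point(np.linspace(0, 1, 10), np.ones(10)) == 0.5


class TestDecimate:
    def test_balanced_to_10pct(self, rng):
        labels = np.array([1] * 10 + [0] * 10)
        idx = np.arange(20)
        out = decimate_test(idx, labels, 0.10, rng)
        kept_pos = labels[out].sum()
        assert kept_pos == 1  # 1/11 ~ 9.1% is the closest feasible fraction
        assert (labels[out] == 0).sum() == 10

    def test_already_below_target_unchanged(self, rng):
        labels = np.array([1] + [0] * 19)
        idx = np.arange(20)
        np.testing.assert_array_equal(decimate_test(idx, labels, 0.10, rng), idx)

    def test_target_half_on_balanced_unchanged(self, rng):
        labels = np.array([1] * 8 + [0] * 8)
        idx = np.arange(16)
        np.testing.assert_array_equal(decimate_test(idx, labels, 0.5, rng), idx)


@pytest.fixture(scope="module")
def planted_result():
    X, y = toy_table(n=50, p=8, signal=3.0, seed=3)
    df = pd.DataFrame(X, columns=[f"f{j}" for j in range(8)])
    cfg = ExperimentConfig(n_iterations=30, inter_corr_filter=False, seed=1)
    return BootstrapForestExperiment(df, y, config=cfg).fit()


class TestExperimentEngine:
    def test_decimation_caps_test_prevalence(self):
        X, y = toy_table(n=50, p=6, signal=1.0, seed=8)
        cfg = ExperimentConfig(
            n_iterations=10, inter_corr_filter=False,
            decimate_to_prevalence=0.2, seed=3,
        )
        res = BootstrapForestExperiment(X, y, config=cfg).fit()
        for test in res.test_indices:
            frac = y[test].mean()
            # closest feasible fraction to 0.2 with >= 1 positive kept
            assert frac <= 0.35
            assert y[test].sum() >= 1

    def test_planted_signal_detected(self, planted_result):
        res = planted_result
        assert res.auc_ci[0] > 0.5
        assert res.n_completed == 30
        assert "f0" in [n for n, _ in res.top_features()]

    def test_no_leakage_and_ci_ordering(self, planted_result):
        res = planted_result
        for b, test in enumerate(res.test_indices):
            assert np.intersect1d(np.unique(res.train_indices[b]), test).size == 0
        assert res.auc_ci[0] <= res.auc_mean <= res.auc_ci[1]
        assert 0.0 <= res.auc_mean <= 1.0

    def test_summary_mentions_key_quantities(self, planted_result):
        s = planted_result.summary()
        assert "AUC" in s and "Sensitivity" in s and "Specificity" in s

    def test_aggregate_ci_closed_form(self):
        # mean and normal-theory CI of {0.6, 0.7}: 0.65 +- 1.96*sd/sqrt(2)
        from sabrrad.experiment import _normal_ci

        m, lo, hi = _normal_ci(np.array([0.6, 0.7]))
        sd = np.std([0.6, 0.7], ddof=1)
        assert m == pytest.approx(0.65)
        assert hi - m == pytest.approx(1.96 * sd / np.sqrt(2))

    def test_null_labels_ci_covers_half(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(50, 8))
        y = np.arange(50) % 2
        cfg = ExperimentConfig(n_iterations=30, inter_corr_filter=False, seed=2)
        res = BootstrapForestExperiment(X, y, config=cfg).fit()
        assert res.auc_ci[0] <= 0.5 <= res.auc_ci[1] or abs(res.auc_mean - 0.5) < 0.08

    def test_shared_seeds_across_filter_variants(self):
        X, y = toy_table(n=40, p=6, signal=1.0, seed=4)
        X = np.column_stack([X, X[:, 0] + np.random.default_rng(0).normal(scale=0.05, size=40)])
        a = BootstrapForestExperiment(
            X, y, config=ExperimentConfig(n_iterations=10, inter_corr_filter=True, seed=9)
        ).fit()
        b = BootstrapForestExperiment(
            X, y, config=ExperimentConfig(n_iterations=10, inter_corr_filter=False, seed=9)
        ).fit()
        np.testing.assert_array_equal(a.train_indices, b.train_indices)
        assert not np.array_equal(a.kept_masks, b.kept_masks)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="n_iterations"):
            ExperimentConfig(n_iterations=1)
        with pytest.raises(ValueError, match="inter_corr_threshold"):
            ExperimentConfig(inter_corr_threshold=1.2)
        with pytest.raises(ValueError, match="volumes"):
            BootstrapForestExperiment(
                np.zeros((10, 2)), np.arange(10) % 2,
                config=ExperimentConfig(volume_filter=True),
            )
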