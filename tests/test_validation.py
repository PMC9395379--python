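"""Classification, linear prediction, group statistics, FDR, power."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import prsfusion as pf
from prsfusion.errors import ConfigurationError, DataError
from prsfusion.validation import (
    MEAN_FEATURES,
    apply_prediction_model,
    classify_svm,
    fdr_correct,
    fit_prediction_model,
    group_difference,
    power_pearson,
)


def _features(n, rng, columns=MEAN_FEATURES):
    return pd.DataFrame(rng.standard_normal((n, len(columns))),
                        index=[f"s{i}" for i in range(n)], columns=list(columns))


class TestClassifySvm:
    def test_separable_classes_perfect(self, rng):
        f = _features(80, rng)
        labels = pd.Series((np.arange(80) < 40).astype(int), index=f.index)
        f.loc[labels == 1] += 5.0  # 5 SD separation
        rep = classify_svm(f, labels, n_folds=5, seed=0)
        assert rep.accuracy == 100.0
        assert rep.auc == 1.0

    def test_permuted_labels_chance_level(self, rng):
        n = 400
        f = _features(n, rng)
        labels = pd.Series(rng.permutation(np.arange(n) % 2), index=f.index)
        rep = classify_svm(f, labels, n_folds=5, seed=1)
        # binomial 95% band around 50% at n = 400: +-4.9 points
        assert 45.0 - 5.0 < rep.accuracy < 55.0 + 5.0

    def test_single_class_rejected(self, rng):
        f = _features(20, rng)
        with pytest.raises(DataError):
            classify_svm(f, pd.Series(1, index=f.index))

    def test_folds_partition_subjects(self, rng):
        from sklearn.model_selection import StratifiedKFold

        n = 60
        y = np.arange(n) % 2
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        seen = []
        for train, test in skf.split(np.zeros((n, 1)), y):
            assert not set(train) & set(test)
            seen.extend(test)
        assert sorted(seen) == list(range(n))

    def test_report_summary_format(self, rng):
        f = _features(40, rng)
        labels = pd.Series(np.arange(40) % 2, index=f.index)
        rep = classify_svm(f, labels, n_folds=4, seed=2)
        assert "ACC" in rep.summary() and "AUC" in rep.summary()


class TestPredictionModel:
    def test_exact_recovery_of_linear_target(self, rng):
        f = _features(50, rng)
        z = (f - f.mean()) / f.std(ddof=1)
        beta = np.array([1.5, -2.0, 0.5, 3.0])
        y = 4.0 + z.to_numpy() @ beta
        model = fit_prediction_model(f, pd.Series(y, index=f.index))
        np.testing.assert_allclose(model.coefficients, beta, atol=1e-10)
        assert model.intercept == pytest.approx(4.0, abs=1e-10)

    def test_null_target_small_coefficients(self, rng):
        f = _features(5000, rng)
        y = pd.Series(rng.standard_normal(5000), index=f.index)
        model = fit_prediction_model(f, y)
        assert np.abs(model.coefficients).max() < 0.08

    def test_intercept_only_signal(self, rng):
        f = _features(100, rng)
        y = pd.Series(np.full(100, 7.3), index=f.index)
        model = fit_prediction_model(f, y)
        np.testing.assert_allclose(model.coefficients, 0.0, atol=1e-10)
        assert model.intercept == pytest.approx(7.3)

    def test_too_few_subjects_rejected(self, rng):
        f = _features(5, rng)
        with pytest.raises(DataError):
            fit_prediction_model(f, pd.Series(np.zeros(5), index=f.index))

    def test_apply_to_training_noiseless(self, rng):
        f = _features(60, rng)
        y = pd.Series(f.to_numpy() @ np.array([1.0, 2.0, -1.0, 0.5]),
                      index=f.index)
        model = fit_prediction_model(f, y)
        _, res = apply_prediction_model(model, f, y)
        assert res["r"] == pytest.approx(1.0, abs=1e-10)

    def test_prediction_is_exactly_linear(self, rng):
        f = _features(30, rng)
        y = pd.Series(rng.standard_normal(30), index=f.index)
        model = fit_prediction_model(f, y)
        pred, _ = apply_prediction_model(model, f)
        mix = 0.3 * f.iloc[[0]].to_numpy() + 0.7 * f.iloc[[1]].to_numpy()
        fmix = pd.DataFrame(mix, index=["mix"], columns=f.columns)
        pmix, _ = apply_prediction_model(model, fmix)
        assert pmix.iloc[0] == pytest.approx(
            0.3 * pred.iloc[0] + 0.7 * pred.iloc[1], abs=1e-10)

    def test_constant_predictions_reported_undefined(self, rng):
        f = _features(20, rng)
        model = fit_prediction_model(
            _features(20, rng), pd.Series(np.full(20, 2.0),
                                          index=[f"s{i}" for i in range(20)]))
        _, res = apply_prediction_model(model, f, pd.Series(
            np.full(20, 1.0), index=f.index))
        assert res.get("r") is None and "note" in res

    def test_missing_feature_column_rejected(self, rng):
        f = _features(30, rng).drop(columns=["GMV_positive"])
        y = pd.Series(np.zeros(30), index=f.index)
        with pytest.raises(DataError):
            fit_prediction_model(f, y)

    def test_cross_cohort_r_near_analytic_value(self):
        # true R^2 = 0.25 -> expected transfer correlation ~ 0.5
        rs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            beta = np.sqrt(0.25) / 2.0 * np.array([1.0, -1.0, 1.0, -1.0])
            fa = _features(100, rng)
            ya = pd.Series(fa.to_numpy() @ beta
                           + np.sqrt(0.75) * rng.standard_normal(100),
                           index=fa.index)
            fb = _features(150, rng)
            yb = pd.Series(fb.to_numpy() @ beta
                           + np.sqrt(0.75) * rng.standard_normal(150),
                           index=fb.index)
            model = fit_prediction_model(fa, ya)
            _, res = apply_prediction_model(model, fb, yb)
            rs.append(res["r"])
        assert np.mean(rs) == pytest.approx(0.5, abs=0.08)


class TestGroupDifference:
    def test_identical_groups_null(self, rng):
        vals = rng.standard_normal(30)
        f = pd.DataFrame({"x": np.concatenate([vals, vals])},
                         index=[f"s{i}" for i in range(60)])
        g = pd.Series([0] * 30 + [1] * 30, index=f.index)
        tab = group_difference(f, g)
        row = tab[tab["test"] == "t"].iloc[0]
        assert row["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert row["p"] == pytest.approx(1.0)

    def test_two_group_anova_equals_t_squared(self, rng):
        f = pd.DataFrame({"x": rng.standard_normal(50)},
                         index=[f"s{i}" for i in range(50)])
        g = pd.Series(np.arange(50) % 2, index=f.index)
        tab = group_difference(f, g, equal_var=True)
        t = tab[tab["test"] == "t"]["statistic"].iloc[0]
        fstat = tab[tab["test"] == "anova"]["statistic"].iloc[0]
        assert fstat == pytest.approx(t**2, abs=1e-10)

    def test_planted_shift_detected(self, rng):
        x = np.concatenate([rng.standard_normal(100),
                            rng.standard_normal(100) + 1.0])
        f = pd.DataFrame({"x": x}, index=[f"s{i}" for i in range(200)])
        g = pd.Series([0] * 100 + [1] * 100, index=f.index)
        tab = group_difference(f, g)
        assert tab[tab["test"] == "t"]["p"].iloc[0] < 1e-8

    def test_three_groups_pairwise_and_anova(self, rng):
        f = pd.DataFrame({"x": rng.standard_normal(90)},
                         index=[f"s{i}" for i in range(90)])
        g = pd.Series(np.arange(90) % 3, index=f.index)
        tab = group_difference(f, g)
        assert (tab["test"] == "t").sum() == 3  # 3 pairwise
        assert (tab["test"] == "anova").sum() == 1

    def test_site_effect_removed(self, rng):
        n = 200
        site = pd.Series(np.array(["a", "b"])[np.arange(n) % 2],
                         index=[f"s{i}" for i in range(n)])
        x = rng.standard_normal(n) + np.where(site == "a", 3.0, 0.0)
        f = pd.DataFrame({"x": x}, index=site.index)
        g = pd.Series(np.arange(n) % 2, index=site.index)  # aligned w/ site
        with_site = group_difference(f, g, site=site)
        without = group_difference(f, g)
        assert abs(with_site[with_site["test"] == "t"]["statistic"].iloc[0]) < \
            abs(without[without["test"] == "t"]["statistic"].iloc[0])

    def test_tiny_group_rejected(self, rng):
        f = pd.DataFrame({"x": rng.standard_normal(5)},
                         index=[f"s{i}" for i in range(5)])
        g = pd.Series([0, 0, 0, 0, 1], index=f.index)
        with pytest.raises(DataError):
            group_difference(f, g)


def _bh_oracle(p):
    """Exhaustive step-up: adj_i = min over j >= rank(i) of m*p_(j)/j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    sorted_p = p[order]
    for i in range(m):
        adj[i] = min(min(m * sorted_p[j] / (j + 1) for j in range(i, m)), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


class TestFdr:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_correct([0.03]), [0.03])

    def test_all_equal_ps(self):
        np.testing.assert_allclose(fdr_correct([0.2] * 5), [0.2] * 5)

    def test_known_vector_matches_oracle(self):
        p = np.array([0.01, 0.02, 0.03, 0.5])
        np.testing.assert_allclose(fdr_correct(p), _bh_oracle(p), atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-10, max_value=1.0), min_size=1,
                    max_size=40))
    def test_matches_oracle_property(self, ps):
        p = np.asarray(ps)
        np.testing.assert_allclose(fdr_correct(p), _bh_oracle(p), atol=1e-10)

    def test_order_invariance(self, rng):
        p = rng.uniform(1e-6, 1.0, 20)
        perm = rng.permutation(20)
        np.testing.assert_allclose(fdr_correct(p)[perm], fdr_correct(p[perm]),
                                   atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            fdr_correct([0.0, 0.5])
        with pytest.raises(DataError):
            fdr_correct([0.5, 1.5])


class TestPower:
    def test_null_correlation_power_equals_alpha(self):
        for alpha in (0.01, 0.05, 0.1):
            assert power_pearson(0.0, 100, alpha) == pytest.approx(alpha, abs=1e-12)

    def test_population_scale_power_saturates(self):
        # tiny effect, population-scale sample: power is numerically 1
        assert power_pearson(0.074, 22_459, 0.05) >= 0.9995

    def test_matches_monte_carlo(self, rng):
        # empirical rejection rate of the exact Pearson test at r = 0.3,
        # n = 100 (bivariate normal simulation)
        r_true, n, alpha, reps = 0.3, 100, 0.05, 20_000
        cov = np.array([[1.0, r_true], [r_true, 1.0]])
        chol = np.linalg.cholesky(cov)
        hits = 0
        for _ in range(reps):
            xy = rng.standard_normal((n, 2)) @ chol.T
            r = np.corrcoef(xy[:, 0], xy[:, 1])[0, 1]
            t = r * np.sqrt((n - 2) / (1 - r**2))
            if 2 * stats.t.sf(abs(t), n - 2) < alpha:
                hits += 1
        assert power_pearson(r_true, n, alpha) == pytest.approx(
            hits / reps, abs=0.015)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ConfigurationError):
            power_pearson(1.0, 100)
        with pytest.raises(ConfigurationError):
            power_pearson(0.3, 3)
        with pytest.raises(ConfigurationError):
            power_pearson(0.3, 100, alpha=0.0)
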