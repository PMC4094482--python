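"""Diagnostic statistics: logistic models, ROC, CART, group tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from rvdyn.stats import (REFERENCE_DIAGNOSTIC_MODEL, LogisticModel,
                         best_split, cart_fit, fit_mixed_logistic,
                         group_tests, predict_logistic, roc_auc)

FEATURES = {"delta_at_preverp_ms": 48.0, "frac_sinus": 3.0,
            "frac_preverp": 3.0, "sinus_rt_ms": 320.0,
            "steady_at_ms": 75.0}


class TestPredictLogistic:
    def test_reference_fixture_linear_predictor(self):
        """Hand-computed linear predictor -2.51 -> p = 0.0752."""
        p = predict_logistic(REFERENCE_DIAGNOSTIC_MODEL, FEATURES)
        lp = (3.57 - 0.03 * 48 + 0.37 * 3 + 0.40 * 3 - 0.01 * 320
              - 0.05 * 75)
        assert lp == pytest.approx(-2.51, abs=1e-12)
        assert p == pytest.approx(1 / (1 + np.exp(2.51)), abs=1e-9)

    def test_all_zero_covariates(self):
        p = predict_logistic(REFERENCE_DIAGNOSTIC_MODEL,
                             {k: 0.0 for k in FEATURES})
        assert p == pytest.approx(1 / (1 + np.exp(-3.57)), abs=1e-9)

    def test_zero_coefficients_give_half(self):
        m = LogisticModel(coefficients={"intercept": 0.0, "x": 0.0})
        assert predict_logistic(m, {"x": 123.0}) == 0.5

    def test_missing_covariate_named(self):
        with pytest.raises(KeyError, match="frac_sinus"):
            predict_logistic(REFERENCE_DIAGNOSTIC_MODEL,
                             {"delta_at_preverp_ms": 48.0})

    @given(st.sampled_from(sorted(FEATURES)),
           st.floats(min_value=0.1, max_value=20.0))
    def test_monotone_in_each_covariate(self, name, delta):
        """p moves in the direction of the coefficient's sign."""
        lo = predict_logistic(REFERENCE_DIAGNOSTIC_MODEL, FEATURES)
        x = dict(FEATURES)
        x[name] += delta
        hi = predict_logistic(REFERENCE_DIAGNOSTIC_MODEL, x)
        beta = REFERENCE_DIAGNOSTIC_MODEL.coefficients[name]
        assert (hi - lo) * beta >= 0


def simulate_mixed(rng, n_groups=250, per_group=12,
                   beta=(0.4, -0.9, 0.7), sigma=0.7):
    rows = []
    u = rng.normal(0, sigma, n_groups)
    for g in range(n_groups):
        X = rng.normal(size=(per_group, 2))
        eta = beta[0] + X @ np.array(beta[1:]) + u[g]
        y = rng.uniform(size=per_group) < 1 / (1 + np.exp(-eta))
        for j in range(per_group):
            rows.append({"x1": X[j, 0], "x2": X[j, 1],
                         "y": float(y[j]), "g": g})
    return pd.DataFrame(rows)


class TestMixedLogistic:
    def test_parameter_recovery(self, rng):
        """Known coefficients are recovered within 2 SE."""
        df = simulate_mixed(rng)
        m = fit_mixed_logistic(df, "y", "g", covariates=["x1", "x2"])
        truth = {"intercept": 0.4, "x1": -0.9, "x2": 0.7}
        for name, b in truth.items():
            est = m.coefficients[name]
            se = m.std_errors[name]
            assert abs(est - b) < 2 * se, (name, est, se)
        assert m.random_intercept_sd == pytest.approx(0.7, abs=0.25)

    def test_null_effects_near_zero(self, rng):
        df = simulate_mixed(rng, beta=(0.0, 0.0, 0.0), sigma=0.5)
        m = fit_mixed_logistic(df, "y", "g", covariates=["x1", "x2"])
        for name in ("x1", "x2"):
            assert abs(m.coefficients[name]) < 2 * m.std_errors[name]

    def test_reduces_to_plain_logistic(self, rng):
        """With the random-intercept variance fixed at zero the fit
        agrees with ordinary logistic regression to 1e-4 relative."""
        import statsmodels.api as sm
        df = simulate_mixed(rng, n_groups=80, sigma=0.0)
        m = fit_mixed_logistic(df, "y", "g", covariates=["x1", "x2"],
                               fit_random=False, ridge=0.0)
        glm = sm.Logit(df.y, sm.add_constant(df[["x1", "x2"]])).fit(disp=0)
        mine = [m.coefficients["intercept"], m.coefficients["x1"],
                m.coefficients["x2"]]
        assert np.allclose(mine, glm.params.values, rtol=1e-4, atol=1e-6)

    def test_single_class_outcome_rejected(self, rng):
        df = simulate_mixed(rng, n_groups=10)
        df["y"] = 1.0
        with pytest.raises(ValueError):
            fit_mixed_logistic(df, "y", "g")


class TestRoc:
    def test_perfect_and_reversed(self):
        _, auc = roc_auc([1, 2, 3, 4], [0, 0, 1, 1])
        assert auc == 1.0
        _, rev = roc_auc([-1, -2, -3, -4], [0, 0, 1, 1])
        assert rev == pytest.approx(1.0 - auc)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, 60)
        _, a1 = roc_auc(scores, labels)
        _, a2 = roc_auc(np.exp(3 * scores), labels)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_permutation_null_mean_half(self, rng):
        """Labels independent of scores: mean AUC over 1000 permutations
        is 0.5 within 0.03."""
        scores = rng.normal(size=60)
        labels = np.array([0] * 30 + [1] * 30)
        aucs = [roc_auc(scores, rng.permutation(labels))[1]
                for _ in range(1000)]
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.03)


class TestCart:
    def test_single_midpoint_split(self):
        X = pd.DataFrame({"f": [50.0, 55.0, 60.0, 20.0, 25.0, 30.0]})
        y = ["A", "A", "A", "B", "B", "B"]
        tree = cart_fit(X, y, min_leaf=1)
        assert tree.root.feature == "f"
        assert tree.root.threshold == 40.0
        assert tree.predict(X) == y
        assert tree.root.left.counts == {"B": 3}

    def test_constant_features_single_leaf(self):
        X = pd.DataFrame({"f": np.ones(20)})
        y = np.r_[np.zeros(10), np.ones(10)]
        assert cart_fit(X, y).root.is_leaf

    def test_first_split_matches_exhaustive_search(self, rng):
        """Oracle equivalence: the root split equals an independent
        exhaustive enumeration over all features x midpoints (n<=200)."""
        for _ in range(5):
            n = int(rng.integers(40, 200))
            X = pd.DataFrame(rng.normal(size=(n, 3)),
                             columns=["a", "b", "c"])
            y = (X.a + 0.8 * rng.normal(size=n) > 0).to_numpy(int)
            tree = cart_fit(X, y, min_leaf=5, max_depth=1)

            def gini(v):
                _, c = np.unique(v, return_counts=True)
                p = c / v.size
                return 1 - np.sum(p * p)

            best = None
            for fi, col in enumerate(["a", "b", "c"]):
                vals = np.unique(X[col].to_numpy())
                for thr in (vals[:-1] + vals[1:]) / 2:
                    m = X[col].to_numpy() <= thr
                    if m.sum() < 5 or (~m).sum() < 5:
                        continue
                    gain = gini(y) - (m.sum() * gini(y[m])
                                      + (~m).sum() * gini(y[~m])) / n
                    if best is None or gain > best[0] + 1e-12:
                        best = (gain, col, thr)
            assert tree.root.feature == best[1]
            assert tree.root.threshold == pytest.approx(best[2])

    def test_separated_groups_split_on_informative_feature(self, rng):
        """Two cohorts whose J-point hysteresis means differ by >3 SD:
        the root split lands on that feature in nearly every run."""
        hits = 0
        for _ in range(100):
            n = 60
            hyst_j = np.r_[rng.normal(50, 5, n // 2),
                           rng.normal(20, 5, n // 2)]
            other = rng.normal(0, 5, n)
            X = pd.DataFrame({"hyst_j": hyst_j, "other": other})
            y = np.r_[np.ones(n // 2), np.zeros(n // 2)]
            tree = cart_fit(X, y, min_leaf=5, max_depth=2)
            hits += tree.root.feature == "hyst_j"
        assert hits >= 95

    def test_sklearn_agreement_on_first_split(self, rng):
        from sklearn.tree import DecisionTreeClassifier
        X = pd.DataFrame(rng.normal(size=(80, 2)), columns=["a", "b"])
        y = (X.a > 0.3).to_numpy(int)
        tree = cart_fit(X, y, min_leaf=5, max_depth=1)
        sk = DecisionTreeClassifier(max_depth=1,
                                    min_samples_leaf=5).fit(X, y)
        assert tree.root.feature == X.columns[sk.tree_.feature[0]]
        assert tree.root.threshold == pytest.approx(
            sk.tree_.threshold[0], abs=1e-6)


class TestGroupTests:
    def test_type_one_error_controlled(self, rng):
        """Under the null (four identical groups) the family-wise
        rejection rate with Holm correction stays near the nominal
        level (<= 6% of 1000 simulations)."""
        fw = 0
        for _ in range(1000):
            vals = rng.normal(0, 1, 48)
            groups = np.repeat(["a", "b", "c", "d"], 12)
            res = group_tests(vals, groups)
            fw += res.significant.any()
        assert fw / 1000 <= 0.06

    def test_shifted_group_detected(self, rng):
        """A +3 SD shifted group (n=50) is detected after correction in
        the vast majority of runs."""
        hits = 0
        for _ in range(100):
            vals = np.r_[rng.normal(0, 1, 50), rng.normal(3, 1, 50)]
            groups = np.r_[["a"] * 50, ["b"] * 50]
            res = group_tests(vals, groups)
            hits += bool(res.significant.iloc[0])
        assert hits >= 95

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            group_tests([1.0, 2.0], ["a", "a"])

    def test_reports_group_moments(self, rng):
        vals = np.r_[rng.normal(5, 1, 30), rng.normal(9, 1, 30)]
        groups = np.r_[["x"] * 30, ["y"] * 30]
        res = group_tests(vals, groups)
        assert res.mean1.iloc[0] == pytest.approx(5.0, abs=0.8)
        assert res.mean2.iloc[0] == pytest.approx(9.0, abs=0.8)
        assert res.n1.iloc[0] == 30
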