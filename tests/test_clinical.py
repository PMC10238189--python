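"""Univariate thresholds, LOOCV logistic panels, ROC/AUC and bootstrap CIs."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from digiwell.clinical import (
    _fit_logistic_irls,
    bootstrap_auc_ci,
    evaluate_panel,
    loocv_logistic,
    panel_search,
    roc_auc,
    sensitivity_specificity,
    univariate_threshold,
)
from digiwell.errors import DomainError, SchemaError, UndefinedMetricError
from digiwell.simulate import simulate_cohort


def _brute_force_youden(cases, controls):
    values = np.unique(np.concatenate([cases, controls]))
    candidates = np.concatenate([[-np.inf], (values[:-1] + values[1:]) / 2, [np.inf]])
    best = -np.inf
    for t in candidates:
        j = (cases > t).mean() - (controls > t).mean()
        best = max(best, j)
    return best


class TestUnivariateThreshold:
    def test_perfect_separation_midpoint(self):
        t = univariate_threshold([10, 20, 30], [0, 0, 1])
        assert t == 5.5
        assert all(np.array([10, 20, 30]) > t)
        assert not any(np.array([0, 0, 1]) > t)

    def test_identical_distributions_call_nothing(self):
        t = univariate_threshold([1, 2, 3], [1, 2, 3])
        assert t == np.inf

    def test_empty_group_rejected(self):
        with pytest.raises(DomainError):
            univariate_threshold([], [1.0])

    def test_matches_brute_force_over_random_cohorts(self):
        for seed in range(200):
            rng = np.random.default_rng(seed)
            cases = rng.poisson(3.0, 15).astype(float)
            controls = rng.poisson(1.5, 15).astype(float)
            t = univariate_threshold(cases, controls)
            j = (cases > t).mean() - (controls > t).mean()
            assert j == pytest.approx(_brute_force_youden(cases, controls), abs=1e-12)


class TestSensitivitySpecificity:
    @pytest.mark.parametrize(
        "pos,n,expected_pct,rounded",
        [
            (25, 39, 64.1026, 64),
            (21, 39, 53.8462, 54),
            (22, 39, 56.4103, 56),
            (35, 39, 89.7436, 90),
        ],
    )
    def test_printed_sensitivities(self, pos, n, expected_pct, rounded):
        calls = np.array([True] * pos + [False] * (n - pos) + [False] * 33)
        labels = np.array(["case"] * n + ["control"] * 33)
        ss = sensitivity_specificity(calls, labels)
        assert ss.sensitivity == pytest.approx(expected_pct, abs=1e-3)
        assert ss.sensitivity_rounded == rounded

    @pytest.mark.parametrize(
        "false_pos,n,expected_pct,rounded",
        [(4, 33, 87.8788, 88), (5, 33, 84.8485, 85), (0, 33, 100.0, 100),
         (6, 33, 81.8182, 82)],
    )
    def test_printed_specificities(self, false_pos, n, expected_pct, rounded):
        calls = np.array([True] * 10 + [False] * 29 + [True] * false_pos
                         + [False] * (n - false_pos))
        labels = np.array(["case"] * 39 + ["control"] * n)
        ss = sensitivity_specificity(calls, labels)
        assert ss.specificity == pytest.approx(expected_pct, abs=1e-3)
        assert ss.specificity_rounded == rounded

    def test_all_correct(self):
        labels = np.array(["case"] * 5 + ["control"] * 5)
        calls = np.array([True] * 5 + [False] * 5)
        ss = sensitivity_specificity(calls, labels)
        assert (ss.sensitivity, ss.specificity) == (100.0, 100.0)

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            sensitivity_specificity([True, False], ["case", "case"])


class TestLogisticIRLS:
    def test_full_data_fit_matches_statsmodels(self):
        """Coefficients agree with an independent MLE implementation to 1e-6."""
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        n = 200
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        logits = 0.5 + 1.2 * X[:, 1] - 0.7 * X[:, 2]
        y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(int)
        beta, converged = _fit_logistic_irls(X, y)
        assert converged
        oracle = sm.Logit(y, X).fit(disp=0).params
        np.testing.assert_allclose(beta, oracle, atol=1e-6)

    def test_separable_data_returns_finite_probabilities(self):
        X = np.column_stack([np.ones(20), np.r_[np.zeros(10), np.ones(10) * 5]])
        y = np.r_[np.zeros(10), np.ones(10)].astype(int)
        beta, _ = _fit_logistic_irls(X, y)
        assert np.all(np.isfinite(beta))


class TestLOOCV:
    def test_perfectly_separated_cohort(self):
        rng = np.random.default_rng(1)
        n = 20
        df = pd.DataFrame(
            {
                "label": ["case"] * n + ["control"] * n,
                "M": np.r_[rng.normal(100, 5, n), rng.normal(0, 5, n)],
            }
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separable folds warn, by design
            probs = loocv_logistic(df, ["M"])
        assert (probs[:n] > 0.5).all()
        assert (probs[n:] < 0.5).all()

    def test_label_permuted_cohort_near_chance(self):
        rng = np.random.default_rng(2)
        n = 100
        df = pd.DataFrame(
            {
                "label": rng.permutation(["case"] * n + ["control"] * n),
                "M1": rng.normal(size=2 * n),
                "M2": rng.normal(size=2 * n),
            }
        )
        probs = loocv_logistic(df, ["M1", "M2"])
        _, auc = roc_auc(probs, df["label"])
        assert 0.35 <= auc <= 0.65

    def test_null_simulated_cohort_near_chance(self):
        """Equal case/control rates for every marker: LOOCV AUC ~ 0.5."""
        params = {m: (5.0, 5.0) for m in ("SOX17", "CDO1", "TAC1", "HOXA7")}
        df = simulate_cohort(100, 100, params, seed=3, covariates=False)
        probs = loocv_logistic(df, list(params))
        _, auc = roc_auc(probs, df["label"])
        assert 0.35 <= auc <= 0.65

    def test_constant_feature_dropped_with_warning(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            {
                "label": ["case"] * 10 + ["control"] * 10,
                "M": rng.normal(size=20),
                "flat": np.ones(20),
            }
        )
        with pytest.warns(UserWarning, match="constant"):
            probs = loocv_logistic(df, ["M", "flat"])
        assert np.isfinite(probs).all()

    def test_too_small_cohort_rejected(self):
        df = pd.DataFrame({"label": ["case", "control"] * 2, "M": [1, 2, 3, 4]})
        with pytest.raises(DomainError):
            loocv_logistic(df, ["M"])


class TestRocAuc:
    def test_perfect_separation(self):
        probs = np.array([0.9, 0.8, 0.2, 0.1])
        labels = ["case", "case", "control", "control"]
        points, auc = roc_auc(probs, labels)
        assert auc == 1.0
        np.testing.assert_array_equal(points[0], [0, 0])
        np.testing.assert_array_equal(points[-1], [1, 1])

    def test_all_tied_probabilities_chance(self):
        _, auc = roc_auc(np.full(10, 0.5), ["case"] * 5 + ["control"] * 5)
        assert auc == 0.5

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc([0.1, 0.9], ["case", "case"])

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        probs = rng.random(50)
        labels = rng.permutation(["case"] * 25 + ["control"] * 25)
        _, a1 = roc_auc(probs, labels)
        _, a2 = roc_auc(np.exp(3 * probs), labels)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_roc_curve_is_monotone_step(self):
        rng = np.random.default_rng(6)
        probs = rng.choice([0.1, 0.5, 0.9], 40)  # heavy ties
        labels = rng.permutation(["case"] * 20 + ["control"] * 20)
        points, _ = roc_auc(probs, labels)
        assert (np.diff(points[:, 0]) >= 0).all()
        assert (np.diff(points[:, 1]) >= 0).all()

    def test_matches_mann_whitney_over_random_cohorts(self):
        """AUC equals U / (n1 n0) with ties counted one half (rank oracle)."""
        for seed in range(500):
            rng = np.random.default_rng(seed)
            n1, n0 = rng.integers(3, 16, 2)
            scores = np.round(rng.random(n1 + n0), 1)  # coarse: many ties
            labels = np.r_[np.ones(n1, int), np.zeros(n0, int)]
            _, auc = roc_auc(scores, labels)
            u = stats.mannwhitneyu(scores[:n1], scores[n1:],
                                   alternative="two-sided").statistic
            assert auc == pytest.approx(u / (n1 * n0), abs=1e-12)


class TestBootstrapCI:
    def test_perfect_separation_degenerate_interval(self):
        probs = np.array([0.9, 0.8, 0.2, 0.1])
        labels = ["case", "case", "control", "control"]
        lo, hi = bootstrap_auc_ci(probs, labels, n_boot=200, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(7)
        probs = rng.random(40)
        labels = ["case"] * 20 + ["control"] * 20
        a = bootstrap_auc_ci(probs, labels, n_boot=300, seed=3)
        b = bootstrap_auc_ci(probs, labels, n_boot=300, seed=3)
        assert a == b

    def test_n_boot_floor(self):
        with pytest.raises(DomainError):
            bootstrap_auc_ci([0.1, 0.9], ["control", "case"], n_boot=50)

    def test_coverage_of_known_population_auc(self):
        """95% interval covers the true AUC in >= 88% of synthetic cohorts.

        Scores are N(mu, 1) for cases vs N(0, 1) for controls with mu chosen
        so the population AUC is 0.8 (binormal: AUC = Phi(mu / sqrt(2))).
        """
        mu = np.sqrt(2) * stats.norm.ppf(0.8)
        rng = np.random.default_rng(8)
        labels = np.r_[np.ones(50, int), np.zeros(50, int)]
        covered = 0
        n_cohorts = 500
        for _ in range(n_cohorts):
            scores = np.r_[rng.normal(mu, 1, 50), rng.normal(0, 1, 50)]
            lo, hi = bootstrap_auc_ci(scores, labels, n_boot=300,
                                      seed=int(rng.integers(2**31)))
            covered += lo <= 0.8 <= hi
        assert covered / n_cohorts >= 0.88


class TestPanelSearch:
    def test_informative_marker_outranks_noise(self):
        rng = np.random.default_rng(9)
        n = 40
        df = pd.DataFrame(
            {
                "label": ["case"] * n + ["control"] * n,
                "signal": np.r_[rng.normal(2, 1, n), rng.normal(0, 1, n)],
                "noise": rng.normal(size=2 * n),
            }
        )
        ranked = panel_search(df, ["signal", "noise"])
        assert len(ranked) == 3  # 2^2 - 1 subsets
        singles = ranked[ranked.n_markers == 1].reset_index(drop=True)
        assert singles.markers[0] == ("signal",)

    def test_identical_columns_tie_within_size(self):
        rng = np.random.default_rng(10)
        base = np.r_[rng.normal(1, 1, 20), rng.normal(0, 1, 20)]
        df = pd.DataFrame(
            {"label": ["case"] * 20 + ["control"] * 20, "A": base, "B": base}
        )
        ranked = panel_search(df, ["A", "B"])
        aucs = ranked.set_index("markers")["loocv_auc"]
        assert aucs[("A",)] == pytest.approx(aucs[("B",)], abs=1e-12)

    def test_four_markers_fifteen_subsets(self):
        df = simulate_cohort(15, 15, seed=11, covariates=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ranked = panel_search(df)
        assert len(ranked) == 15

    def test_marker_limit_enforced(self):
        df = simulate_cohort(10, 10, seed=12)
        with pytest.raises(DomainError):
            panel_search(df, [f"m{i}" for i in range(9)])


class TestEvaluatePanel:
    def test_panel_evaluation_end_to_end(self):
        df = simulate_cohort(39, 33, seed=13)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ev = evaluate_panel(df, n_boot=300, seed=1)
        assert 0.5 < ev.auc <= 1.0
        assert ev.auc_ci_low <= ev.auc <= ev.auc_ci_high
        assert 0 <= ev.sensitivity <= 100 and 0 <= ev.specificity <= 100
        assert set(ev.per_marker["marker"]) == {"SOX17", "CDO1", "TAC1", "HOXA7"}

    def test_labels_schema_enforced(self):
        df = pd.DataFrame({"label": ["yes", "no"] * 10, "M": np.arange(20.0)})
        with pytest.raises(SchemaError):
            loocv_logistic(df, ["M"])
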