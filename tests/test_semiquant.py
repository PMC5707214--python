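"""Normal limits, ROC optimal cut-off, and the 18 semi-quantification methods."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.base import clone

import fpcitbench as fb
from fpcitbench.errors import (
    ConfigurationError,
    DegenerateRegressionError,
    InsufficientComparatorsError,
)
from fpcitbench.semiquant import (
    SQ_METHODS,
    NormalLimitModel,
    age_matched_normals,
    classify_sq,
    cohort_to_xy,
    fit_age_regression,
    limit_mean_minus_ksd,
    limit_minimum,
    limit_regression_minus_kse,
    roc_optimal_cutoff,
    run_sq_method,
)


def roc_accuracy(c, normals, abnormals):
    """Accuracy of the rule 'abnormal iff value < c' (boundary = normal)."""
    normals, abnormals = np.asarray(normals), np.asarray(abnormals)
    return ((normals >= c).sum() + (abnormals < c).sum()) / (normals.size + abnormals.size)


def roc_brute_force(normals, abnormals):
    """Exhaustive-search oracle: best accuracy over every threshold position.

    Accuracy is piecewise constant, changing only at data values, so probing
    just below/above every pooled value plus the extremes covers all cases.
    """
    pooled = np.unique(np.concatenate([normals, abnormals]))
    eps = 1e-9 * max(1.0, np.abs(pooled).max())
    probes = np.concatenate([pooled - eps, pooled + eps,
                             [pooled[0] - 1.0, pooled[-1] + 1.0]])
    return max(roc_accuracy(c, normals, abnormals) for c in probes)


class TestLimitPrimitives:
    def test_mean_minus_2sd_hand_value(self):
        # sample SD of {2.0, 2.2, 2.4} is 0.2
        assert limit_mean_minus_ksd([2.0, 2.2, 2.4], 2) == pytest.approx(1.8)

    def test_k_zero_collapses_to_mean(self):
        assert limit_mean_minus_ksd([1.0, 2.0, 3.0], 0) == pytest.approx(2.0)

    def test_zero_variance(self):
        assert limit_mean_minus_ksd([1.7, 1.7, 1.7], 2.5) == pytest.approx(1.7)

    def test_mean_minus_ksd_needs_two(self):
        with pytest.raises(InsufficientComparatorsError):
            limit_mean_minus_ksd([2.0], 2)

    def test_minimum(self):
        assert limit_minimum([2.0, 2.2, 2.4]) == 2.0
        assert limit_minimum([1.5]) == 1.5
        assert limit_minimum([2.4, 2.0, 2.2]) == limit_minimum([2.0, 2.2, 2.4])

    def test_minimum_empty(self):
        with pytest.raises(InsufficientComparatorsError):
            limit_minimum([])


class TestRegressionLimit:
    def test_points_on_exact_line(self):
        pts = [(a, 3 - 0.01 * a) for a in (40.0, 55.0, 70.0)]
        for k in (0, 1, 2):
            assert limit_regression_minus_kse(pts, 50.0, k) == pytest.approx(3 - 0.5)

    def test_k_zero_gives_fitted_value(self):
        pts = [(40, 2.45), (50, 2.15), (60, 2.00)]
        a, b, _, _ = fit_age_regression([p[0] for p in pts], [p[1] for p in pts])
        assert limit_regression_minus_kse(pts, 55.0, 0) == pytest.approx(a + b * 55.0)

    def test_hand_computed_normal_equations(self):
        """Independent closed-form least squares for ages {40,50,60}."""
        ages = np.array([40.0, 50.0, 60.0])
        sbrs = np.array([2.45, 2.15, 2.00])
        sxx = np.sum((ages - ages.mean()) ** 2)
        b = np.sum((ages - ages.mean()) * (sbrs - sbrs.mean())) / sxx
        a = sbrs.mean() - b * ages.mean()
        rss = np.sum((sbrs - a - b * ages) ** 2)
        rse = np.sqrt(rss / 1)
        expected = a + b * 50.0 - 1 * rse
        got = limit_regression_minus_kse(list(zip(ages, sbrs)), 50.0, 1)
        assert got == pytest.approx(expected)
        assert got == pytest.approx(2.2 - np.sqrt(0.00375))

    def test_identical_ages_degenerate(self):
        with pytest.raises(DegenerateRegressionError):
            limit_regression_minus_kse([(50, 2.0), (50, 2.1), (50, 2.2)], 50, 1)

    def test_mean_se_band_is_narrower(self):
        pts = [(a, 2.5 - 0.005 * a + 0.01 * (-1) ** i) for i, a in enumerate(range(40, 80, 4))]
        resid = limit_regression_minus_kse(pts, 60, 2, se_kind="residual")
        mean = limit_regression_minus_kse(pts, 60, 2, se_kind="mean")
        assert mean > resid  # mean-SE band sits above (is tighter than) the residual band


class TestAgeMatching:
    @pytest.fixture()
    def cohort(self):
        recs = [
            fb.PatientRecord(id=f"n{a}", age=a, sex="F", label="normal",
                             sbr={r: 2.0 for r in fb.REGIONS})
            for a in (54, 55, 60, 65, 66)
        ]
        return fb.Cohort(records=recs)

    def test_boundary_inclusive(self, cohort):
        matched = age_matched_normals(cohort, 60.0, window=5.0)
        assert sorted(r.age for r in matched) == [55, 60, 65]

    def test_empty_window_errors(self):
        recs = [fb.PatientRecord(id=f"n{i}", age=40, sex="M", label="normal",
                                 sbr={r: 2.0 for r in fb.REGIONS}) for i in range(5)]
        with pytest.raises(InsufficientComparatorsError):
            age_matched_normals(fb.Cohort(records=recs), 70.0, window=5.0)

    def test_infinite_window_keeps_all_normals(self, cohort):
        assert len(age_matched_normals(cohort, 60.0, window=np.inf)) == len(cohort)


class TestRocOptimalCutoff:
    def test_perfect_separation(self):
        c = roc_optimal_cutoff([2.0, 2.5, 3.0], [1.0, 1.5])
        assert c == pytest.approx(1.75)
        assert roc_accuracy(c, [2.0, 2.5, 3.0], [1.0, 1.5]) == 1.0

    def test_tie_broken_toward_smallest(self):
        # 1.75 and 2.3 (midpoint of 2.1/2.5) both score 5/6; the smaller wins
        c = roc_optimal_cutoff([2.0, 2.5, 3.0], [1.0, 1.5, 2.1])
        assert c == pytest.approx(1.75)
        assert roc_accuracy(c, [2.0, 2.5, 3.0], [1.0, 1.5, 2.1]) == pytest.approx(5 / 6)

    def test_indistinguishable_singletons(self):
        c = roc_optimal_cutoff([2.0], [2.0])
        assert c < 2.0
        assert roc_accuracy(c, [2.0], [2.0]) == 0.5

    def test_empty_class_rejected(self):
        with pytest.raises(InsufficientComparatorsError):
            roc_optimal_cutoff([], [1.0])

    @given(st.data())
    def test_matches_brute_force_oracle(self, data):
        n1 = data.draw(st.integers(1, 30))
        n2 = data.draw(st.integers(1, 30))
        vals = st.floats(0.01, 5.0, allow_nan=False)
        normals = np.array(data.draw(st.lists(vals, min_size=n1, max_size=n1)))
        abnormals = np.array(data.draw(st.lists(vals, min_size=n2, max_size=n2)))
        c = roc_optimal_cutoff(normals, abnormals)
        assert roc_accuracy(c, normals, abnormals) == pytest.approx(
            roc_brute_force(normals, abnormals)
        )


class TestClassifyRule:
    LIMITS = {
        "l_putamen": NormalLimitModel("l_putamen", "constant", "minimum", 0, 5, 1.5),
        "r_putamen": NormalLimitModel("r_putamen", "constant", "minimum", 0, 5, 1.5),
    }

    def test_all_above_is_normal(self):
        assert classify_sq({"l_putamen": 2.0, "r_putamen": 2.0}, 60, self.LIMITS) == "normal"

    def test_any_below_is_abnormal(self):
        assert classify_sq({"l_putamen": 1.4, "r_putamen": 2.0}, 60, self.LIMITS) == "abnormal"

    def test_exactly_on_cutoff_counts_as_normal(self):
        assert classify_sq({"l_putamen": 1.5, "r_putamen": 2.0}, 60, self.LIMITS) == "normal"

    def test_missing_limit_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            classify_sq({"l_putamen": 2.0}, 60,
                        {"r_putamen": self.LIMITS["r_putamen"]})


class TestMethodTable:
    def test_eighteen_methods(self):
        assert len(SQ_METHODS) == 18

    def test_family_structure(self):
        for i in range(1, 9):
            assert SQ_METHODS[f"SQ{i}"].comparison == "age_matched_normals"
        for i in range(9, 15):
            assert SQ_METHODS[f"SQ{i}"].comparison == "all_normals"
        assert SQ_METHODS["SQ15"].comparison == "all_both_classes"
        assert SQ_METHODS["SQ17"].comparison == "age_matched_both_classes"
        # odd ids up to 14 use the putamen pair only, even ids add the caudate
        for i in range(1, 15):
            n_regions = len(SQ_METHODS[f"SQ{i}"].regions)
            assert n_regions == (2 if i % 2 == 1 else 4)
        assert SQ_METHODS["SQ15"].regions == ("lowest_putamen",)
        assert SQ_METHODS["SQ16"].regions == ("lowest_putamen", "lowest_caudate")

    def test_k_values(self):
        assert [SQ_METHODS[f"SQ{i}"].k for i in (1, 3, 5)] == [2.0, 1.5, 1.0]
        assert [SQ_METHODS[f"SQ{i}"].k for i in (9, 11, 13)] == [2.0, 1.5, 1.0]


class TestSemiQuantClassifier:
    def split(self, cohort, n_test=40):
        X, y = cohort_to_xy(cohort)
        rng = np.random.default_rng(0)
        idx = rng.permutation(len(y))
        return X[idx[n_test:]], y[idx[n_test:]], X[idx[:n_test]], y[idx[:n_test]]

    @pytest.mark.parametrize("method", sorted(SQ_METHODS, key=lambda s: int(s[2:])))
    def test_every_method_predicts_valid_labels(self, research_cohort, method):
        X_tr, y_tr, X_te, _ = self.split(research_cohort)
        clf = fb.SemiQuantClassifier(method=method).fit(X_tr, y_tr)
        pred = clf.predict(X_te)
        assert set(pred) <= {"normal", "abnormal"}
        assert len(pred) == len(X_te)

    def test_k_monotone_abnormal_call_sets(self, research_cohort):
        """Larger k → lower cut-offs → strictly fewer (or equal) abnormal calls.

        Checked as set inclusion, which implies the sensitivity/specificity
        ordering for any test labels."""
        X_tr, y_tr, X_te, _ = self.split(research_cohort)
        calls = {}
        for m in ("SQ1", "SQ3", "SQ5"):  # k = 2, 1.5, 1
            clf = fb.SemiQuantClassifier(method=m).fit(X_tr, y_tr)
            calls[m] = set(np.flatnonzero(clf.predict(X_te) == "abnormal"))
        assert calls["SQ1"] <= calls["SQ3"] <= calls["SQ5"]

    def test_caudate_superset_of_flags(self, research_cohort):
        """Adding caudate limits can only add abnormal calls (any-below rule)."""
        X_tr, y_tr, X_te, _ = self.split(research_cohort)
        for narrow, wide in (("SQ1", "SQ2"), ("SQ7", "SQ8"), ("SQ15", "SQ16")):
            a = fb.SemiQuantClassifier(method=narrow).fit(X_tr, y_tr).predict(X_te)
            b = fb.SemiQuantClassifier(method=wide).fit(X_tr, y_tr).predict(X_te)
            assert set(np.flatnonzero(a == "abnormal")) <= set(np.flatnonzero(b == "abnormal"))

    def test_window_widens_instead_of_failing(self):
        """A test age far outside the comparator range widens the window."""
        recs = [
            fb.PatientRecord(id=f"n{i}", age=40 + i, sex="F", label="normal",
                             sbr={r: 2.3 + 0.05 * i for r in fb.REGIONS})
            for i in range(8)
        ] + [
            fb.PatientRecord(id=f"a{i}", age=40 + i, sex="M", label="abnormal",
                             sbr={r: 1.0 for r in fb.REGIONS})
            for i in range(8)
        ]
        cohort = fb.Cohort(records=recs)
        X, y = cohort_to_xy(cohort)
        clf = fb.SemiQuantClassifier(method="SQ1").fit(X, y)
        test = np.array([[2.5, 2.5, 2.5, 2.5, 80.0]])  # no normals within ±5 y
        assert clf.predict(test)[0] == "normal"

    def test_exhausted_widening_errors(self):
        recs = [
            fb.PatientRecord(id=f"n{i}", age=40, sex="F", label="normal",
                             sbr={r: 2.5 for r in fb.REGIONS})
            for i in range(3)
        ]
        X, y = cohort_to_xy(fb.Cohort(records=recs))
        clf = fb.SemiQuantClassifier(method="SQ1", min_support=5, max_window=6).fit(X, y)
        with pytest.raises(InsufficientComparatorsError):
            clf.predict(np.array([[2.0, 2.0, 2.0, 2.0, 60.0]]))

    def test_roc_methods_require_both_classes(self, research_cohort):
        X, y = cohort_to_xy(research_cohort)
        normals_only = y == "normal"
        with pytest.raises(InsufficientComparatorsError):
            fb.SemiQuantClassifier(method="SQ15").fit(X[normals_only], y[normals_only])

    def test_sklearn_protocol(self, research_cohort):
        clf = fb.SemiQuantClassifier(method="SQ9", window=4.0)
        assert clone(clf).get_params()["window"] == 4.0
        X_tr, y_tr, X_te, _ = self.split(research_cohort)
        fitted = clf.fit(X_tr, y_tr)
        assert set(fitted.classes_) == {"normal", "abnormal"}
        assert fitted.limits_["l_putamen"].form == "linear_in_age"

    def test_run_sq_method_wrapper(self, research_cohort, tiny_cohort):
        pred = run_sq_method("SQ7", research_cohort, tiny_cohort)
        assert len(pred) == len(tiny_cohort)

    def test_recovers_labels_on_separable_cohort(self, research_cohort):
        """On high-separability data the ROC method is near-perfect."""
        X_tr, y_tr, X_te, y_te = self.split(research_cohort)
        pred = fb.SemiQuantClassifier(method="SQ15").fit(X_tr, y_tr).predict(X_te)
        assert (pred == y_te).mean() > 0.9
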