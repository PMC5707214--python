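"""The 18 semi-quantification classifiers: normal limits + the any-below rule.

Semi-quantification classifies a scan by comparing each regional striatal
binding ratio (SBR) against a lower cut-off derived from comparison data.
The decision rule is rigid: any SBR strictly below its cut-off makes the
overall call abnormal; all SBRs at or above their cut-offs make it normal
(a value exactly on the cut-off counts as within limits).

Four families of cut-off are implemented, combined with different
comparison sets and region subsets to give the 18 built-in methods:

======  ==========================  ==========================  ==================
method  comparison data             SBRs considered             cut-off
======  ==========================  ==========================  ==================
SQ 1-6  age-matched normals (±5 y)  L+R putamen (± caudate)     mean − k·SD, k ∈ {2, 1.5, 1}
SQ 7-8  age-matched normals         L+R putamen (± caudate)     minimum
SQ 9-14 all normals                 L+R putamen (± caudate)     age regression − k·SE, k ∈ {2, 1.5, 1}
SQ 15-16 all data, both classes     lowest putamen (± caudate)  ROC optimal point
SQ 17-18 age-matched, both classes  lowest putamen (± caudate)  ROC optimal point
======  ==========================  ==========================  ==================

"Lowest putamen/caudate" is the per-subject minimum of the left and right
SBR; ROC methods threshold that discriminant directly, with the cut-off
placed at the accuracy-maximising operating point on the training ROC
curve.  Age-matched methods that find fewer than ``min_support``
comparators widen the window symmetrically in 1-year steps rather than
fail mid-experiment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .errors import (
    ConfigurationError,
    DegenerateRegressionError,
    InsufficientComparatorsError,
    InvalidParameterError,
)
from .features import SBR_FEATURE_COLUMNS
from .synth import LABEL_ABNORMAL, LABEL_NORMAL, REGIONS, Cohort

logger = logging.getLogger(__name__)

__all__ = [
    "NormalLimitModel",
    "SQMethodSpec",
    "SQ_METHODS",
    "SemiQuantClassifier",
    "age_matched_normals",
    "limit_mean_minus_ksd",
    "limit_minimum",
    "fit_age_regression",
    "limit_regression_minus_kse",
    "roc_optimal_cutoff",
    "classify_sq",
    "run_sq_method",
    "cohort_to_xy",
]

#: derived per-subject discriminants used by the ROC methods
DERIVED = {
    "lowest_putamen": ("l_putamen", "r_putamen"),
    "lowest_caudate": ("l_caudate", "r_caudate"),
}

PUTAMEN_PAIR = ("l_putamen", "r_putamen")
ALL_REGIONS = REGIONS


@dataclass(frozen=True)
class NormalLimitModel:
    """A per-region lower cut-off, constant or linear in age."""

    region: str
    form: str  # "constant" | "linear_in_age"
    method: str
    k: float
    support_n: int
    intercept: float
    slope: float = 0.0
    residual_se: float | None = None

    def cutoff_at(self, age: float) -> float:
        if self.form == "constant":
            return self.intercept
        return self.intercept + self.slope * age


@dataclass(frozen=True)
class SQMethodSpec:
    """Declarative description of one semi-quantification method."""

    sq_id: int
    comparison: str  # age_matched_normals | all_normals | all_both_classes | age_matched_both_classes
    regions: tuple[str, ...]
    rule: str  # mean_minus_ksd | minimum | regression_minus_kse | roc_optimal
    k: float = 0.0

    @property
    def name(self) -> str:
        return f"SQ{self.sq_id}"

    def describe(self) -> str:
        rule = {
            "mean_minus_ksd": f"Mean − {self.k:g}SD",
            "minimum": "Minimum",
            "regression_minus_kse": f"Regression − {self.k:g}SE",
            "roc_optimal": "Optimal point on ROC curve",
        }[self.rule]
        return f"{rule} | {'+'.join(self.regions)} | {self.comparison}"


def _build_sq_methods() -> dict[str, SQMethodSpec]:
    specs = [
        SQMethodSpec(1, "age_matched_normals", PUTAMEN_PAIR, "mean_minus_ksd", 2.0),
        SQMethodSpec(2, "age_matched_normals", ALL_REGIONS, "mean_minus_ksd", 2.0),
        SQMethodSpec(3, "age_matched_normals", PUTAMEN_PAIR, "mean_minus_ksd", 1.5),
        SQMethodSpec(4, "age_matched_normals", ALL_REGIONS, "mean_minus_ksd", 1.5),
        SQMethodSpec(5, "age_matched_normals", PUTAMEN_PAIR, "mean_minus_ksd", 1.0),
        SQMethodSpec(6, "age_matched_normals", ALL_REGIONS, "mean_minus_ksd", 1.0),
        SQMethodSpec(7, "age_matched_normals", PUTAMEN_PAIR, "minimum"),
        SQMethodSpec(8, "age_matched_normals", ALL_REGIONS, "minimum"),
        SQMethodSpec(9, "all_normals", PUTAMEN_PAIR, "regression_minus_kse", 2.0),
        SQMethodSpec(10, "all_normals", ALL_REGIONS, "regression_minus_kse", 2.0),
        SQMethodSpec(11, "all_normals", PUTAMEN_PAIR, "regression_minus_kse", 1.5),
        SQMethodSpec(12, "all_normals", ALL_REGIONS, "regression_minus_kse", 1.5),
        SQMethodSpec(13, "all_normals", PUTAMEN_PAIR, "regression_minus_kse", 1.0),
        SQMethodSpec(14, "all_normals", ALL_REGIONS, "regression_minus_kse", 1.0),
        SQMethodSpec(15, "all_both_classes", ("lowest_putamen",), "roc_optimal"),
        SQMethodSpec(16, "all_both_classes", ("lowest_putamen", "lowest_caudate"), "roc_optimal"),
        SQMethodSpec(17, "age_matched_both_classes", ("lowest_putamen",), "roc_optimal"),
        SQMethodSpec(18, "age_matched_both_classes", ("lowest_putamen", "lowest_caudate"), "roc_optimal"),
    ]
    return {s.name: s for s in specs}


#: the 18 built-in method specifications
SQ_METHODS = _build_sq_methods()


# ---------------------------------------------------------------------------
# cut-off primitives


def age_matched_normals(
    train: Cohort, test_age: float, window: float = 5.0, min_support: int = 1
):
    """Normal-labelled training records with |age − test_age| ≤ window."""
    if window <= 0:
        raise InvalidParameterError("window must be > 0")
    matches = [
        r
        for r in train
        if r.label == LABEL_NORMAL and abs(r.age - test_age) <= window
    ]
    if len(matches) < min_support:
        raise InsufficientComparatorsError(
            f"only {len(matches)} age-matched normals in ±{window} y of age {test_age}"
        )
    return matches


def limit_mean_minus_ksd(values: Sequence[float], k: float) -> float:
    """Mean minus k sample standard deviations (n−1 denominator)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InsufficientComparatorsError("mean − kSD needs at least 2 comparators")
    return float(v.mean() - k * v.std(ddof=1))


def limit_minimum(values: Sequence[float]) -> float:
    """Smallest comparator value."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise InsufficientComparatorsError("minimum needs at least 1 comparator")
    return float(v.min())


def fit_age_regression(ages: Sequence[float], sbrs: Sequence[float]) -> tuple[float, float, float, int]:
    """OLS fit sbr = a + b·age; returns (a, b, residual SE, n).

    Residual standard error is sqrt(RSS / (n − 2)) — the spread of normal
    values about the fitted age trend, which is what a clinical normal band
    subtracts multiples of.
    """
    ages = np.asarray(ages, dtype=float)
    sbrs = np.asarray(sbrs, dtype=float)
    n = ages.size
    if n < 3:
        raise InsufficientComparatorsError("age regression needs at least 3 comparators")
    if np.ptp(ages) == 0:
        raise DegenerateRegressionError("all comparator ages identical; regression undefined")
    b, a = np.polyfit(ages, sbrs, 1)
    rss = float(np.sum((sbrs - (a + b * ages)) ** 2))
    rse = float(np.sqrt(max(rss, 0.0) / (n - 2)))
    return float(a), float(b), rse, int(n)


def limit_regression_minus_kse(
    normals: Sequence[tuple[float, float]],
    test_age: float,
    k: float,
    se_kind: str = "residual",
) -> float:
    """Cut-off from the normal age-trend: fitted value at test_age − k·SE.

    ``se_kind="residual"`` (default) uses the residual standard error;
    ``"mean"`` uses the standard error of the predicted mean at test_age.
    """
    pairs = np.asarray(list(normals), dtype=float)
    a, b, rse, n = fit_age_regression(pairs[:, 0], pairs[:, 1])
    if se_kind == "residual":
        se = rse
    elif se_kind == "mean":
        ages = pairs[:, 0]
        sxx = float(np.sum((ages - ages.mean()) ** 2))
        se = rse * float(np.sqrt(1.0 / n + (test_age - ages.mean()) ** 2 / sxx))
    else:
        raise InvalidParameterError(f"unknown se_kind {se_kind!r}")
    return a + b * test_age - k * se


def roc_optimal_cutoff(
    normal_values: Sequence[float], abnormal_values: Sequence[float]
) -> float:
    """Accuracy-maximising threshold for the rule "abnormal iff value < c".

    Candidates are the midpoints between consecutive distinct pooled values
    plus one sentinel below the minimum and one above the maximum; ties in
    accuracy go to the smallest candidate (favouring specificity).
    """
    normals = np.asarray(normal_values, dtype=float)
    abnormals = np.asarray(abnormal_values, dtype=float)
    if normals.size == 0 or abnormals.size == 0:
        raise InsufficientComparatorsError("ROC cut-off needs values from both classes")
    distinct = np.unique(np.concatenate([normals, abnormals]))
    candidates = np.concatenate(
        [[distinct[0] - 1.0], (distinct[:-1] + distinct[1:]) / 2.0, [distinct[-1] + 1.0]]
    )
    # accuracy(c) = P(normal >= c) + P(abnormal < c), pooled counts
    correct = (normals[None, :] >= candidates[:, None]).sum(axis=1) + (
        abnormals[None, :] < candidates[:, None]
    ).sum(axis=1)
    best = int(np.argmax(correct))  # first max → smallest candidate
    return float(candidates[best])


def classify_sq(
    sbr_values: Mapping[str, float], age: float, limits: Mapping[str, NormalLimitModel]
) -> str:
    """Rigid any-below rule over the configured regions/discriminants."""
    for name, model in limits.items():
        if name not in sbr_values:
            raise ConfigurationError(f"no SBR value for limit {name!r}")
        if sbr_values[name] < model.cutoff_at(age):
            return LABEL_ABNORMAL
    return LABEL_NORMAL


# ---------------------------------------------------------------------------
# estimator


def cohort_to_xy(cohort: Cohort) -> tuple[np.ndarray, np.ndarray]:
    """Cohort → (X, y) with X columns (sbr_l_putamen, sbr_r_putamen,
    sbr_l_caudate, sbr_r_caudate, age) and y the string labels."""
    X = np.array([[r.sbr[reg] for reg in REGIONS] + [r.age] for r in cohort])
    return X, cohort.labels


def _column_index(name: str) -> int:
    return SBR_FEATURE_COLUMNS.index(f"sbr_{name}" if name in REGIONS else name)


_AGE_COL = SBR_FEATURE_COLUMNS.index("age")


def _discriminant(X: np.ndarray, name: str) -> np.ndarray:
    """Per-subject value of a region SBR or a derived lowest-of-pair."""
    if name in REGIONS:
        return X[:, _column_index(name)]
    left, right = DERIVED[name]
    return np.minimum(X[:, _column_index(left)], X[:, _column_index(right)])


class SemiQuantClassifier(ClassifierMixin, BaseEstimator):
    """One of the 18 semi-quantification methods as a scikit-learn classifier.

    Parameters
    ----------
    method:
        Built-in method name ``"SQ1"`` … ``"SQ18"``, or an
        :class:`SQMethodSpec` for a custom combination.
    window:
        Half-width in years of the age-matching window.
    min_support:
        Minimum number of comparators (per class, for two-class ROC
        methods) before the window is widened.
    widen_step, max_window:
        Widening increment and a hard stop for pathological cohorts.
    se_kind:
        ``"residual"`` or ``"mean"`` standard error for the regression band.

    Feature matrix ``X`` must have columns in the order of
    :data:`fpcitbench.features.SBR_FEATURE_COLUMNS` (four SBRs, then age).
    """

    def __init__(
        self,
        method: str | SQMethodSpec = "SQ1",
        window: float = 5.0,
        min_support: int = 5,
        widen_step: float = 1.0,
        max_window: float = 150.0,
        se_kind: str = "residual",
    ):
        self.method = method
        self.window = window
        self.min_support = min_support
        self.widen_step = widen_step
        self.max_window = max_window
        self.se_kind = se_kind

    # -- helpers -----------------------------------------------------------
    def _spec(self) -> SQMethodSpec:
        if isinstance(self.method, SQMethodSpec):
            return self.method
        if self.method in SQ_METHODS:
            return SQ_METHODS[self.method]
        raise ConfigurationError(f"unknown semi-quantification method {self.method!r}")

    @staticmethod
    def _validate_xy(X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(SBR_FEATURE_COLUMNS):
            raise InvalidParameterError(
                f"X must be (n, {len(SBR_FEATURE_COLUMNS)}) in canonical SBR column order"
            )
        if y is not None:
            y = np.asarray(y)
            if y.shape[0] != X.shape[0]:
                raise InvalidParameterError("X and y length mismatch")
        return X, y

    def fit(self, X, y):
        X, y = self._validate_xy(X, y)
        spec = self._spec()
        if spec.comparison in ("all_both_classes", "age_matched_both_classes"):
            if not {LABEL_NORMAL, LABEL_ABNORMAL} <= set(map(str, y)):
                raise InsufficientComparatorsError(
                    f"{spec.name} needs training data from both classes"
                )
        elif LABEL_NORMAL not in set(map(str, y)):
            raise InsufficientComparatorsError(f"{spec.name} needs normal training data")
        self.X_ = X
        self.y_ = np.asarray([str(v) for v in y])
        self.classes_ = np.unique(self.y_)
        self.n_features_in_ = X.shape[1]

        if spec.comparison == "all_normals":
            normal_rows = self.X_[self.y_ == LABEL_NORMAL]
            self.limits_ = {}
            for region in spec.regions:
                a, b, rse, n = fit_age_regression(
                    normal_rows[:, _AGE_COL], normal_rows[:, _column_index(region)]
                )
                if self.se_kind == "residual":
                    offset = spec.k * rse
                    slope = b
                    intercept = a - offset
                else:
                    # mean-SE band varies with age; fall back to pointwise at predict time
                    intercept, slope = a, b
                self.limits_[region] = NormalLimitModel(
                    region=region,
                    form="linear_in_age",
                    method="regression_minus_kse",
                    k=spec.k,
                    support_n=n,
                    intercept=intercept,
                    slope=slope,
                    residual_se=rse,
                )
        elif spec.comparison == "all_both_classes":
            self.limits_ = {}
            for disc in spec.regions:
                values = _discriminant(self.X_, disc)
                cutoff = roc_optimal_cutoff(
                    values[self.y_ == LABEL_NORMAL], values[self.y_ == LABEL_ABNORMAL]
                )
                self.limits_[disc] = NormalLimitModel(
                    region=disc,
                    form="constant",
                    method="roc_optimal",
                    k=0.0,
                    support_n=int(self.X_.shape[0]),
                    intercept=cutoff,
                )
        else:
            self.limits_ = None  # per-test-subject fitting
        return self

    # -- per-subject comparator selection ----------------------------------
    def _windowed(self, mask_rows: np.ndarray, test_age: float, per_class: bool) -> np.ndarray:
        """Boolean row mask of comparators, widening the window as needed."""
        ages = self.X_[:, _AGE_COL]
        window = self.window
        if window <= 0:
            raise InvalidParameterError("window must be > 0")
        while True:
            sel = mask_rows & (np.abs(ages - test_age) <= window)
            if per_class:
                n_no = int(np.sum(sel & (self.y_ == LABEL_NORMAL)))
                n_ab = int(np.sum(sel & (self.y_ == LABEL_ABNORMAL)))
                enough = min(n_no, n_ab) >= self.min_support
            else:
                enough = int(sel.sum()) >= self.min_support
            if enough:
                if window != self.window:
                    logger.info(
                        "age window widened to ±%.1f y for test age %.1f", window, test_age
                    )
                return sel
            if window >= self.max_window:
                raise InsufficientComparatorsError(
                    f"cannot reach min_support={self.min_support} comparators "
                    f"within ±{self.max_window} y of age {test_age}"
                )
            window += self.widen_step

    def _limits_for_subject(self, test_age: float) -> dict[str, NormalLimitModel]:
        spec = self._spec()
        if spec.comparison == "age_matched_normals":
            sel = self._windowed(self.y_ == LABEL_NORMAL, test_age, per_class=False)
            rows = self.X_[sel]
            limits = {}
            for region in spec.regions:
                vals = rows[:, _column_index(region)]
                if spec.rule == "mean_minus_ksd":
                    cut = limit_mean_minus_ksd(vals, spec.k)
                else:
                    cut = limit_minimum(vals)
                limits[region] = NormalLimitModel(
                    region=region,
                    form="constant",
                    method=spec.rule,
                    k=spec.k,
                    support_n=int(vals.size),
                    intercept=cut,
                )
            return limits
        # age_matched_both_classes: ROC refit inside the window
        sel = self._windowed(np.ones(len(self.y_), dtype=bool), test_age, per_class=True)
        limits = {}
        for disc in spec.regions:
            values = _discriminant(self.X_[sel], disc)
            labels = self.y_[sel]
            cutoff = roc_optimal_cutoff(
                values[labels == LABEL_NORMAL], values[labels == LABEL_ABNORMAL]
            )
            limits[disc] = NormalLimitModel(
                region=disc,
                form="constant",
                method="roc_optimal",
                k=0.0,
                support_n=int(sel.sum()),
                intercept=cutoff,
            )
        return limits

    def _subject_limits(self, test_age: float) -> dict[str, NormalLimitModel]:
        spec = self._spec()
        if self.limits_ is not None:
            if spec.comparison == "all_normals" and self.se_kind == "mean":
                normal_rows = self.X_[self.y_ == LABEL_NORMAL]
                out = {}
                for region in spec.regions:
                    cut = limit_regression_minus_kse(
                        list(
                            zip(
                                normal_rows[:, _AGE_COL],
                                normal_rows[:, _column_index(region)],
                            )
                        ),
                        test_age,
                        spec.k,
                        se_kind="mean",
                    )
                    out[region] = NormalLimitModel(
                        region=region,
                        form="constant",
                        method="regression_minus_kse",
                        k=spec.k,
                        support_n=int(normal_rows.shape[0]),
                        intercept=cut,
                    )
                return out
            return self.limits_
        return self._limits_for_subject(test_age)

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "X_")
        X, _ = self._validate_xy(X)
        spec = self._spec()
        out = []
        for row in X:
            age = row[_AGE_COL]
            limits = self._subject_limits(age)
            values = {
                name: float(_discriminant(row[None, :], name)[0]) for name in spec.regions
            }
            out.append(classify_sq(values, age, limits))
        return np.asarray(out)

    def predict_detail(self, X):
        """Per-subject table of each discriminant's value, cut-off and flag."""
        import pandas as pd

        check_is_fitted(self, "X_")
        X, _ = self._validate_xy(X)
        spec = self._spec()
        rows = []
        for row in X:
            age = row[_AGE_COL]
            limits = self._subject_limits(age)
            entry = {"age": age}
            flagged = False
            for name in spec.regions:
                value = float(_discriminant(row[None, :], name)[0])
                cut = limits[name].cutoff_at(age)
                below = value < cut
                flagged = flagged or below
                entry[f"{name}_sbr"] = value
                entry[f"{name}_cutoff"] = cut
                entry[f"{name}_below"] = below
            entry["predicted_label"] = LABEL_ABNORMAL if flagged else LABEL_NORMAL
            rows.append(entry)
        return pd.DataFrame(rows)


def run_sq_method(
    spec: str | SQMethodSpec, train: Cohort, test: Cohort, **kwargs
) -> np.ndarray:
    """Fit one semi-quantification method on ``train`` and label ``test``."""
    clf = SemiQuantClassifier(method=spec, **kwargs)
    X_tr, y_tr = cohort_to_xy(train)
    clf.fit(X_tr, y_tr)
    X_te, _ = cohort_to_xy(test)
    return clf.predict(X_te)
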