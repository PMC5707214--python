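"""SVM classification pipelines (13 methods): features → PCA → SVM.

Each pipeline standardizes its inputs, optionally projects voxel features
onto the first 3/5/10/15/20 principal components, and trains a soft-margin
SVM (linear or RBF kernel).  Hyperparameters are chosen by a coarse grid
search — C over 2⁻³ … 2⁸ and γ over 2⁻⁸ … 2³, both in ×2 steps — scored by
the mean F-score (positive class = abnormal) over a stratified inner
cross-validation of the training data.  Everything fitted (scaler, PCA,
hyperparameters, SVM) is a function of training rows only.

The 13 built-in methods:

======  =========  ======  =======
method  features   # PCs   kernel
======  =========  ======  =======
ML 1-5  PCs        3/5/10/15/20  linear
ML 6-10 PCs        3/5/10/15/20  RBF
ML 11   voxels     —       linear (a kernel on raw voxels invites overfitting)
ML 12   SBRs       —       linear
ML 13   SBRs       —       RBF
======  =========  ======  =======

Age rides along as the last feature column of every family; for PC
pipelines it bypasses the projection and is standardized together with the
projected coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import PCA
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .errors import InsufficientDataError, InvalidParameterError, StratificationError
from .synth import LABEL_ABNORMAL

__all__ = [
    "MLMethodSpec",
    "ML_METHODS",
    "GridSpec",
    "SVMPipelineClassifier",
    "standardize_fit",
    "pca_fit",
    "f_score",
    "grid_search",
    "fit_predict",
]

#: permitted principal-component counts (configurable via MLMethodSpec)
DEFAULT_PC_CHOICES = (3, 5, 10, 15, 20)


@dataclass(frozen=True)
class MLMethodSpec:
    """Declarative description of one SVM pipeline."""

    ml_id: int
    feature_kind: str  # "pcs" | "voxels" | "sbrs"
    kernel: str  # "linear" | "rbf"
    n_components: int | None = None

    def __post_init__(self) -> None:
        if self.feature_kind not in ("pcs", "voxels", "sbrs"):
            raise InvalidParameterError(f"unknown feature kind {self.feature_kind!r}")
        if self.kernel not in ("linear", "rbf"):
            raise InvalidParameterError(f"unknown kernel {self.kernel!r}")
        if self.feature_kind == "voxels" and self.kernel != "linear":
            raise InvalidParameterError("voxel features admit only a linear kernel")
        if self.feature_kind == "pcs" and self.n_components is None:
            raise InvalidParameterError("pcs feature kind requires n_components")

    @property
    def name(self) -> str:
        return f"ML{self.ml_id}"

    def describe(self) -> str:
        pcs = f" ({self.n_components} PCs)" if self.feature_kind == "pcs" else ""
        return f"{self.feature_kind}{pcs} | {self.kernel} SVM"


def _build_ml_methods() -> dict[str, MLMethodSpec]:
    specs = []
    for i, n in enumerate(DEFAULT_PC_CHOICES, start=1):
        specs.append(MLMethodSpec(i, "pcs", "linear", n))
    for i, n in enumerate(DEFAULT_PC_CHOICES, start=6):
        specs.append(MLMethodSpec(i, "pcs", "rbf", n))
    specs.append(MLMethodSpec(11, "voxels", "linear"))
    specs.append(MLMethodSpec(12, "sbrs", "linear"))
    specs.append(MLMethodSpec(13, "sbrs", "rbf"))
    return {s.name: s for s in specs}


#: the 13 built-in pipelines
ML_METHODS = _build_ml_methods()


@dataclass(frozen=True)
class GridSpec:
    """Coarse hyperparameter grid scored by mean inner-fold F-score."""

    c_values: tuple[float, ...] = tuple(float(2.0**e) for e in range(-3, 9))
    gamma_values: tuple[float, ...] = tuple(float(2.0**e) for e in range(-8, 4))

    def __post_init__(self) -> None:
        if not self.c_values or not self.gamma_values:
            raise InvalidParameterError("hyperparameter grids must be non-empty")


# ---------------------------------------------------------------------------
# spec-surface primitives


def standardize_fit(train_matrix: np.ndarray) -> StandardScaler:
    """Fit per-column (mean, sample SD) scaling on training rows.

    Zero-variance columns are mapped to 0 (the scaler guards the division).
    """
    train_matrix = np.asarray(train_matrix, dtype=float)
    if train_matrix.ndim != 2 or train_matrix.shape[0] < 2:
        raise InsufficientDataError("standardization needs at least 2 training rows")
    return StandardScaler().fit(train_matrix)


def pca_fit(train_matrix: np.ndarray, n_components: int, random_state: int | None = None) -> PCA:
    """Fit a PCA projection on training rows only."""
    train_matrix = np.asarray(train_matrix, dtype=float)
    max_n = min(train_matrix.shape[0] - 1, train_matrix.shape[1])
    if not 1 <= n_components <= max_n:
        raise InvalidParameterError(
            f"n_components={n_components} out of range 1..{max_n} for shape {train_matrix.shape}"
        )
    return PCA(n_components=n_components, svd_solver="randomized", random_state=random_state).fit(
        train_matrix
    )


def f_score(predictions, labels, positive_class: str = LABEL_ABNORMAL) -> float:
    """Harmonic mean of precision and recall for the positive (abnormal) class.

    Returns 0 when the classifier predicts no positives at all.
    """
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise InvalidParameterError("predictions and labels must have equal length")
    if positive_class not in set(map(str, labels)):
        raise InvalidParameterError("labels contain no positive-class examples")
    return float(
        f1_score(labels.astype(str), predictions.astype(str), pos_label=positive_class, zero_division=0)
    )


# ---------------------------------------------------------------------------
# estimator


class SVMPipelineClassifier(ClassifierMixin, BaseEstimator):
    """standardize → (optional PCA) → SVM, with nested grid search.

    Parameters
    ----------
    feature_kind:
        ``"sbrs"``, ``"voxels"`` or ``"pcs"``.  For ``"pcs"`` the last
        column of ``X`` is taken as age and bypasses the projection.
    n_components:
        Number of principal components (``"pcs"`` only).
    kernel:
        ``"linear"`` or ``"rbf"``; voxel features admit only linear.
    grid:
        :class:`GridSpec` of candidate (C, γ); γ is ignored for linear.
    inner_k:
        Stratified folds of the inner selection loop (single repetition).
    standardize_projected:
        If True (default), standardize PC coefficients after projection;
        if False, standardize the voxel block before the PCA instead.
    random_state:
        Seeds the inner-fold shuffling and the randomized PCA solver.

    Attributes (after :meth:`fit`)
    ------------------------------
    chosen_c_, chosen_gamma_ : selected hyperparameters
    grid_scores_ : list of ((C, γ), mean inner F-score)
    scaler_, pca_, svc_ : the refitted pipeline stages
    """

    def __init__(
        self,
        feature_kind: str = "sbrs",
        n_components: int | None = None,
        kernel: str = "linear",
        grid: GridSpec | None = None,
        inner_k: int = 10,
        standardize_projected: bool = True,
        random_state: int | None = None,
    ):
        self.feature_kind = feature_kind
        self.n_components = n_components
        self.kernel = kernel
        self.grid = grid
        self.inner_k = inner_k
        self.standardize_projected = standardize_projected
        self.random_state = random_state

    @classmethod
    def from_spec(cls, spec: MLMethodSpec | str, **kwargs) -> "SVMPipelineClassifier":
        if isinstance(spec, str):
            if spec not in ML_METHODS:
                raise InvalidParameterError(f"unknown ML method {spec!r}")
            spec = ML_METHODS[spec]
        return cls(
            feature_kind=spec.feature_kind,
            n_components=spec.n_components,
            kernel=spec.kernel,
            **kwargs,
        )

    # -- internals ---------------------------------------------------------
    def _validate(self):
        # reuse the spec dataclass validation (voxels ⇒ linear, pcs ⇒ n set)
        MLMethodSpec(0, self.feature_kind, self.kernel, self.n_components)
        if self.inner_k < 2:
            raise InvalidParameterError("inner_k must be >= 2")

    def _grid(self) -> GridSpec:
        return self.grid if self.grid is not None else GridSpec()

    def _fit_transformers(self, X_tr: np.ndarray):
        """Fit scaler (+PCA) on training rows; return (transform, scaler, pca)."""
        if self.feature_kind != "pcs":
            scaler = standardize_fit(X_tr)
            return (lambda X: scaler.transform(X)), scaler, None

        vox, age = X_tr[:, :-1], X_tr[:, -1:]
        if self.standardize_projected:
            pca = pca_fit(vox, self.n_components, random_state=self.random_state)
            proj = np.hstack([pca.transform(vox), age])
            scaler = standardize_fit(proj)

            def transform(X):
                return scaler.transform(np.hstack([pca.transform(X[:, :-1]), X[:, -1:]]))

        else:
            pre = standardize_fit(vox)
            pca = pca_fit(pre.transform(vox), self.n_components, random_state=self.random_state)
            age_scaler = standardize_fit(age)
            scaler = (pre, age_scaler)

            def transform(X):
                return np.hstack(
                    [pca.transform(pre.transform(X[:, :-1])), age_scaler.transform(X[:, -1:])]
                )

        return transform, scaler, pca

    def _candidate_params(self):
        grid = self._grid()
        if self.kernel == "linear":
            return [(c, None) for c in grid.c_values]
        return [(c, g) for c in grid.c_values for g in grid.gamma_values]

    def _make_svc(self, c: float, gamma: float | None) -> SVC:
        if self.kernel == "linear":
            return SVC(kernel="linear", C=c)
        return SVC(kernel="rbf", C=c, gamma=gamma)

    def _grid_search(self, X: np.ndarray, y: np.ndarray):
        candidates = self._candidate_params()
        if len(candidates) == 1:
            return candidates[0], [(candidates[0], np.nan)]
        counts = {c: int((y == c).sum()) for c in np.unique(y)}
        if min(counts.values()) < self.inner_k:
            raise StratificationError(
                f"smallest class ({min(counts.values())}) < inner_k={self.inner_k}"
            )
        skf = StratifiedKFold(n_splits=self.inner_k, shuffle=True, random_state=self.random_state)
        scores = np.zeros(len(candidates))
        n_folds = 0
        for tr_idx, te_idx in skf.split(X, y):
            X_tr, y_tr = X[tr_idx], y[tr_idx]
            X_te, y_te = X[te_idx], y[te_idx]
            transform, _, _ = self._fit_transformers(X_tr)
            Z_tr, Z_te = transform(X_tr), transform(X_te)
            for j, (c, g) in enumerate(candidates):
                svc = self._make_svc(c, g).fit(Z_tr, y_tr)
                scores[j] += f_score(svc.predict(Z_te), y_te)
            n_folds += 1
        scores /= n_folds
        best = int(np.argmax(scores))  # candidates ordered by (C, γ): first max wins ties
        return candidates[best], list(zip(candidates, scores))

    # -- sklearn API -------------------------------------------------------
    def fit(self, X, y):
        self._validate()
        X = np.asarray(X, dtype=float)
        y = np.asarray([str(v) for v in np.asarray(y)])
        if X.ndim != 2:
            raise InvalidParameterError("X must be 2-D")
        if len(np.unique(y)) < 2:
            raise InsufficientDataError("training data must contain both classes")
        self.classes_ = np.unique(y)
        self.n_features_in_ = X.shape[1]

        (c, g), self.grid_scores_ = self._grid_search(X, y)
        self.chosen_c_ = c
        self.chosen_gamma_ = g
        transform, self.scaler_, self.pca_ = self._fit_transformers(X)
        self._transform = transform
        self.svc_ = self._make_svc(c, g).fit(transform(X), y)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "svc_")
        X = np.asarray(X, dtype=float)
        return self.svc_.predict(self._transform(X))

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "svc_")
        X = np.asarray(X, dtype=float)
        return self.svc_.decision_function(self._transform(X))


# ---------------------------------------------------------------------------
# functional wrappers


def grid_search(
    X,
    y,
    spec: MLMethodSpec | str,
    grid: GridSpec | None = None,
    inner_k: int = 10,
    seed: int | None = None,
):
    """Return the (C, γ) with the highest mean inner-fold F-score."""
    clf = SVMPipelineClassifier.from_spec(spec, grid=grid, inner_k=inner_k, random_state=seed)
    clf._validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray([str(v) for v in np.asarray(y)])
    (c, g), _ = clf._grid_search(X, y)
    return c, g


def fit_predict(
    spec: MLMethodSpec | str,
    X_train,
    y_train,
    X_test,
    grid: GridSpec | None = None,
    inner_k: int = 10,
    seed: int | None = None,
) -> np.ndarray:
    """Grid-search on the training split, refit, and label the test split."""
    clf = SVMPipelineClassifier.from_spec(spec, grid=grid, inner_k=inner_k, random_state=seed)
    clf.fit(X_train, y_train)
    return clf.predict(X_test)
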