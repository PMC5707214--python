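"""Repeated, stratified, nested 10-fold cross-validation and report tables.

Every method — semi-quantification or SVM pipeline — is evaluated under the
same scheme: the cohort is split into k stratified folds, each method is
trained on k−1 folds (normal limits re-estimated, ML grid search re-run)
and scored on the held-out fold, and the whole partition is redrawn
``repeats`` times from seeded sub-seeds.  All methods share identical fold
assignments within a repeat, so comparisons between methods are paired.
Accuracy, sensitivity and specificity (abnormal = positive class) are
aggregated to mean/SD over the repeat × fold cells.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .errors import (
    FpcitBenchError,
    InvalidParameterError,
    StratificationError,
    UndefinedMetricError,
)
from .features import FeatureSet, extract_features
from .ml import ML_METHODS, GridSpec, SVMPipelineClassifier
from .semiquant import SQ_METHODS, SemiQuantClassifier, cohort_to_xy
from .synth import (
    LABEL_ABNORMAL,
    LABEL_NORMAL,
    Cohort,
    PRESETS,
    default_geometry,
    generate_cohort,
    generate_volume,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FoldAssignment",
    "CVSummary",
    "stratified_folds",
    "confusion_metrics",
    "synthesize_voxel_features",
    "run_experiment",
    "write_report",
    "run_experiment_from_config",
]

_SEED_MOD = 2**31


def repeat_seed(master_seed: int, repeat_index: int) -> int:
    """Deterministic per-repeat sub-seed (fixed counter scheme)."""
    return int((master_seed * 100003 + 7919 * (repeat_index + 1)) % _SEED_MOD)


def method_seed(master_seed: int, repeat_index: int, fold_index: int) -> int:
    """Sub-seed for stochastic steps inside one (repeat, fold) cell."""
    return int((master_seed * 100003 + 7919 * (repeat_index + 1) + 101 * (fold_index + 1) + 1) % _SEED_MOD)


@dataclass(frozen=True)
class FoldAssignment:
    """A seeded stratified partition: fold index per cohort row."""

    membership: tuple[int, ...]
    k: int
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.membership) == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.membership) != fold)


def stratified_folds(labels, k: int, seed: int) -> FoldAssignment:
    """Label-stratified partition into k folds (per-fold class counts ±1)."""
    labels = np.asarray([str(v) for v in np.asarray(labels)])
    if k < 2:
        raise InvalidParameterError("k must be >= 2")
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise StratificationError(
            f"smallest class has {counts.min()} members; cannot stratify into {k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % _SEED_MOD)
    membership = np.empty(len(labels), dtype=int)
    for fold, (_, te_idx) in enumerate(skf.split(np.zeros((len(labels), 1)), labels)):
        membership[te_idx] = fold
    return FoldAssignment(membership=tuple(int(m) for m in membership), k=k, seed=seed)


def confusion_metrics(predictions, labels, positive_class: str = LABEL_ABNORMAL):
    """(accuracy, sensitivity, specificity) with abnormal as positive class."""
    predictions = np.asarray([str(v) for v in np.asarray(predictions)])
    labels = np.asarray([str(v) for v in np.asarray(labels)])
    if predictions.shape != labels.shape:
        raise InvalidParameterError("predictions and labels must have equal length")
    pos = labels == positive_class
    if not pos.any() or pos.all():
        raise UndefinedMetricError("both classes must be present in the labels")
    pred_pos = predictions == positive_class
    tp = int(np.sum(pred_pos & pos))
    tn = int(np.sum(~pred_pos & ~pos))
    fp = int(np.sum(pred_pos & ~pos))
    fn = int(np.sum(~pred_pos & pos))
    n = tp + tn + fp + fn
    return (tp + tn) / n, tp / (tp + fn), tn / (tn + fp)


def synthesize_voxel_features(
    cohort: Cohort,
    geometry=None,
    noise_sd: float = 0.05,
    seed: int = 0,
    kind: str = "pcs",
) -> FeatureSet:
    """Render phantom volumes for a cohort and extract voxel features.

    Volumes are generated one at a time and discarded after extraction, so
    cohort-scale feature building stays within modest memory.
    """
    if geometry is None:
        geometry = default_geometry()

    def volume_for(subject_id: str):
        record = next(r for r in cohort if r.id == subject_id)
        stable = zlib.crc32(subject_id.encode()) % 65521
        sub_seed = int((seed * 100003 + stable) % _SEED_MOD)
        return generate_volume(record, geometry, noise_sd=noise_sd, seed=sub_seed)

    return extract_features(cohort, volumes=volume_for, kind=kind)


@dataclass
class CVSummary:
    """Per-cell metrics and mean/SD aggregates for one method."""

    method_id: str
    descriptor: str
    cells: pd.DataFrame  # columns: repeat, fold, accuracy, sensitivity, specificity

    @property
    def coverage(self) -> float:
        """Fraction of (repeat, fold) cells that completed without error."""
        return float(self.cells["accuracy"].notna().mean())

    def _agg(self, metric: str) -> tuple[float, float]:
        vals = self.cells[metric].dropna()
        return float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0

    @property
    def mean_accuracy(self) -> float:
        return self._agg("accuracy")[0]

    @property
    def mean_sensitivity(self) -> float:
        return self._agg("sensitivity")[0]

    @property
    def mean_specificity(self) -> float:
        return self._agg("specificity")[0]

    def row(self) -> dict:
        acc, acc_sd = self._agg("accuracy")
        sens, sens_sd = self._agg("sensitivity")
        spec, spec_sd = self._agg("specificity")
        return {
            "method": self.method_id,
            "descriptor": self.descriptor,
            "accuracy": acc,
            "accuracy_sd": acc_sd,
            "sensitivity": sens,
            "sensitivity_sd": sens_sd,
            "specificity": spec,
            "specificity_sd": spec_sd,
            "coverage": self.coverage,
        }


def _method_descriptor(method_id: str) -> str:
    if method_id in SQ_METHODS:
        return SQ_METHODS[method_id].describe()
    if method_id in ML_METHODS:
        return ML_METHODS[method_id].describe()
    raise InvalidParameterError(f"unknown method {method_id!r}")


def _needs_voxels(method_id: str) -> bool:
    return method_id in ML_METHODS and ML_METHODS[method_id].feature_kind in ("pcs", "voxels")


def run_experiment(
    methods: list[str],
    cohort: Cohort,
    voxel_features: FeatureSet | None = None,
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
    inner_k: int = 10,
    grid: GridSpec | None = None,
    sq_kwargs: dict | None = None,
) -> dict[str, CVSummary]:
    """Cross-validate every method on one cohort with paired fold splits.

    ``voxel_features`` must be supplied (e.g. from
    :func:`synthesize_voxel_features`) when any requested ML method uses
    voxel or principal-component features.  A method that fails on a fold
    (e.g. comparator exhaustion) records that cell as missing; the summary
    reports coverage.
    """
    for m in methods:
        _method_descriptor(m)  # validates ids early
    if any(_needs_voxels(m) for m in methods) and voxel_features is None:
        raise InvalidParameterError(
            "voxel_features required for voxel/PC-based ML methods"
        )
    labels = cohort.labels
    X_sbr, y = cohort_to_xy(cohort)
    X_vox = voxel_features.values if voxel_features is not None else None
    if X_vox is not None and X_vox.shape[0] != len(cohort):
        raise InvalidParameterError("voxel feature rows must match cohort size")

    cells: dict[str, list[dict]] = {m: [] for m in methods}
    for r in range(repeats):
        assignment = stratified_folds(labels, k, repeat_seed(seed, r))
        for f in range(k):
            tr, te = assignment.train_indices(f), assignment.test_indices(f)
            for m in methods:
                cell = {"repeat": r, "fold": f}
                try:
                    if m in SQ_METHODS:
                        clf = SemiQuantClassifier(method=m, **(sq_kwargs or {}))
                        clf.fit(X_sbr[tr], y[tr])
                        pred = clf.predict(X_sbr[te])
                    else:
                        spec = ML_METHODS[m]
                        X = X_sbr if spec.feature_kind == "sbrs" else X_vox
                        clf = SVMPipelineClassifier.from_spec(
                            spec,
                            grid=grid,
                            inner_k=inner_k,
                            random_state=method_seed(seed, r, f),
                        )
                        clf.fit(X[tr], y[tr])
                        pred = clf.predict(X[te])
                    acc, sens, spec_ = confusion_metrics(pred, y[te])
                    cell.update(accuracy=acc, sensitivity=sens, specificity=spec_)
                except FpcitBenchError as exc:
                    logger.warning("method %s failed on repeat %d fold %d: %s", m, r, f, exc)
                    cell.update(accuracy=np.nan, sensitivity=np.nan, specificity=np.nan)
                cells[m].append(cell)
    return {
        m: CVSummary(
            method_id=m,
            descriptor=_method_descriptor(m),
            cells=pd.DataFrame(cells[m], columns=["repeat", "fold", "accuracy", "sensitivity", "specificity"]),
        )
        for m in methods
    }


def write_report(
    summaries: dict[str, CVSummary],
    out_dir: str | Path,
    name: str = "report",
    header: dict | None = None,
) -> tuple[Path, Path]:
    """Write the per-method summary as a 2-decimal CSV plus a full-precision JSON twin."""
    if not summaries:
        raise InvalidParameterError("no summaries to report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = [s.row() for s in summaries.values()]

    csv_path = out_dir / f"{name}.csv"
    cols = [
        "method",
        "descriptor",
        "accuracy",
        "accuracy_sd",
        "sensitivity",
        "sensitivity_sd",
        "specificity",
        "specificity_sd",
        "coverage",
    ]
    lines = [",".join(cols)]
    for row in rows:
        cells = []
        for c in cols:
            v = row[c]
            if isinstance(v, float):
                cells.append(f"{v:.2f}")
            else:
                cells.append(f'"{v}"' if "," in str(v) else str(v))
        lines.append(",".join(cells))
    csv_path.write_text("\n".join(lines) + "\n")

    json_path = out_dir / f"{name}.json"
    payload = {
        "header": {
            "seed_scheme": "repeat_seed(seed, r) = (seed*100003 + 7919*(r+1)) mod 2^31",
            **(header or {}),
        },
        "methods": {
            m: {
                **s.row(),
                "cells": s.cells.to_dict(orient="records"),
            }
            for m, s in summaries.items()
        },
    }
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True, allow_nan=True))
    return csv_path, json_path


def run_experiment_from_config(config: dict | str | Path, out_dir: str | Path | None = None):
    """Run a full experiment from a YAML config (or an equivalent dict).

    Config schema::

        cohort:
          preset: research | clinical      # or csv: path/to/cohort.csv
          seed: 1                          # generator seed (preset cohorts)
          n_normal: 209                    # optional count overrides
          n_abnormal: 448
        methods: [SQ1, ..., ML13]          # default: all 31
        k: 10
        repeats: 10
        seed: 1                            # cross-validation master seed
        volumes:                           # only needed for voxel/PC methods
          geometry_size: 64
          noise_sd: 0.05
        out_dir: results/
        report_name: report
    """
    import yaml

    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)

    cohort_cfg = config.get("cohort", {})
    if "csv" in cohort_cfg:
        cohort = Cohort.from_csv(cohort_cfg["csv"])
    else:
        preset = cohort_cfg.get("preset", "research")
        if preset not in PRESETS:
            raise InvalidParameterError(f"unknown preset {preset!r}")
        overrides = {
            key: cohort_cfg[key]
            for key in ("n_normal", "n_abnormal")
            if key in cohort_cfg
        }
        cohort = generate_cohort(PRESETS[preset](seed=cohort_cfg.get("seed", 0), **overrides))

    methods = config.get("methods") or (list(SQ_METHODS) + list(ML_METHODS))
    seed = int(config.get("seed", 0))
    k = int(config.get("k", 10))
    repeats = int(config.get("repeats", 10))

    voxel_features = None
    if any(_needs_voxels(m) for m in methods):
        vol_cfg = config.get("volumes", {})
        geometry = default_geometry(size=int(vol_cfg.get("geometry_size", 64)))
        voxel_features = synthesize_voxel_features(
            cohort,
            geometry=geometry,
            noise_sd=float(vol_cfg.get("noise_sd", 0.05)),
            seed=seed,
        )

    summaries = run_experiment(
        methods, cohort, voxel_features=voxel_features, k=k, repeats=repeats, seed=seed
    )
    out = Path(out_dir or config.get("out_dir", "results"))
    header = {"seed": seed, "k": k, "repeats": repeats, "n_subjects": len(cohort)}
    write_report(summaries, out, name=config.get("report_name", "report"), header=header)
    return summaries
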