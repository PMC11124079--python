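"""Toxicity QSAR protocols: leave-one-out linear regression, 10-fold
logistic classification with training-fold minority oversampling, and
fingerprint feature assembly (base features / fingerprint sections /
concatenation of both).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .fingerprint import NanoFingerprint

__all__ = [
    "QSARDataset",
    "FittedModel",
    "EvalReport",
    "assemble_features",
    "confusion_metrics",
    "evaluate_loo_linear",
    "evaluate_cv_logistic",
    "fit_linear",
    "predict_ldh",
]

logger = logging.getLogger(__name__)

LDH_FEATURES = ("size", "size_water", "size_pbs", "concentration", "zeta_potential")
TOX_FEATURES = (
    "CoreSize", "HydroSize", "SurfCharge", "SurfArea",
    "Ec", "Time", "Dose", "Eneg", "NOxygen",
)


@dataclass
class QSARDataset:
    """Feature matrix + target vector, with names, for one modelling task."""

    features: np.ndarray
    feature_names: list[str]
    target: np.ndarray
    group_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.target = np.asarray(self.target, dtype=float)
        n, p = self.features.shape
        if len(self.feature_names) != p:
            raise ValueError(f"{len(self.feature_names)} names for {p} columns")
        if len(self.target) != n:
            raise ValueError(f"{len(self.target)} targets for {n} rows")
        if not np.all(np.isfinite(self.features)) or not np.all(np.isfinite(self.target)):
            raise ValueError("dataset contains missing or non-finite values")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def p(self) -> int:
        return self.features.shape[1]

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, target_column: str, feature_columns: Sequence[str] | None = None
    ) -> "QSARDataset":
        if feature_columns is None:
            feature_columns = [c for c in frame.columns if c != target_column]
        return cls(
            features=frame[list(feature_columns)].to_numpy(dtype=float),
            feature_names=list(feature_columns),
            target=frame[target_column].to_numpy(dtype=float),
        )


@dataclass
class FittedModel:
    kind: str  # "linear" | "logistic"
    coefficients: np.ndarray
    intercept: float
    feature_names: list[str]
    protocol: dict = field(default_factory=dict)

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        eta = x @ self.coefficients + self.intercept
        if self.kind == "logistic":
            return 1.0 / (1.0 + np.exp(-eta))
        return eta


@dataclass
class EvalReport:
    """Averaged fold metrics. FP/FN are mean counts per evaluation fold."""

    balanced_accuracy: float | None = None
    accuracy: float | None = None
    precision: float | None = None
    recall: float | None = None
    false_positives: float | None = None
    false_negatives: float | None = None
    mse: float | None = None
    std: float | None = None

    def as_dict(self) -> dict[str, float]:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def _section_columns(fp: NanoFingerprint, sections: Iterable[int]) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = []
    names: list[str] = []
    for s in sorted(set(sections)):
        sl = fp.section_slice(s)
        cols.append(fp.vector[sl])
        names.extend(f"fp_s{s}_{i}" for i in range(sl.stop - sl.start))
    if not cols:
        return np.empty((0,)), []
    return np.concatenate(cols), names


def assemble_features(
    base: QSARDataset,
    fingerprints: Sequence[NanoFingerprint] | None = None,
    sections: Iterable[int] = (),
    include_base: bool = True,
) -> QSARDataset:
    """Append fingerprint sections (in section order) to a base dataset.

    ``include_base=False`` yields the fingerprint-only design (Test2);
    the default concatenation is Test3; empty ``sections`` returns the
    base unchanged (Test1).
    """
    sections = sorted(set(sections))
    if not sections:
        return base if include_base else QSARDataset(
            np.empty((base.n, 0)), [], base.target, base.group_ids
        )
    if fingerprints is None or len(fingerprints) != base.n:
        raise ValueError(
            f"need one fingerprint per row: {0 if fingerprints is None else len(fingerprints)} "
            f"fingerprints for {base.n} rows"
        )
    max_set = {fp.max_bonds for fp in fingerprints}
    if len(max_set) != 1:
        raise ValueError(f"fingerprints have mixed MAX values: {sorted(max_set)}")
    blocks = []
    names: list[str] = []
    for fp in fingerprints:
        vec, names = _section_columns(fp, sections)
        blocks.append(vec)
    fp_matrix = np.vstack(blocks)
    if include_base:
        features = np.hstack([base.features, fp_matrix])
        all_names = list(base.feature_names) + names
    else:
        features = fp_matrix
        all_names = names
    return QSARDataset(features, all_names, base.target, base.group_ids)


def _drop_zero_variance(x: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    keep = x.std(axis=0) > 0
    dropped = [n for n, k in zip(names, keep) if not k]
    if dropped:
        logger.info("dropping %d zero-variance columns", len(dropped))
    return x[:, keep], [n for n, k in zip(names, keep) if k]


def evaluate_loo_linear(data: QSARDataset) -> EvalReport:
    """Leave-one-out ordinary least squares.

    Each sample is predicted by a model fitted on the other n-1; the report
    carries the mean and standard deviation of the squared errors.
    """
    if data.n < 3:
        raise ValueError(f"need at least 3 samples for LOO, got {data.n}")
    x, names = _drop_zero_variance(data.features, list(data.feature_names))
    design = np.hstack([np.ones((data.n, 1)), x])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        corr = np.corrcoef(x, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"rank-deficient design (rank {rank} < {design.shape[1]}); "
            f"most collinear columns: {names[i]!r}, {names[j]!r}"
        )
    sq_errors = np.empty(data.n)
    for i in range(data.n):
        mask = np.ones(data.n, dtype=bool)
        mask[i] = False
        model = LinearRegression().fit(x[mask], data.target[mask])
        pred = model.predict(x[i : i + 1])[0]
        sq_errors[i] = (pred - data.target[i]) ** 2
    return EvalReport(mse=float(sq_errors.mean()), std=float(sq_errors.std()))


def confusion_metrics(truth: np.ndarray, pred: np.ndarray) -> dict[str, float]:
    """Fold metrics from 0/1 truth and prediction vectors.

    balanced_accuracy = (TPR + TNR) / 2; FP/FN are raw counts.
    """
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    tp = int(np.sum((pred == 1) & (truth == 1)))
    tn = int(np.sum((pred == 0) & (truth == 0)))
    fp = int(np.sum((pred == 1) & (truth == 0)))
    fn = int(np.sum((pred == 0) & (truth == 1)))
    tpr = tp / (tp + fn) if tp + fn else 0.0
    tnr = tn / (tn + fp) if tn + fp else 0.0
    return {
        "balanced_accuracy": (tpr + tnr) / 2,
        "accuracy": (tp + tn) / len(truth),
        "precision": tp / (tp + fp) if tp + fp else 0.0,
        "recall": tpr,
        "false_positives": fp,
        "false_negatives": fn,
    }


def _oversample_train(
    x: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Duplicate minority rows (with replacement) until classes balance."""
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts[0] == counts[1]:
        return x, y
    minority = classes[np.argmin(counts)]
    deficit = int(abs(counts[0] - counts[1]))
    idx = np.flatnonzero(y == minority)
    extra = rng.choice(idx, size=deficit, replace=True)
    return np.vstack([x, x[extra]]), np.concatenate([y, y[extra]])


def evaluate_cv_logistic(
    data: QSARDataset,
    folds: int = 10,
    oversample: bool = True,
    seed: int = 0,
    ridge: bool = False,
) -> EvalReport:
    """Stratified k-fold logistic regression with optional training-fold
    minority oversampling; evaluation folds are never resampled.

    Balanced accuracy = (TPR + TNR) / 2 averaged over folds; FP/FN are mean
    counts per fold. ``ridge=True`` switches from plain maximum likelihood
    to an L2-penalised fit for ill-conditioned fingerprint blocks.
    """
    y = data.target
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"binary target required, got classes {classes}")
    if folds < 2:
        raise ValueError(f"folds must be >= 2, got {folds}")
    x, _ = _drop_zero_variance(data.features, list(data.feature_names))
    rng = np.random.default_rng(seed)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    bal_acc, acc, prec, rec, fps, fns = [], [], [], [], [], []
    for train_idx, test_idx in skf.split(x, y):
        x_tr, y_tr = x[train_idx], y[train_idx]
        if oversample:
            x_tr, y_tr = _oversample_train(x_tr, y_tr, rng)
        # C=inf disables the penalty (plain maximum likelihood)
        model = LogisticRegression(
            C=1.0 if ridge else np.inf,
            solver="lbfgs",
            max_iter=2000,
        ).fit(x_tr, y_tr)
        pred = model.predict(x[test_idx])
        metrics = confusion_metrics(y[test_idx], pred)
        bal_acc.append(metrics["balanced_accuracy"])
        acc.append(metrics["accuracy"])
        prec.append(metrics["precision"])
        rec.append(metrics["recall"])
        fps.append(metrics["false_positives"])
        fns.append(metrics["false_negatives"])
    return EvalReport(
        balanced_accuracy=float(np.mean(bal_acc)),
        accuracy=float(np.mean(acc)),
        precision=float(np.mean(prec)),
        recall=float(np.mean(rec)),
        false_positives=float(np.mean(fps)),
        false_negatives=float(np.mean(fns)),
    )


def fit_linear(data: QSARDataset, protocol: Mapping | None = None) -> FittedModel:
    """Ordinary least squares on the full dataset."""
    model = LinearRegression().fit(data.features, data.target)
    return FittedModel(
        kind="linear",
        coefficients=np.asarray(model.coef_, dtype=float),
        intercept=float(model.intercept_),
        feature_names=list(data.feature_names),
        protocol=dict(protocol or {}),
    )


def predict_ldh(
    model: FittedModel,
    size_nm: float,
    concentration_mg_L: float,
    extra: Mapping[str, float] | None = None,
) -> float:
    """Predict LDH release from particle size (nm) and concentration (mg/L).

    Any further features the fitted model requires (e.g. size in water/PBS,
    zeta potential) are supplied through ``extra``; a missing feature is an
    error.
    """
    if model.kind != "linear":
        raise ValueError(f"LDH prediction requires a linear model, got {model.kind!r}")
    supplied = {"size": size_nm, "concentration": concentration_mg_L}
    supplied.update(extra or {})
    missing = [n for n in model.feature_names if n not in supplied]
    if missing:
        raise ValueError(f"missing model features: {missing}")
    row = np.array([supplied[n] for n in model.feature_names], dtype=float)
    return float(model.predict(row)[0])
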