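"""Multi-feature fusion classification of lameness severity.

Retained features are z-standardised on the training split, fused into
one vector, and fed to Random Forest, K-Nearest-Neighbours and RBF-SVM
classifiers.  Performance is reported from the 3x3 confusion matrix as
overall accuracy, per-class sensitivity and specificity, and the macro
F1 score, so every metric is recomputable from the matrix alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .features import FEATURE_NAMES
from .sequences import CLASS_LABELS

__all__ = [
    "ALGORITHMS",
    "FUSION_SUBSETS",
    "ClassificationReport",
    "standardize",
    "stratified_split",
    "train_and_predict",
    "evaluate",
    "run_fusion_grid",
]

ALGORITHMS = ("RF", "KNN", "SVM")

#: The studied fusion subsets: each single feature, then the cumulative
#: fusions up to the full six-feature set.
FUSION_SUBSETS: tuple[tuple[str, ...], ...] = (
    ("BC",),
    ("MAI",),
    ("VOB",),
    ("VOH",),
    ("TI",),
    ("LSAS",),
    ("BC", "MAI", "VOB"),
    ("BC", "MAI", "VOB", "VOH"),
    ("BC", "MAI", "VOB", "VOH", "TI"),
    FEATURE_NAMES,
)


def standardize(
    train_X: np.ndarray, apply_X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Z-score both tables with mean/sd estimated on the training table.

    A zero-variance training feature cannot be standardised and raises.
    """
    train_X = np.asarray(train_X, dtype=float)
    apply_X = np.asarray(apply_X, dtype=float)
    if train_X.shape[0] < 2:
        raise ValueError("need at least two training rows")
    mu = train_X.mean(axis=0)
    sd = train_X.std(axis=0)
    if (sd <= 1e-12 * (np.abs(mu) + 1.0)).any():
        raise ValueError("zero-variance feature cannot be standardised")
    return (train_X - mu) / sd, (apply_X - mu) / sd


def stratified_split(
    X, y, test_frac: float = 0.2, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stratified train/validation split (default 8:2 by class)."""
    return train_test_split(
        np.asarray(X, dtype=float),
        np.asarray(y),
        test_size=test_frac,
        stratify=np.asarray(y),
        random_state=int(seed) % 2**31,
    )


def _make_model(algo: str, seed: int, rf_trees: int, knn_k: int, svm_c: float):
    if algo == "RF":
        return RandomForestClassifier(
            n_estimators=rf_trees, random_state=int(seed) % 2**31, n_jobs=1
        )
    if algo == "KNN":
        return KNeighborsClassifier(n_neighbors=knn_k)
    if algo == "SVM":
        # gamma="auto" is 1/d on the z-scored features
        return SVC(kernel="rbf", C=svm_c, gamma="auto")
    raise ValueError(f"unknown algorithm {algo!r}")


def train_and_predict(
    train_X,
    train_y,
    test_X,
    algo: str = "RF",
    seed: int = 0,
    rf_trees: int = 500,
    knn_k: int = 5,
    svm_c: float = 1.0,
) -> np.ndarray:
    """Fit one classifier on standardised features and predict the test set."""
    train_Z, test_Z = standardize(train_X, test_X)
    model = _make_model(algo, seed, rf_trees, knn_k, svm_c)
    model.fit(train_Z, np.asarray(train_y))
    return model.predict(test_Z)


@dataclass
class ClassificationReport:
    """Confusion matrix and the metrics derived from it."""

    confusion: np.ndarray  # rows = true class, cols = predicted
    classes: tuple[str, ...]
    accuracy: float
    sensitivity: dict[str, float]
    specificity: dict[str, float]
    macro_f1: float
    algorithm: str = ""
    subset: tuple[str, ...] = field(default_factory=tuple)

    def to_row(self) -> dict:
        row = {
            "subset": "+".join(self.subset),
            "algorithm": self.algorithm,
            "ACC": self.accuracy,
            "macro_F1": self.macro_f1,
        }
        for c in self.classes:
            row[f"SENS_{c}"] = self.sensitivity[c]
            row[f"SPEC_{c}"] = self.specificity[c]
        return row


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined (zero denominator); reported as 0")
        return 0.0
    return num / den


def evaluate(
    y_true, y_pred, classes: tuple[str, ...] = CLASS_LABELS
) -> ClassificationReport:
    """Confusion-matrix metrics for a 3-class prediction.

    Accuracy is the fraction of correct predictions; per-class
    sensitivity TP/(TP+FN) and specificity TN/(TN+FP); macro F1 the
    arithmetic mean of per-class F1.  Degenerate classes (zero
    denominators) are reported as 0 with a warning.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    index = {c: i for i, c in enumerate(classes)}
    conf = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        conf[index[t], index[p]] += 1
    return report_from_confusion(conf, classes)


def report_from_confusion(
    conf: np.ndarray, classes: tuple[str, ...] = CLASS_LABELS
) -> ClassificationReport:
    """Derive every metric from a confusion matrix (rows = truth)."""
    conf = np.asarray(conf, dtype=int)
    n = conf.sum()
    acc = _safe_div(np.trace(conf), n, "accuracy")
    sens, spec, f1s = {}, {}, []
    for i, c in enumerate(classes):
        tp = conf[i, i]
        fn = conf[i].sum() - tp
        fp = conf[:, i].sum() - tp
        tn = n - tp - fn - fp
        sens[c] = _safe_div(tp, tp + fn, f"sensitivity[{c}]")
        spec[c] = _safe_div(tn, tn + fp, f"specificity[{c}]")
        precision = _safe_div(tp, tp + fp, f"precision[{c}]")
        recall = sens[c]
        if precision + recall == 0:
            f1s.append(0.0)
        else:
            f1s.append(2 * precision * recall / (precision + recall))
    return ClassificationReport(
        confusion=conf,
        classes=tuple(classes),
        accuracy=float(acc),
        sensitivity=sens,
        specificity=spec,
        macro_f1=float(np.mean(f1s)),
    )


def run_fusion_grid(
    features: pd.DataFrame,
    subsets: tuple[tuple[str, ...], ...] = FUSION_SUBSETS,
    algos: tuple[str, ...] = ALGORITHMS,
    seed: int = 0,
    test_frac: float = 0.2,
    rf_trees: int = 500,
    knn_k: int = 5,
    svm_c: float = 1.0,
) -> list[ClassificationReport]:
    """One classification report per (feature subset, algorithm).

    ``features`` is a tidy table with a ``label`` column and one column
    per feature name.  The stratified split is drawn once per call, so
    all grid cells compare on identical train/validation rows.
    """
    for subset in subsets:
        unknown = [f for f in subset if f not in features.columns]
        if unknown:
            raise ValueError(f"unknown feature name(s): {unknown}")
    y = features["label"].to_numpy()
    all_cols = sorted({f for subset in subsets for f in subset})
    X_all = features[all_cols].to_numpy(dtype=float)
    train_X, test_X, train_y, test_y = stratified_split(
        X_all, y, test_frac=test_frac, seed=seed
    )
    col = {name: j for j, name in enumerate(all_cols)}
    reports = []
    for subset in subsets:
        idx = [col[f] for f in subset]
        for algo in algos:
            pred = train_and_predict(
                train_X[:, idx],
                train_y,
                test_X[:, idx],
                algo=algo,
                seed=seed,
                rf_trees=rf_trees,
                knn_k=knn_k,
                svm_c=svm_c,
            )
            rep = evaluate(test_y, pred)
            rep.algorithm = algo
            rep.subset = tuple(subset)
            reports.append(rep)
    return reports


def grid_to_frame(reports: list[ClassificationReport]) -> pd.DataFrame:
    """Fusion-grid reports as a tidy table (one row per subset x algo)."""
    return pd.DataFrame([r.to_row() for r in reports])
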