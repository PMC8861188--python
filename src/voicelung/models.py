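"""Prediction tasks, cross-validation and the metric suite.

Three tasks are evaluated: FEV1% regression, ATS severity multi-class
classification, and normal/abnormal binary classification.  Each runs under
three algorithm families — linear (ordinary least squares, or logistic for
classification), random forest, and an RBF-kernel support vector machine —
with library-default hyperparameters, with and without the biological
covariates (the "_P" variants), giving 18 reports per partition.

Model training uses 10-fold cross-validation on the training split for a
training-performance estimate; the headline metrics come from the held-out
test split.  Classification reports include accuracy, per-class
precision/recall, macro and weighted F1, sensitivity (recall of the
abnormal class), specificity and the confusion matrix; the binary task adds
ROC points and AUC.  SVM ROC scores come from the decision-function ranking
(no probability calibration).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.metrics import (
    auc as _trapezoid_auc,
    confusion_matrix,
    precision_recall_fscore_support,
    roc_curve,
)
from sklearn.model_selection import KFold
from sklearn.svm import SVC, SVR

from .dataset import (
    ACOUSTIC_FEATURES,
    BIOLOGICAL_FEATURES,
    MinMaxNormalizer,
    PartitionSpec,
    impute_from_train,
)

TASKS = ("regression", "multiclass", "binary")
ALGORITHMS = ("linear", "random_forest", "svm_rbf")

#: positive class of the binary task
POSITIVE = "abnormal"


@dataclass(frozen=True)
class TaskSpec:
    """One prediction task to fit and evaluate."""

    task: str
    algorithm: str
    use_biological: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")

    @property
    def name(self) -> str:
        suffix = "P" if self.use_biological else ""
        number = {"regression": 1, "multiclass": 2, "binary": 3}[self.task]
        return f"model_{number}{suffix}_{self.algorithm}"


@dataclass
class EvaluationReport:
    """Metrics of one fitted task on its held-out test split."""

    task: str
    algorithm: str
    use_biological: bool
    n_train: int
    n_test: int
    cv_scores: list[float] = field(default_factory=list)
    metrics: dict[str, Any] = field(default_factory=dict)
    flagged: bool = False
    notes: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


def make_estimator(task: TaskSpec):
    """Library-default estimator for a task/algorithm pair.

    "linear" means ordinary least squares for regression and (multinomial)
    logistic regression for classification.
    """
    seed = task.seed
    if task.task == "regression":
        return {
            "linear": LinearRegression(),
            "random_forest": RandomForestRegressor(random_state=seed),
            "svm_rbf": SVR(kernel="rbf"),
        }[task.algorithm]
    return {
        "linear": LogisticRegression(max_iter=5000),
        "random_forest": RandomForestClassifier(random_state=seed),
        "svm_rbf": SVC(kernel="rbf"),
    }[task.algorithm]


def fit_model(task: TaskSpec, X: pd.DataFrame, y: np.ndarray):
    """Fit the estimator for ``task`` on normalised features."""
    y = np.asarray(y)
    if len(X) < 2:
        raise ValueError("need at least 2 training rows")
    if task.task != "regression" and len(np.unique(y)) < 2:
        raise ValueError("classification requires at least 2 classes in train")
    est = make_estimator(task)
    est.fit(X, y)
    return est


def class_scores(est, X: pd.DataFrame, positive: str = POSITIVE) -> np.ndarray:
    """Score of the positive class for ROC ranking.

    Probability for estimators exposing it; otherwise the decision function
    oriented so larger means more positive.
    """
    if hasattr(est, "predict_proba"):
        idx = list(est.classes_).index(positive)
        return est.predict_proba(X)[:, idx]
    scores = est.decision_function(X)
    # binary decision_function is the margin of classes_[1]
    if est.classes_[1] != positive:
        scores = -scores
    return scores


def evaluate_regression(predictions: np.ndarray, truth: np.ndarray) -> dict:
    """RMSE and MAE of point predictions."""
    predictions = np.asarray(predictions, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if predictions.size == 0 or predictions.shape != truth.shape:
        raise ValueError("prediction/truth vectors must be equal-length, non-empty")
    err = predictions - truth
    return {
        "rmse": float(np.sqrt(np.mean(err**2))),
        "mae": float(np.mean(np.abs(err))),
    }


def roc_auc(scores: np.ndarray, truth: np.ndarray, positive: str = POSITIVE) -> dict:
    """ROC points and trapezoidal AUC, positive class = ``positive``."""
    truth = np.asarray(truth)
    if len(np.unique(truth)) < 2:
        raise ValueError("ROC requires both classes in the truth vector")
    fpr, tpr, _ = roc_curve(truth, np.asarray(scores, float), pos_label=positive)
    return {
        "roc_fpr": fpr.tolist(),
        "roc_tpr": tpr.tolist(),
        "auc": float(_trapezoid_auc(fpr, tpr)),
    }


def auc_pair_count(
    scores: np.ndarray, truth: np.ndarray, positive: str = POSITIVE
) -> float:
    """AUC as the probability that a random positive outranks a random
    negative, ties counting one half.  O(n_pos * n_neg); used as an
    independent cross-check of the trapezoidal AUC."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    pos = scores[truth == positive]
    neg = scores[truth != positive]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need both classes")
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((wins + 0.5 * ties) / (len(pos) * len(neg)))


def evaluate_classification(
    predictions: np.ndarray,
    truth: np.ndarray,
    labels: list[str],
    scores: np.ndarray | None = None,
    positive: str = POSITIVE,
) -> dict:
    """Accuracy, per-class precision/recall, F1, confusion matrix and — when
    scores are given and the task is binary — sensitivity, specificity and
    ROC/AUC."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.size == 0 or predictions.shape != truth.shape:
        raise ValueError("prediction/truth vectors must be equal-length, non-empty")
    cm = confusion_matrix(truth, predictions, labels=labels)
    prec, rec, f1, support = precision_recall_fscore_support(
        truth, predictions, labels=labels, zero_division=0
    )
    out: dict[str, Any] = {
        "accuracy": float(np.trace(cm) / cm.sum()),
        "confusion_matrix": cm.tolist(),
        "labels": list(labels),
        "per_class_precision": prec.tolist(),
        "per_class_recall": rec.tolist(),
        "per_class_support": support.tolist(),
        "f1_macro": float(np.mean(f1)),
        "f1_weighted": float(np.average(f1, weights=np.maximum(support, 1e-12)))
        if support.sum() > 0
        else 0.0,
    }
    if positive in labels and len(labels) == 2:
        i_pos = labels.index(positive)
        i_neg = 1 - i_pos
        tp, fn = cm[i_pos, i_pos], cm[i_pos, i_neg]
        tn, fp = cm[i_neg, i_neg], cm[i_neg, i_pos]
        out["sensitivity"] = float(tp / (tp + fn)) if tp + fn else float("nan")
        out["specificity"] = float(tn / (tn + fp)) if tn + fp else float("nan")
        if scores is not None and len(np.unique(truth)) == 2:
            out.update(roc_auc(scores, truth, positive))
    return out


def cross_validate_10fold(
    task: TaskSpec, X: pd.DataFrame, y: np.ndarray, n_splits: int = 10
) -> list[float]:
    """Seeded 10-fold CV on the training split.

    Folds are a disjoint cover of the training rows.  The per-fold score is
    RMSE for regression and accuracy for classification.  Folds whose
    training part collapses to one class are scored NaN.
    """
    y = np.asarray(y)
    if len(X) < n_splits:
        raise ValueError(f"need at least {n_splits} training rows")
    kf = KFold(n_splits=n_splits, shuffle=True, random_state=task.seed)
    scores: list[float] = []
    for tr, va in kf.split(X):
        try:
            est = fit_model(task, X.iloc[tr], y[tr])
        except ValueError:
            scores.append(float("nan"))
            continue
        pred = est.predict(X.iloc[va])
        if task.task == "regression":
            scores.append(evaluate_regression(pred, y[va])["rmse"])
        else:
            scores.append(float(np.mean(pred == y[va])))
    return scores


def _target_vector(dataset: pd.DataFrame, task: str) -> np.ndarray:
    return {
        "regression": dataset["fev1_pct"].to_numpy(dtype=float),
        "multiclass": dataset["ats_grade"].to_numpy(),
        "binary": dataset["binary_label"].to_numpy(),
    }[task]


def run_single_task(
    task: TaskSpec,
    dataset: pd.DataFrame,
    partition: PartitionSpec,
    feature_columns: list[str] | None = None,
    run_cv: bool = True,
) -> EvaluationReport:
    """Impute + normalise on train, fit, cross-validate and test one task."""
    if feature_columns is None:
        feature_columns = list(ACOUSTIC_FEATURES)
        if task.use_biological:
            feature_columns = feature_columns + BIOLOGICAL_FEATURES
    train = dataset.loc[list(partition.train_ids)]
    test = dataset.loc[list(partition.test_ids)]

    X_all, _ = impute_from_train(dataset[feature_columns], train.index)
    norm = MinMaxNormalizer().fit(X_all.loc[train.index])
    X_train = norm.transform(X_all.loc[train.index])
    X_test = norm.transform(X_all.loc[test.index])
    y_train = _target_vector(train, task.task)
    y_test = _target_vector(test, task.task)

    report = EvaluationReport(
        task=task.task,
        algorithm=task.algorithm,
        use_biological=task.use_biological,
        n_train=len(train),
        n_test=len(test),
    )
    try:
        est = fit_model(task, X_train, y_train)
    except ValueError as exc:
        report.flagged = True
        report.notes = f"fit failed: {exc}"
        return report
    if run_cv and len(train) >= 10:
        report.cv_scores = cross_validate_10fold(task, X_train, y_train)

    pred = est.predict(X_test)
    if task.task == "regression":
        report.metrics = evaluate_regression(pred, y_test)
    else:
        labels = sorted(set(y_train) | set(y_test))
        missing = set(y_test) - set(y_train)
        if missing:
            report.flagged = True
            report.notes = f"classes absent from train: {sorted(missing)}"
        scores = None
        if task.task == "binary" and len(np.unique(y_test)) == 2:
            scores = class_scores(est, X_test)
        elif task.task == "binary":
            report.flagged = True
            report.notes = "test split lacks a class; ROC skipped"
        report.metrics = evaluate_classification(
            pred, y_test, labels=labels, scores=scores
        )
    return report


def run_task_suite(
    dataset: pd.DataFrame,
    partition: PartitionSpec,
    seed: int = 0,
    run_cv: bool = True,
) -> list[EvaluationReport]:
    """All 18 reports: 3 tasks x 3 algorithms x {acoustic, +biological}."""
    reports = []
    for task_name in TASKS:
        for algo in ALGORITHMS:
            for use_bio in (False, True):
                spec = TaskSpec(
                    task=task_name,
                    algorithm=algo,
                    use_biological=use_bio,
                    seed=seed,
                )
                reports.append(
                    run_single_task(spec, dataset, partition, run_cv=run_cv)
                )
    return reports


def compare_feature_subsets(
    dataset: pd.DataFrame,
    partition: PartitionSpec,
    seed: int = 0,
) -> pd.DataFrame:
    """Regression MAE/RMSE using speech-only, breath-only and combined
    acoustic features, per algorithm."""
    subsets = {
        "speech_only": [c for c in ACOUSTIC_FEATURES if c.startswith("speech_")],
        "breath_only": [
            c
            for c in ACOUSTIC_FEATURES
            if c.startswith("breath_") or c == "mean_breath_cycle_s"
        ],
        "combined": list(ACOUSTIC_FEATURES),
    }
    rows = []
    for name, cols in subsets.items():
        for algo in ALGORITHMS:
            spec = TaskSpec(task="regression", algorithm=algo, seed=seed)
            rep = run_single_task(
                spec, dataset, partition, feature_columns=cols, run_cv=False
            )
            rows.append(
                {
                    "subset": name,
                    "algorithm": algo,
                    "rmse": rep.metrics.get("rmse"),
                    "mae": rep.metrics.get("mae"),
                }
            )
    return pd.DataFrame(rows)


def reports_table(reports: list[EvaluationReport]) -> pd.DataFrame:
    """Flat summary table of a report list."""
    rows = []
    for r in reports:
        row = {
            "task": r.task,
            "algorithm": r.algorithm,
            "use_biological": r.use_biological,
            "n_train": r.n_train,
            "n_test": r.n_test,
            "cv_mean": float(np.nanmean(r.cv_scores)) if r.cv_scores else np.nan,
            "flagged": r.flagged,
        }
        for key in ("rmse", "mae", "accuracy", "f1_weighted", "f1_macro",
                    "sensitivity", "specificity", "auc"):
            if key in r.metrics:
                row[key] = r.metrics[key]
        rows.append(row)
    return pd.DataFrame(rows)
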