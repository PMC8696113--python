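"""Stratified cross-validation, confusion/ROC/UMAP reporting, label regrouping.

The evaluation protocol: samples are split into k stratified folds
(default 5, i.e. 20% of the data per test fold); for each trial, the
remaining k−1 folds are further split, stratified, into a training set
(80% of them, 64% of the whole) and a validation set (20% of them, 16% of
the whole) used only for early stopping.  One network is trained per
fold, metrics are pooled/averaged over folds, and the test fold is never
seen by its network during training, validation or normalization.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as skmetrics
from sklearn.model_selection import StratifiedKFold, train_test_split

from .model import ResNetTrajectoryClassifier

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------------
# Label schemes


@dataclass(frozen=True)
class LabelScheme:
    """Bidirectional map between fine labels and coarse groups."""

    mapping: Mapping[str, str]  # fine -> coarse

    def __post_init__(self) -> None:
        if not self.mapping:
            raise ValueError("empty label scheme")

    @property
    def fine_labels(self) -> list[str]:
        return sorted(self.mapping)

    @property
    def coarse_labels(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    def coarse(self, fine: str) -> str:
        try:
            return self.mapping[fine]
        except KeyError:
            raise KeyError(f"label {fine!r} not in scheme (knows {self.fine_labels})")

    def fines_of(self, coarse: str) -> list[str]:
        return sorted(f for f, c in self.mapping.items() if c == coarse)


#: Breast-cancer cell lines -> clinical receptor status: hormone-receptor
#: positive (HR+), HER2 positive (HER2+) and triple negative (TN).
RECEPTOR_STATUS_SCHEME = LabelScheme(
    mapping={
        "MCF7": "HR+",
        "BT474": "HER2+",
        "SKBR3": "HER2+",
        "MDA-MB-468": "TN",
        "MDA-MB-231": "TN",
        "BT549": "TN",
    }
)


def regroup_labels(labels: Sequence[str], scheme: LabelScheme) -> np.ndarray:
    """Replace fine labels by their coarse group; counts are conserved."""
    return np.array([scheme.coarse(l) for l in labels])


# ----------------------------------------------------------------------------
# Fold planning


@dataclass
class FoldTrial:
    """Index sets of one cross-validation trial (64/16/20 of the data)."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray


@dataclass
class FoldPlan:
    """Stratified k-fold assignment with inner train/validation splits."""

    k: int
    assignments: np.ndarray  # per-sample test-fold index
    trials: list[FoldTrial]
    seed: int


class StratificationError(ValueError):
    pass


def make_fold_plan(labels: Sequence[str], k: int = 5, seed: int = 0,
                   val_fraction: float = 0.2) -> FoldPlan:
    """Stratified k-fold plan with stratified inner 80/20 train/val splits.

    With class counts divisible by 25 and k = 5 the fractions are exactly
    64% train / 16% validation / 20% test per trial; otherwise they hold
    up to ±1 sample per class per split.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    too_small = classes[counts < k]
    if len(too_small):
        raise StratificationError(
            f"classes with fewer than k={k} samples: {list(map(str, too_small))}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = np.empty(len(labels), dtype=np.int64)
    trials = []
    for fold, (rest_idx, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignments[test_idx] = fold
        train_idx, val_idx = train_test_split(
            rest_idx,
            test_size=val_fraction,
            stratify=labels[rest_idx],
            random_state=seed + fold,
        )
        trials.append(
            FoldTrial(train_idx=np.sort(train_idx), val_idx=np.sort(val_idx),
                      test_idx=np.sort(test_idx))
        )
    return FoldPlan(k=k, assignments=assignments, trials=trials, seed=seed)


# ----------------------------------------------------------------------------
# Metrics


def confusion_matrix(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    labels: Sequence[str] | None = None,
    pred_labels: Sequence[str] | None = None,
    normalize: str | None = None,
) -> pd.DataFrame:
    """Confusion matrix with true labels as rows, predictions as columns.

    ``normalize="true-rows"`` divides each row by its support (rows with
    zero support are left as zeros and flagged in the log).  Row and
    column label sets may differ (e.g. scoring classes unseen at
    training time), in which case ``labels`` / ``pred_labels`` name them.
    """
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences differ in length")
    row_labels = list(labels) if labels is not None else sorted(
        set(true_labels) | set(predicted_labels))
    col_labels = list(pred_labels) if pred_labels is not None else row_labels
    unknown = set(true_labels) - set(row_labels)
    unknown |= set(predicted_labels) - set(col_labels)
    if unknown:
        raise ValueError(f"labels outside the declared label set: {sorted(unknown)}")
    if row_labels == col_labels:
        mat = skmetrics.confusion_matrix(true_labels, predicted_labels,
                                         labels=row_labels).astype(float)
    else:
        mat = np.zeros((len(row_labels), len(col_labels)))
        ri = {l: i for i, l in enumerate(row_labels)}
        ci = {l: i for i, l in enumerate(col_labels)}
        for t, p in zip(true_labels, predicted_labels):
            mat[ri[t], ci[p]] += 1
    if normalize == "true-rows":
        support = mat.sum(axis=1, keepdims=True)
        empty = np.flatnonzero(support[:, 0] == 0)
        if len(empty):
            logger.warning("zero-support rows in confusion matrix: %s",
                           [row_labels[i] for i in empty])
        mat = np.divide(mat, support, out=np.zeros_like(mat), where=support > 0)
    elif normalize is not None:
        raise ValueError(f"unknown normalize mode {normalize!r}")
    return pd.DataFrame(mat, index=row_labels, columns=col_labels)


@dataclass
class ROCResult:
    """One-vs-rest ROC curve and AUC for a single class."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float | None  # None when undefined (no positives or no negatives)


def roc_auc(
    probabilities: np.ndarray,
    true_labels: Sequence[str],
    classes: Sequence[str],
) -> dict[str, ROCResult]:
    """One-vs-rest ROC curves by threshold sweep; AUC by trapezoidal rule.

    A class with zero positives or zero negatives gets ``auc=None``.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    true_labels = np.asarray(true_labels)
    if probabilities.shape != (len(true_labels), len(classes)):
        raise ValueError("probabilities must be (n_samples, n_classes)")
    if not np.allclose(probabilities.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    out: dict[str, ROCResult] = {}
    for j, cls in enumerate(classes):
        pos = true_labels == cls
        if pos.all() or not pos.any():
            out[cls] = ROCResult(fpr=np.array([]), tpr=np.array([]), auc=None)
            continue
        fpr, tpr, _ = skmetrics.roc_curve(pos.astype(int), probabilities[:, j])
        out[cls] = ROCResult(fpr=fpr, tpr=tpr, auc=float(np.trapezoid(tpr, fpr)))
    return out


def umap_project(
    features: np.ndarray,
    labels: Sequence[str] | None = None,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> np.ndarray:
    """Deterministic (seeded) 2D UMAP embedding of feature vectors."""
    features = np.asarray(features, dtype=float)
    if len(features) < 10:
        raise ValueError("need at least 10 samples for a UMAP projection")
    if len(features) <= n_neighbors:
        raise ValueError(
            f"n_neighbors={n_neighbors} must be < n_samples={len(features)}; "
            "lower n_neighbors for small datasets"
        )
    import umap  # deferred: numba compilation is slow to import

    reducer = umap.UMAP(
        n_components=2, n_neighbors=n_neighbors, min_dist=min_dist,
        random_state=seed,
    )
    coords = reducer.fit_transform(features)
    if not np.all(np.isfinite(coords)):
        raise RuntimeError("UMAP produced non-finite coordinates")
    return np.asarray(coords)


# ----------------------------------------------------------------------------
# Reports


@dataclass
class EvaluationReport:
    """Cross-validation (or held-out) evaluation results.

    Confusion matrices are pooled over raw per-fold counts and then
    normalized; per-fold matrices are retained.  ``embedding`` holds 2D
    UMAP coordinates of penultimate-layer features when computed.
    """

    classes: list[str]
    true_labels: np.ndarray
    predicted_labels: np.ndarray
    probabilities: np.ndarray
    fold_of_sample: np.ndarray | None = None
    per_fold_confusion: list[pd.DataFrame] = field(default_factory=list)
    features: np.ndarray | None = None
    embedding: np.ndarray | None = None
    config: dict = field(default_factory=dict)
    row_classes: list[str] | None = None  # true-label set when != trained classes

    @property
    def confusion_raw(self) -> pd.DataFrame:
        return confusion_matrix(
            self.true_labels, self.predicted_labels,
            labels=self.row_classes or self.classes, pred_labels=self.classes,
        )

    @property
    def confusion_normalized(self) -> pd.DataFrame:
        return confusion_matrix(
            self.true_labels, self.predicted_labels,
            labels=self.row_classes or self.classes, pred_labels=self.classes,
            normalize="true-rows",
        )

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.true_labels == self.predicted_labels))

    @property
    def per_fold_accuracy(self) -> list[float]:
        if self.fold_of_sample is None:
            return [self.accuracy]
        return [
            float(np.mean(
                self.true_labels[self.fold_of_sample == f]
                == self.predicted_labels[self.fold_of_sample == f]
            ))
            for f in np.unique(self.fold_of_sample)
        ]

    def roc(self) -> dict[str, ROCResult]:
        return roc_auc(self.probabilities, self.true_labels, self.classes)

    def auc_table(self) -> pd.Series:
        return pd.Series({c: r.auc for c, r in self.roc().items()}, name="auc")

    def classification_fractions(self) -> pd.Series:
        """Fraction of samples predicted as each trained class."""
        pred = pd.Categorical(self.predicted_labels, categories=self.classes)
        return pred.value_counts().reindex(self.classes) / len(self.predicted_labels)

    def to_dict(self) -> dict:
        d = {
            "classes": self.classes,
            "accuracy": self.accuracy,
            "per_fold_accuracy": self.per_fold_accuracy,
            "confusion_raw": self.confusion_raw.to_dict(),
            "confusion_normalized": self.confusion_normalized.to_dict(),
            "auc": {c: r.auc for c, r in self.roc().items()},
            "config": self.config,
        }
        return d

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    def save_tables(self, out_dir: str | Path, prefix: str = "report") -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []
        for name, df in [
            ("confusion_raw", self.confusion_raw),
            ("confusion_normalized", self.confusion_normalized),
        ]:
            p = out_dir / f"{prefix}_{name}.csv"
            df.to_csv(p)
            written.append(p)
        p = out_dir / f"{prefix}_predictions.csv"
        pd.DataFrame(
            {
                "true": self.true_labels,
                "predicted": self.predicted_labels,
                **{f"p_{c}": self.probabilities[:, j] for j, c in enumerate(self.classes)},
            }
        ).to_csv(p, index=False)
        written.append(p)
        return written


def percent_change(before: float, after: float) -> float:
    """Relative change in percent: 0.19 -> 0.46 is +142%."""
    if before == 0:
        raise ZeroDivisionError("baseline fraction is zero")
    return (after - before) / before * 100.0


def compare_classification_fractions(
    report_before: EvaluationReport, report_after: EvaluationReport
) -> pd.DataFrame:
    """Per-class predicted-fraction deltas between two datasets, in percent."""
    before = report_before.classification_fractions()
    after = report_after.classification_fractions()
    rows = {}
    for cls in report_before.classes:
        b, a = float(before[cls]), float(after[cls])
        rows[cls] = {
            "fraction_before": b,
            "fraction_after": a,
            "percent_change": percent_change(b, a) if b > 0 else np.nan,
        }
    return pd.DataFrame(rows).T


# ----------------------------------------------------------------------------
# Orchestration


def cross_validate(
    X,
    labels: Sequence[str],
    estimator_factory: Callable[[int], ResNetTrajectoryClassifier] | None = None,
    fold_plan: FoldPlan | None = None,
    k: int = 5,
    seed: int = 0,
    compute_features: bool = True,
    compute_embedding: bool = False,
    umap_seed: int = 0,
    **estimator_params,
) -> EvaluationReport:
    """Stratified k-fold cross-validation of the trajectory classifier.

    One fresh network per fold is trained on that trial's 64% train split
    (normalization statistics included), early-stopped on the 16%
    validation split, and scored on the untouched 20% test fold.  Results
    are pooled over folds.

    ``estimator_factory(fold)`` may supply a configured estimator per
    fold; by default ``ResNetTrajectoryClassifier(seed=seed + fold,
    **estimator_params)`` is used.
    """
    from .model import as_position_array

    X = as_position_array(X)
    labels = np.asarray(labels)
    if fold_plan is None:
        fold_plan = make_fold_plan(labels, k=k, seed=seed)
    classes = sorted(np.unique(labels))
    n = len(labels)
    predicted = np.empty(n, dtype=labels.dtype)
    probabilities = np.zeros((n, len(classes)))
    features = None
    per_fold_conf = []

    for fold, trial in enumerate(fold_plan.trials):
        if estimator_factory is not None:
            est = estimator_factory(fold)
        else:
            est = ResNetTrajectoryClassifier(seed=seed + fold, **estimator_params)
        est.fit(
            X[trial.train_idx], labels[trial.train_idx],
            X_val=X[trial.val_idx], y_val=labels[trial.val_idx],
        )
        proba = est.predict_proba(X[trial.test_idx])
        # align the estimator's class order onto the global one
        col = {c: j for j, c in enumerate(est.classes_)}
        for j, c in enumerate(classes):
            if c in col:
                probabilities[trial.test_idx, j] = proba[:, col[c]]
        pred = est.classes_[np.argmax(proba, axis=1)]
        predicted[trial.test_idx] = pred
        per_fold_conf.append(
            confusion_matrix(labels[trial.test_idx], pred, labels=classes)
        )
        if compute_features:
            feats = est.extract_features(X[trial.test_idx])
            if features is None:
                features = np.zeros((n, feats.shape[1]))
            features[trial.test_idx] = feats
        logger.info("fold %d/%d: test accuracy %.3f", fold + 1, fold_plan.k,
                    float(np.mean(pred == labels[trial.test_idx])))

    report = EvaluationReport(
        classes=list(classes),
        true_labels=labels,
        predicted_labels=predicted,
        probabilities=probabilities,
        fold_of_sample=fold_plan.assignments,
        per_fold_confusion=per_fold_conf,
        features=features,
        config={"k": fold_plan.k, "seed": seed, **estimator_params},
    )
    if compute_embedding and features is not None:
        report.embedding = umap_project(
            features, labels, seed=umap_seed,
            n_neighbors=min(15, len(features) - 1),
        )
    return report


def evaluate_pretrained(
    model: ResNetTrajectoryClassifier,
    X,
    labels: Sequence[str],
    scheme: LabelScheme | None = None,
) -> EvaluationReport:
    """Score a trained model on a new dataset.

    If ``scheme`` is given, true labels are regrouped to coarse groups
    before scoring (predictions stay in the model's trained classes).
    Labels unseen at training time are allowed: they contribute confusion
    rows but no prediction column.
    """
    labels = np.asarray(labels)
    true = regroup_labels(labels, scheme) if scheme is not None else labels
    proba = model.predict_proba(X)
    pred = model.classes_[np.argmax(proba, axis=1)]
    classes = [str(c) for c in model.classes_]
    row_classes = sorted(set(map(str, true)) | set(classes))
    return EvaluationReport(
        classes=classes,
        true_labels=true.astype(str),
        predicted_labels=pred.astype(str),
        probabilities=proba,
        row_classes=row_classes if row_classes != classes else None,
        config={"pretrained": True},
    )


# ----------------------------------------------------------------------------
# Plots


def plot_confusion(report: EvaluationReport, path: str | Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cm = report.confusion_normalized
    fig, ax = plt.subplots(figsize=(5.5, 5))
    im = ax.imshow(cm.to_numpy(), vmin=0, vmax=1, cmap="Blues")
    ax.set_xticks(range(len(cm.columns)), cm.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(cm.index)), cm.index)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    for i in range(cm.shape[0]):
        for j in range(cm.shape[1]):
            v = cm.iat[i, j]
            ax.text(j, i, f"{v:.2f}", ha="center", va="center",
                    color="white" if v > 0.5 else "black", fontsize=8)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_roc(report: EvaluationReport, path: str | Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.5, 5))
    for cls, r in report.roc().items():
        if r.auc is None:
            continue
        ax.plot(r.fpr, r.tpr, label=f"{cls} (AUC {r.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_embedding(report: EvaluationReport, path: str | Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if report.embedding is None:
        raise ValueError("report has no embedding; run with compute_embedding=True")
    fig, ax = plt.subplots(figsize=(5.5, 5))
    for cls in report.classes:
        m = report.true_labels == cls
        ax.scatter(report.embedding[m, 0], report.embedding[m, 1], s=6, label=cls)
    ax.set_xlabel("UMAP 1")
    ax.set_ylabel("UMAP 2")
    ax.legend(fontsize=8, markerscale=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
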