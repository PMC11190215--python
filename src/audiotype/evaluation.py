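"""Evaluation protocol: stratified K-fold CV, metrics, ROC-AUC, McNemar.

Class imbalance makes plain K-fold splits unreliable (a fold can lose most
of a rare class), so folds are stratified: within each class, indices are
shuffled once (seeded) and dealt round-robin, which bounds per-class fold
counts to differ by at most one.

From a K×K confusion matrix (rows = true class, columns = predicted, fixed
order normal/conductive/mixed/sensorineural) the one-vs-rest TP/TN/FP/FN of
each class yield

    accuracy  = (TP+TN) / (TP+TN+FP+FN)
    precision = TP / (TP+FP)
    recall    = TP / (TP+FN)
    F1        = 2·precision·recall / (precision+recall)

with the convention F1 = 0 (and precision/recall = 0) on an empty
denominator.  Aggregates are support-weighted by default (macro available),
and overall accuracy is trace/total.  Cross-validation summaries report the
arithmetic mean and population (ddof=0) standard deviation over folds.

Multiclass ROC-AUC uses the micro-averaged one-vs-rest construction: the K
binary (indicator, score) problems are pooled into one and AUC is the
normalised Mann–Whitney rank statistic (ties count ½), identical to
trapezoidal integration of the pooled ROC curve.

Two classifiers on the same samples are compared with McNemar's test on the
discordant-pair counts n01/n10, χ² = (|n01−n10|−1)²/(n01+n10) with
continuity correction by default (toggleable), p from the χ²(1 df) tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2 as _chi2
from scipy.stats import rankdata as _rankdata

from .core import CLINICAL_LABELS, AudiogramSet, HearingLossLabel
from .models import (
    ModelConfig,
    TreeConfig,
    audiograms_to_flat_features,
    labels_to_indices,
    train_sequence_model,
    train_tree_baseline,
)
from .preprocessing import (
    apply_normalizer,
    compute_class_weights,
    encode_set,
    fit_normalizer,
    sequences_to_array,
)

__all__ = [
    "StratifiedFolds",
    "ConfusionMatrix",
    "MetricsReport",
    "CVReport",
    "McNemarResult",
    "stratified_folds",
    "confusion",
    "metrics_from_confusion",
    "aggregate_cv",
    "binary_auc",
    "roc_auc_micro_ovr",
    "mcnemar",
    "run_cv_experiment",
]


# ---------------------------------------------------------------------------
# Stratified folds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StratifiedFolds:
    k: int
    folds: tuple[tuple[int, ...], ...]
    seed: int

    def split(self):
        """Yield (train_indices, test_indices) per fold."""
        all_idx = set(i for fold in self.folds for i in fold)
        for fold in self.folds:
            test = np.array(fold, dtype=int)
            train = np.array(sorted(all_idx - set(fold)), dtype=int)
            yield train, test


def stratified_folds(labels, k: int = 10, seed: int = 0) -> StratifiedFolds:
    """Partition indices into *k* folds preserving class proportions.

    Within each class the indices are shuffled (seeded) and dealt
    round-robin, so per-class counts across folds differ by at most one.
    Raises if any class has fewer than *k* members.
    """
    labels = list(labels)
    rng = np.random.default_rng(seed)
    y = np.array([str(lab) for lab in labels])
    buckets: list[list[int]] = [[] for _ in range(k)]
    for c in sorted(set(y)):
        idx = np.flatnonzero(y == c)
        if len(idx) < k:
            raise ValueError(f"class {c!r} has {len(idx)} samples, fewer than k={k}")
        idx = idx[rng.permutation(len(idx))]
        for pos, i in enumerate(idx):
            buckets[pos % k].append(int(i))
    return StratifiedFolds(k=k, folds=tuple(tuple(sorted(b)) for b in buckets), seed=seed)


# ---------------------------------------------------------------------------
# Confusion matrix and metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    """4×4 counts; rows = true, columns = predicted, order (N, C, M, S)."""

    counts: np.ndarray
    classes: tuple[HearingLossLabel, ...] = CLINICAL_LABELS

    def __post_init__(self) -> None:
        k = len(self.classes)
        if self.counts.shape != (k, k) or (self.counts < 0).any():
            raise ValueError("confusion counts must be a nonnegative K×K matrix")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts, self.classes)


def confusion(true_labels, predicted_labels) -> ConfusionMatrix:
    """Count (true, predicted) pairs over the four clinical classes."""
    yt = labels_to_indices(true_labels)
    yp = labels_to_indices(predicted_labels)
    if len(yt) != len(yp):
        raise ValueError(f"length mismatch: {len(yt)} true vs {len(yp)} predicted")
    k = len(CLINICAL_LABELS)
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (yt, yp), 1)
    return ConfusionMatrix(counts)


@dataclass(frozen=True)
class ClassMetrics:
    tp: int
    tn: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float


@dataclass(frozen=True)
class MetricsReport:
    per_class: dict[HearingLossLabel, ClassMetrics]
    accuracy: float
    precision: float
    recall: float
    f1: float
    averaging: str = "weighted"

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "averaging": self.averaging,
            "per_class": {
                str(c): {"tp": m.tp, "tn": m.tn, "fp": m.fp, "fn": m.fn,
                         "precision": m.precision, "recall": m.recall, "f1": m.f1}
                for c, m in self.per_class.items()
            },
        }


def _safe_div(a: float, b: float) -> float:
    return a / b if b > 0 else 0.0


def metrics_from_confusion(cm: ConfusionMatrix, averaging: str = "weighted") -> MetricsReport:
    """One-vs-rest per-class metrics plus overall accuracy and aggregates.

    ``averaging`` is ``"weighted"`` (support-weighted, default) or
    ``"macro"``.
    """
    counts = cm.counts.astype(float)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    per_class: dict[HearingLossLabel, ClassMetrics] = {}
    supports, precisions, recalls, f1s = [], [], [], []
    for i, c in enumerate(cm.classes):
        tp = counts[i, i]
        fn = counts[i, :].sum() - tp
        fp = counts[:, i].sum() - tp
        tn = total - tp - fn - fp
        prec = _safe_div(tp, tp + fp)
        rec = _safe_div(tp, tp + fn)
        f1 = _safe_div(2 * prec * rec, prec + rec)
        per_class[c] = ClassMetrics(int(tp), int(tn), int(fp), int(fn), prec, rec, f1)
        supports.append(tp + fn)
        precisions.append(prec)
        recalls.append(rec)
        f1s.append(f1)
    if averaging == "weighted":
        w = np.array(supports) / total
    elif averaging == "macro":
        w = np.full(len(supports), 1.0 / len(supports))
    else:
        raise ValueError(f"averaging must be weighted|macro, got {averaging!r}")
    return MetricsReport(
        per_class=per_class,
        accuracy=float(np.trace(counts) / total),
        precision=float(w @ np.array(precisions)),
        recall=float(w @ np.array(recalls)),
        f1=float(w @ np.array(f1s)),
        averaging=averaging,
    )


@dataclass(frozen=True)
class CVReport:
    """Per-fold metric reports with mean ± population sd summaries."""

    fold_reports: tuple[MetricsReport, ...]
    mean: dict[str, float]
    sd: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "folds": [r.to_dict() for r in self.fold_reports],
            "mean": dict(self.mean),
            "sd": dict(self.sd),
        }


def aggregate_cv(fold_reports) -> CVReport:
    """Arithmetic mean and population (ddof=0) sd of each aggregate metric."""
    fold_reports = tuple(fold_reports)
    if len(fold_reports) < 2:
        raise ValueError("need at least 2 folds to aggregate")
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    for name in ("accuracy", "precision", "recall", "f1"):
        vals = np.array([getattr(r, name) for r in fold_reports])
        mean[name] = float(vals.mean())
        sd[name] = float(vals.std(ddof=0))
    return CVReport(fold_reports=fold_reports, mean=mean, sd=sd)


# ---------------------------------------------------------------------------
# ROC-AUC (micro-averaged one-vs-rest)
# ---------------------------------------------------------------------------

def binary_auc(indicator, scores) -> float:
    """AUC of one binary problem via the Mann–Whitney rank statistic.

    Equals the probability that a random positive outscores a random
    negative, ties counting ½ — identical to trapezoidal ROC integration.
    """
    pos = np.asarray(indicator, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(pos.sum())
    n_neg = pos.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both positive and negative samples")
    ranks = _rankdata(scores)  # average ranks for ties
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_auc_micro_ovr(true_labels, probabilities) -> float:
    """Micro-averaged one-vs-rest multiclass AUC.

    The K one-vs-rest binary problems are flattened into one pooled set of
    (indicator, score) pairs and AUC is computed as the Mann–Whitney rank
    statistic with ties contributing ½.  Raises on a single-class truth
    vector (AUC undefined).
    """
    y = labels_to_indices(true_labels)
    proba = np.asarray(probabilities, dtype=float)
    if proba.ndim != 2 or proba.shape[0] != len(y):
        raise ValueError("probabilities must be (n_samples, n_classes)")
    k = proba.shape[1]
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined for a single-class truth vector")
    indicator = np.zeros((len(y), k), dtype=bool)
    indicator[np.arange(len(y)), y] = True
    return binary_auc(indicator.ravel(), proba.ravel())


# ---------------------------------------------------------------------------
# McNemar's paired test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class McNemarResult:
    n00: int  # misclassified by both A and B
    n01: int  # misclassified by A only
    n10: int  # misclassified by B only
    n11: int  # classified correctly by both
    statistic: float
    p_value: float
    continuity_correction: bool
    no_discordant_pairs: bool = False

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha

    def to_dict(self) -> dict:
        return {
            "n00": self.n00, "n01": self.n01, "n10": self.n10, "n11": self.n11,
            "statistic": self.statistic, "p_value": self.p_value,
            "continuity_correction": self.continuity_correction,
            "no_discordant_pairs": self.no_discordant_pairs,
        }


def mcnemar(truth, preds_a, preds_b, continuity_correction: bool = True) -> McNemarResult:
    """McNemar's test on the discordant misclassifications of two classifiers.

    n00 counts samples misclassified by both A and B, n01 by A only, n10 by
    B only, n11 by neither.  With no discordant pairs the statistic is 0 and
    p = 1 (flagged, not an error).
    """
    truth, preds_a, preds_b = list(truth), list(preds_a), list(preds_b)
    if not (len(truth) == len(preds_a) == len(preds_b)):
        raise ValueError("truth, preds_a, preds_b must have equal lengths")
    ok_a = np.array([p == t for p, t in zip(preds_a, truth)])
    ok_b = np.array([p == t for p, t in zip(preds_b, truth)])
    n00 = int((~ok_a & ~ok_b).sum())
    n01 = int((~ok_a & ok_b).sum())
    n10 = int((ok_a & ~ok_b).sum())
    n11 = int((ok_a & ok_b).sum())
    if n01 + n10 == 0:
        return McNemarResult(n00, n01, n10, n11, 0.0, 1.0,
                             continuity_correction, no_discordant_pairs=True)
    diff = abs(n01 - n10)
    if continuity_correction:
        stat = (diff - 1) ** 2 / (n01 + n10)
    else:
        stat = diff ** 2 / (n01 + n10)
    p = float(_chi2.sf(stat, df=1))
    return McNemarResult(n00, n01, n10, n11, float(stat), p, continuity_correction)


# ---------------------------------------------------------------------------
# Cross-validated experiment
# ---------------------------------------------------------------------------

@dataclass
class ExperimentResult:
    cv_report: CVReport
    pooled_confusion: ConfusionMatrix
    auc: float
    predictions: list[HearingLossLabel]  # pooled out-of-fold predictions
    probabilities: np.ndarray  # pooled out-of-fold probabilities
    order: np.ndarray  # original index of each pooled prediction

    def to_dict(self) -> dict:
        return {
            "cv": self.cv_report.to_dict(),
            "pooled_confusion": self.pooled_confusion.counts.tolist(),
            "class_order": [str(c) for c in CLINICAL_LABELS],
            "auc_micro_ovr": self.auc,
        }


def run_cv_experiment(
    data: AudiogramSet,
    model_cfg: ModelConfig | TreeConfig,
    normalization: str = "zscore",
    k: int = 10,
    seed: int = 0,
    averaging: str = "weighted",
) -> ExperimentResult:
    """Stratified K-fold evaluation of one model configuration.

    Per fold: fit the normaliser and class weights on the training split
    only, train, and evaluate on the held-out fold.  Confusion counts and
    probabilities are pooled over all folds for single-matrix reporting;
    the per-fold metric reports are aggregated to mean ± sd.  Reproducible
    from *seed*.
    """
    if data.labels is None:
        raise ValueError("run_cv_experiment requires a labelled AudiogramSet")
    labels = data.labels
    folds = stratified_folds(labels, k=k, seed=seed)
    is_tree = isinstance(model_cfg, TreeConfig)
    seqs = None if is_tree else encode_set(data.records)
    flat = audiograms_to_flat_features(data.records) if is_tree else None

    fold_reports = []
    pooled_cm = None
    pooled_proba = []
    pooled_preds: list[HearingLossLabel] = []
    pooled_order: list[int] = []
    for fold_i, (train_idx, test_idx) in enumerate(folds.split()):
        y_train = [labels[i] for i in train_idx]
        y_test = [labels[i] for i in test_idx]
        if is_tree:
            model = train_tree_baseline(flat[train_idx], y_train, model_cfg)
            proba = model.predict_proba(flat[test_idx])
            preds = model.predict_label(flat[test_idx])
        else:
            norm = fit_normalizer([seqs[i] for i in train_idx], method=normalization)
            X_train = sequences_to_array([apply_normalizer(norm, seqs[i]) for i in train_idx])
            X_test = sequences_to_array([apply_normalizer(norm, seqs[i]) for i in test_idx])
            weights = compute_class_weights(y_train)
            fold_cfg = ModelConfig(**{**model_cfg.__dict__, "seed": model_cfg.seed + fold_i})
            model = train_sequence_model(X_train, y_train, weights, fold_cfg)
            proba = model.predict_proba(X_test)
            preds = model.predict_label(X_test)
        cm = confusion(y_test, preds)
        fold_reports.append(metrics_from_confusion(cm, averaging=averaging))
        pooled_cm = cm if pooled_cm is None else pooled_cm + cm
        pooled_proba.append(proba)
        pooled_preds.extend(preds)
        pooled_order.extend(int(i) for i in test_idx)

    pooled_proba_arr = np.vstack(pooled_proba)
    pooled_truth = [labels[i] for i in pooled_order]
    auc = roc_auc_micro_ovr(pooled_truth, pooled_proba_arr)
    return ExperimentResult(
        cv_report=aggregate_cv(fold_reports),
        pooled_confusion=pooled_cm,
        auc=auc,
        predictions=pooled_preds,
        probabilities=pooled_proba_arr,
        order=np.array(pooled_order, dtype=int),
    )
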