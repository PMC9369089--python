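"""Confusion-matrix metrics, ROC/PR curves, cross-validation and
imbalanced-ratio dataset construction.

The metric set follows the 6mA benchmarking convention: accuracy,
sensitivity, specificity, Matthews correlation coefficient, ROC AUC, and —
because cross-species test sets are deliberately imbalanced — the area
under the precision–recall curve, whose no-skill baseline equals the
positive fraction of the evaluated set (0.15 for a 15%-positive set).

Cross-validation refits the feature selector inside every fold on that
fold's training rows only, so no held-out row ever influences feature
selection or network training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_curve
from sklearn.model_selection import StratifiedKFold

from .sequence_io import LabeledDataset
from .encoders import encode_dataset
from .feature_selector import SelectorModel, apply_selector, fit_selector
from .classifier import (
    NetworkConfig,
    TrainConfig,
    TrainedModel,
    build_network,
    classify,
    predict_proba,
    train,
)

logger = logging.getLogger("sixmanet")


# ---------------------------------------------------------------------------
# confusion counts and scalar metrics

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    acc: float
    sn: float
    sp: float
    mcc: float
    auc: float | None = None
    auprc: float | None = None
    baseline_auprc: float | None = None
    counts: ConfusionCounts | None = None

    def as_dict(self) -> dict:
        d = {"acc": self.acc, "sn": self.sn, "sp": self.sp, "mcc": self.mcc}
        for k in ("auc", "auprc", "baseline_auprc"):
            v = getattr(self, k)
            if v is not None:
                d[k] = v
        if self.counts is not None:
            d.update(tp=self.counts.tp, tn=self.counts.tn,
                     fp=self.counts.fp, fn=self.counts.fn)
        return d


def confusion(y_true: np.ndarray, y_call: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_call = np.asarray(y_call).astype(int)
    if y_true.shape != y_call.shape:
        raise ValueError("label/call length mismatch")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_call == 1))),
        tn=int(np.sum((y_true == 0) & (y_call == 0))),
        fp=int(np.sum((y_true == 0) & (y_call == 1))),
        fn=int(np.sum((y_true == 1) & (y_call == 0))),
    )


def metrics(c: ConfusionCounts) -> MetricsReport:
    """Acc, Sn, Sp and MCC from raw counts.

    Sn/Sp with an empty class and MCC with a zero denominator are defined
    as 0 (the conventional completion of the undefined ratio).
    """
    if c.total == 0:
        raise ValueError("no samples evaluated")
    tp, tn, fp, fn = (float(v) for v in (c.tp, c.tn, c.fp, c.fn))
    acc = (tp + tn) / c.total
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return MetricsReport(acc=acc, sn=sn, sp=sp, mcc=float(mcc), counts=c)


# ---------------------------------------------------------------------------
# threshold-free metrics

def roc_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Trapezoidal area under the ROC curve.

    Equals the Mann–Whitney probability that a random positive outscores a
    random negative, counting ties as 1/2.
    """
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    fpr, tpr, _ = roc_curve(y_true, scores)
    return float(np.trapezoid(tpr, fpr))


@dataclass
class PRCurve:
    recall: np.ndarray  # non-decreasing
    precision: np.ndarray
    area: float  # AUPRC, average-precision convention


def pr_curve(y_true: np.ndarray, scores: np.ndarray) -> PRCurve:
    """Step-wise precision–recall curve.

    The area uses the average-precision convention — the sum of precision
    at each threshold weighted by the recall increment — which avoids the
    optimism of linear interpolation between PR points.
    """
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    precision, recall, _ = precision_recall_curve(y_true, scores)
    # sklearn returns recall in decreasing order; flip to non-decreasing
    area = float(average_precision_score(y_true, scores))
    return PRCurve(recall=recall[::-1], precision=precision[::-1], area=area)


def baseline_auprc(labels) -> float:
    """No-skill AUPRC baseline = positive fraction of the set."""
    if isinstance(labels, LabeledDataset):
        n_pos, n = labels.positive_count, len(labels)
    else:
        labels = np.asarray(labels).astype(int)
        n_pos, n = int(labels.sum()), labels.size
    if n == 0:
        raise ValueError("empty label set")
    return n_pos / n


def score_metrics(y_true: np.ndarray, scores: np.ndarray,
                  threshold: float = 0.5) -> MetricsReport:
    """Full report: thresholded confusion metrics plus AUC and AUPRC."""
    calls = classify(np.asarray(scores, dtype=float), threshold)
    report = metrics(confusion(y_true, calls))
    report.auc = roc_auc(y_true, scores)
    report.auprc = pr_curve(y_true, scores).area
    report.baseline_auprc = baseline_auprc(y_true)
    return report


# ---------------------------------------------------------------------------
# imbalanced-ratio construction

def subsample_ratio(dataset: LabeledDataset, ratio: int,
                    seed: int = 0) -> LabeledDataset:
    """Build a 1:ratio (positive:negative) dataset.

    All negatives are kept; floor(n_neg / ratio) positives are drawn
    uniformly without replacement (seeded).  This is the construction that
    reproduces the benchmark ratio counts, e.g. 1966 negatives at 1:10 ->
    floor(1966/10) = 196 positives.
    """
    if ratio < 1 or int(ratio) != ratio:
        raise ValueError("ratio must be an integer >= 1")
    labels = np.asarray(dataset.labels)
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    n_keep = neg_idx.size // int(ratio)
    if n_keep == 0:
        raise ValueError(
            f"ratio {ratio} leaves zero positives ({neg_idx.size} negatives)"
        )
    if n_keep > pos_idx.size:
        raise ValueError(
            f"need {n_keep} positives for 1:{ratio} but only {pos_idx.size} present"
        )
    rng = np.random.default_rng(seed)
    kept_pos = np.sort(rng.choice(pos_idx, size=n_keep, replace=False))
    order = np.concatenate([kept_pos, neg_idx])
    return LabeledDataset(
        sequences=[dataset.sequences[i] for i in order],
        labels=[int(labels[i]) for i in order],
        name=f"{dataset.name}_1to{int(ratio)}",
    )


# ---------------------------------------------------------------------------
# pipeline fitting and evaluation

def train_pipeline(
    dataset: LabeledDataset,
    l1: float | None = None,
    l2: float | None = None,
    net_config: NetworkConfig | None = None,
    train_config: TrainConfig | None = None,
) -> TrainedModel:
    """Encode -> fit selector -> train the CNN on one labeled dataset."""
    X, y = encode_dataset(dataset)
    selector = fit_selector(X, y, l1=l1, l2=l2)
    if selector.n_selected == 0:
        raise ValueError(
            "feature selection retained zero features; lower the penalties"
        )
    X_red = apply_selector(selector, X)
    cfg = train_config or TrainConfig()
    net = build_network(X_red.shape[1], net_config, seed=cfg.seed)
    return train(net, X_red, y, cfg, selector=selector)


def evaluate_model(model: TrainedModel, dataset: LabeledDataset,
                   threshold: float = 0.5) -> MetricsReport:
    """Apply a trained selector+network unchanged to a labeled dataset.

    This is the cross-species protocol: the selector's index set and the
    network weights fitted on one species are used as-is on another.
    """
    if model.selector is None:
        raise ValueError("model carries no feature selector")
    X, y = encode_dataset(dataset)
    scores = predict_proba(model, apply_selector(model.selector, X))
    return score_metrics(y, scores, threshold)


# ---------------------------------------------------------------------------
# cross-validation

@dataclass
class CVResult:
    fold_reports: list[MetricsReport]
    fold_selected_counts: list[int]
    mean: dict
    std: dict

    def format_mean_std(self, key: str, digits: int = 4) -> str:
        return f"{self.mean[key]:.{digits}f}±{self.std[key]:.{digits}f}"


def kfold_cv(
    dataset: LabeledDataset,
    k: int = 5,
    l1: float | None = None,
    l2: float | None = None,
    net_config: NetworkConfig | None = None,
    train_config: TrainConfig | None = None,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold cross-validation of the full pipeline.

    Within each fold the selector is refit on the training rows only and
    its index set transferred to the test rows; the per-fold retained
    feature counts are recorded.
    """
    y_all = np.asarray(dataset.labels)
    n_pos, n_neg = int(y_all.sum()), int((1 - y_all).sum())
    if min(n_pos, n_neg) < k:
        raise ValueError(
            f"each class must have >= k={k} members (have {n_pos} pos, {n_neg} neg)"
        )
    X, y = encode_dataset(dataset)
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)

    fold_reports: list[MetricsReport] = []
    fold_counts: list[int] = []
    base_cfg = train_config or TrainConfig()
    for fold, (tr, te) in enumerate(splitter.split(X, y)):
        selector = fit_selector(X[tr], y[tr], l1=l1, l2=l2)
        if selector.n_selected == 0:
            raise ValueError(f"fold {fold}: zero features selected")
        fold_counts.append(selector.n_selected)
        X_tr = apply_selector(selector, X[tr])
        X_te = apply_selector(selector, X[te])
        cfg = TrainConfig(**{**base_cfg.__dict__, "seed": base_cfg.seed + fold})
        net = build_network(X_tr.shape[1], net_config, seed=cfg.seed)
        model = train(net, X_tr, y[tr], cfg, selector=selector)
        scores = predict_proba(model, X_te)
        fold_reports.append(score_metrics(y[te], scores))
        logger.info("fold %d: %d features, acc %.4f",
                    fold, selector.n_selected, fold_reports[-1].acc)

    keys = ("acc", "sn", "sp", "mcc", "auc", "auprc")
    mean = {k_: float(np.mean([getattr(r, k_) for r in fold_reports])) for k_ in keys}
    std = {k_: float(np.std([getattr(r, k_) for r in fold_reports])) for k_ in keys}
    return CVResult(fold_reports=fold_reports, fold_selected_counts=fold_counts,
                    mean=mean, std=std)
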