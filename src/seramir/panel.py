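"""Nested leave-one-out SVM classification with in-fold feature selection.

The procedure evaluates miRNA panels for separating patients from controls:
for every held-out sample, differential expression is re-run on the training
samples only (filter -> TMM -> quasi-likelihood F-test), the top-k miRNAs by
p-value form the panel, an RBF support-vector machine is trained on
standardized log-CPM features, and the held-out sample is scored. Panel size
is swept upward from six until accuracy saturates; the pooled panel is the
union of fold-selected miRNAs at the optimal size. Because feature selection,
normalization and standardization are all refit inside every fold, the
reported metrics carry no selection leakage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .de import (
    CONTROL,
    PATIENT,
    CountMatrix,
    NormalizationResult,
    compute_cpm,
    filter_low_expression,
    fit_dispersions,
    ql_f_test,
    tmm_factor_for_sample,
    tmm_factors,
)

__all__ = [
    "ClassifierConfig",
    "FoldRecord",
    "ConfusionCounts",
    "PanelMetrics",
    "PanelSweepResult",
    "rank_features_in_fold",
    "loocv_evaluate",
    "sweep_panel_sizes",
    "confusion_metrics",
    "roc_auc",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """SVM settings: RBF kernel, cost 1, gamma = 1/n_features by default."""

    kernel: str = "rbf"
    cost: float = 1.0
    gamma: str | float = "auto"  # 'auto' == 1 / n_features
    class_weight: str | None = None  # 'balanced' optional for 8-vs-22 designs
    min_cpm: float = 1.0
    min_libraries: int = 2
    prior_df: float = 10.0
    log_prior: float = 0.5  # pseudo-CPM added before log2
    patients_only_folds: bool = False


@dataclass
class FoldRecord:
    held_out: str
    selected: list[str]
    true_label: str
    predicted: str
    score: float  # larger => more patient-like


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class PanelMetrics:
    accuracy: float
    sensitivity: float | None
    specificity: float | None
    mcc: float
    auc: float
    confusion: ConfusionCounts
    folds: list[FoldRecord]


@dataclass
class PanelSweepResult:
    per_size: dict[int, PanelMetrics]
    optimal_size: int
    pooled_unique_mirnas: set[str]
    saturation_trace: list[tuple[int, float]]  # (size, accuracy) in sweep order

    @property
    def optimal_metrics(self) -> PanelMetrics:
        return self.per_size[self.optimal_size]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def confusion_metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Accuracy, sensitivity, specificity and MCC from a confusion table.

    Positive class = patient. MCC is 0 by convention when any denominator
    factor vanishes; sensitivity/specificity are None when undefined.
    """
    if c.total == 0:
        raise ValueError("empty confusion table")
    tp, fp, tn, fn = float(c.tp), float(c.fp), float(c.tn), float(c.fn)
    accuracy = (tp + tn) / c.total
    sensitivity = tp / (tp + fn) if tp + fn > 0 else None
    specificity = tn / (tn + fp) if tn + fp > 0 else None
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom > 0 else 0.0
    return {
        "accuracy": accuracy,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "mcc": float(mcc),
    }


def roc_auc(scores, labels) -> tuple[float, pd.DataFrame]:
    """AUC as the Mann-Whitney concordance probability (ties count 1/2).

    Returns (auc, roc_points) where roc_points holds (threshold, fpr, tpr)
    at every distinct score.
    """
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == PATIENT
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for ROC analysis")
    ranks = rankdata(scores)
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    pts = []
    for t in thresholds:
        pred_pos = scores >= t
        tpr = (pred_pos & pos).sum() / n_pos
        fpr = (pred_pos & ~pos).sum() / n_neg
        pts.append((t, fpr, tpr))
    roc = pd.DataFrame(pts, columns=["threshold", "fpr", "tpr"])
    return float(auc), roc


# ---------------------------------------------------------------------------
# in-fold machinery
# ---------------------------------------------------------------------------


def _log_cpm_features(
    counts: CountMatrix, norm: NormalizationResult, mirnas, log_prior: float
) -> pd.DataFrame:
    """Samples x features log2(CPM + prior) matrix restricted to ``mirnas``."""
    cpm = compute_cpm(counts, norm)
    return np.log2(cpm.loc[list(mirnas)] + log_prior).T


def rank_features_in_fold(
    train_counts: CountMatrix,
    train_sheet: pd.DataFrame,
    k: int | None = None,
    config: ClassifierConfig = ClassifierConfig(),
):
    """Rank miRNAs on the training samples only; return the top ``k``.

    Runs the full DE pipeline (filter -> TMM -> QLF) on the fold's training
    data and sorts by ascending p-value, then larger |log2FC|, then ID.
    Returns (ordered ids, filtered training CountMatrix, NormalizationResult).
    """
    if k is not None and k < 1:
        raise ValueError("k must be at least 1")
    filtered = filter_low_expression(
        train_counts, min_cpm=config.min_cpm, min_libraries=config.min_libraries
    )
    norm = tmm_factors(filtered)
    disp = fit_dispersions(filtered, train_sheet, norm, prior_df=config.prior_df)
    de = ql_f_test(filtered, train_sheet, norm, disp)
    ranked = list(de.sorted().index)
    if k is not None and k > len(ranked):
        warnings.warn(
            f"requested {k} features but only {len(ranked)} available; returning all"
        )
        k = len(ranked)
    return (ranked if k is None else ranked[:k]), filtered, norm


@dataclass
class _FoldContext:
    """Everything a fold needs that does not depend on the panel size."""

    held_out: str
    ranking: list[str]
    train_counts: CountMatrix
    norm: NormalizationResult
    heldout_factor: float


def _prepare_folds(
    counts: CountMatrix, sample_sheet: pd.DataFrame, config: ClassifierConfig
) -> list[_FoldContext]:
    labels = sample_sheet.set_index("sample_id")["group"].reindex(counts.samples)
    if (labels == PATIENT).sum() < 2 or (labels == CONTROL).sum() < 2:
        raise ValueError("LOOCV requires at least two samples per class")
    fold_samples = (
        [s for s in counts.samples if labels[s] == PATIENT]
        if config.patients_only_folds
        else list(counts.samples)
    )
    contexts = []
    for held in fold_samples:
        train_ids = [s for s in counts.samples if s != held]
        train_labels = labels[train_ids]
        if train_labels.nunique() < 2:
            raise ValueError(f"training fold without both classes when holding out {held}")
        train = counts.subset_samples(train_ids)
        sheet = sample_sheet[sample_sheet["sample_id"].isin(train_ids)]
        ranking, filtered, norm = rank_features_in_fold(train, sheet, k=None, config=config)
        factor = tmm_factor_for_sample(
            counts.counts[held], float(counts.library_sizes[held]), filtered, norm
        )
        contexts.append(
            _FoldContext(
                held_out=held,
                ranking=ranking,
                train_counts=filtered,
                norm=norm,
                heldout_factor=factor,
            )
        )
    return contexts


def _evaluate_size(
    counts: CountMatrix,
    labels: pd.Series,
    contexts: list[_FoldContext],
    panel_size: int,
    config: ClassifierConfig,
) -> PanelMetrics:
    records = []
    for ctx in contexts:
        selected = ctx.ranking[: min(panel_size, len(ctx.ranking))]
        x_train = _log_cpm_features(ctx.train_counts, ctx.norm, selected, config.log_prior)
        y_train = labels[x_train.index].to_numpy()

        mean = x_train.mean(axis=0).to_numpy()
        sd = x_train.std(axis=0, ddof=1).to_numpy()
        sd = np.where(sd > 0, sd, 1.0)
        x_tr = (x_train.to_numpy() - mean) / sd

        eff = float(counts.library_sizes[ctx.held_out]) * ctx.heldout_factor
        held_cpm = (
            counts.counts[ctx.held_out].reindex(selected).fillna(0).to_numpy() / eff * 1e6
        )
        x_te = (np.log2(held_cpm + config.log_prior) - mean) / sd

        clf = SVC(
            kernel=config.kernel,
            C=config.cost,
            gamma=config.gamma,
            class_weight=config.class_weight,
        )
        clf.fit(x_tr, y_train)
        pred = clf.predict(x_te[None, :])[0]
        raw = float(clf.decision_function(x_te[None, :])[0])
        # sklearn orients the decision function toward classes_[1]
        score = raw if clf.classes_[1] == PATIENT else -raw
        records.append(
            FoldRecord(
                held_out=ctx.held_out,
                selected=list(selected),
                true_label=labels[ctx.held_out],
                predicted=pred,
                score=score,
            )
        )

    tp = sum(1 for r in records if r.true_label == PATIENT and r.predicted == PATIENT)
    fn = sum(1 for r in records if r.true_label == PATIENT and r.predicted != PATIENT)
    tn = sum(1 for r in records if r.true_label == CONTROL and r.predicted == CONTROL)
    fp = sum(1 for r in records if r.true_label == CONTROL and r.predicted != CONTROL)
    conf = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
    m = confusion_metrics(conf)
    scores = [r.score for r in records]
    truth = [r.true_label for r in records]
    if len(set(truth)) == 2:
        auc, _ = roc_auc(scores, truth)
    else:  # patients-only folds: AUC undefined over held-out scores
        auc = float("nan")
    return PanelMetrics(
        accuracy=m["accuracy"],
        sensitivity=m["sensitivity"],
        specificity=m["specificity"],
        mcc=m["mcc"],
        auc=auc,
        confusion=conf,
        folds=records,
    )


def loocv_evaluate(
    counts: CountMatrix,
    sample_sheet: pd.DataFrame,
    panel_size: int,
    config: ClassifierConfig = ClassifierConfig(),
    _contexts: list[_FoldContext] | None = None,
) -> PanelMetrics:
    """Leave-one-out evaluation of a fixed panel size with in-fold selection."""
    if panel_size < 1:
        raise ValueError("panel_size must be at least 1")
    labels = sample_sheet.set_index("sample_id")["group"].reindex(counts.samples)
    contexts = _contexts or _prepare_folds(counts, sample_sheet, config)
    return _evaluate_size(counts, labels, contexts, panel_size, config)


def sweep_panel_sizes(
    counts: CountMatrix,
    sample_sheet: pd.DataFrame,
    start: int = 6,
    step: int = 1,
    patience: int = 3,
    max_size: int | None = None,
    config: ClassifierConfig = ClassifierConfig(),
) -> PanelSweepResult:
    """Sweep panel sizes upward from ``start`` until accuracy saturates.

    Stops after ``patience`` consecutive sizes without improving the best
    accuracy (or at ``max_size``). The optimal size is the smallest one
    achieving the best accuracy; the pooled panel is the union of features
    selected across folds at that size.
    """
    if start < 1 or step < 1 or patience < 1:
        raise ValueError("start, step and patience must be positive")
    labels = sample_sheet.set_index("sample_id")["group"].reindex(counts.samples)
    contexts = _prepare_folds(counts, sample_sheet, config)
    n_available = min(len(ctx.ranking) for ctx in contexts)
    if start > n_available:
        raise ValueError(f"start={start} exceeds the {n_available} available features")
    limit = n_available if max_size is None else min(max_size, n_available)

    per_size: dict[int, PanelMetrics] = {}
    trace: list[tuple[int, float]] = []
    best_acc = -np.inf
    stale = 0
    size = start
    while size <= limit:
        metrics = _evaluate_size(counts, labels, contexts, size, config)
        per_size[size] = metrics
        trace.append((size, metrics.accuracy))
        if metrics.accuracy > best_acc + 1e-12:
            best_acc = metrics.accuracy
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                break
        size += step

    optimal = min(s for s, m in per_size.items() if m.accuracy >= best_acc - 1e-12)
    pooled = set()
    for rec in per_size[optimal].folds:
        pooled.update(rec.selected)
    return PanelSweepResult(
        per_size=per_size,
        optimal_size=optimal,
        pooled_unique_mirnas=pooled,
        saturation_trace=trace,
    )
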