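"""Repeated stratified cross-validation and classification metrics.

The study protocol is five-fold stratified cross-validation repeated many
times (200 in the original protocol; a smaller repeat count is the desk
default): per repeat, subjects of each class are shuffled and dealt
round-robin into folds, so every fold's class composition matches the
overall prevalence to within one subject.  Each fold's training 80% fits
the entire pipeline — normalization, PCA, one SR-DBN per modality, ELM —
and the held-out 20% is scored.  Metrics are accuracy, sensitivity and
specificity in percent, plus AUC; fold-level metrics are averaged into
repeat-level means and aggregated as mean ± sd across repeats.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np

from ._utils import ValidationError, substream
from .io_prep import LabeledDataset

__all__ = [
    "CVConfig",
    "ConfusionCounts",
    "CVResult",
    "stratified_folds",
    "confusion_metrics",
    "roc_auc",
    "run_task_cv",
    "run_experiment_suite",
]


@dataclass(frozen=True)
class CVConfig:
    n_folds: int = 5
    n_repeats: int = 10
    seed: int = 0
    positive_class: str | None = None   # defaults to the task's first-listed class

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValidationError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValidationError("n_repeats must be >= 1")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class CVResult:
    """Per-repeat metric records plus mean ± sd aggregates."""

    task: str
    metrics: Dict[str, List[float]]          # repeat-level means per metric
    fold_records: list                       # (repeat, fold) -> metric dict
    aggregate: Dict[str, Dict[str, float]]   # metric -> {mean, sd}
    roc_points: list = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "task": self.task,
                "metrics": self.metrics,
                "fold_records": self.fold_records,
                "aggregate": self.aggregate,
                "roc_points": self.roc_points,
                "config": self.config,
            },
            indent=2,
            sort_keys=True,
        )


def stratified_folds(labels, n_folds: int, seed: int) -> np.ndarray:
    """Per-class shuffle + round-robin fold assignment.

    Guarantees each fold's per-class count differs from the ideal by at
    most one subject, and that folds partition the index set.
    """
    labels = np.asarray(labels)
    if n_folds < 2:
        raise ValidationError("n_folds must be >= 2")
    rng = substream(seed, "folds")
    assignment = np.full(labels.shape[0], -1, dtype=np.int64)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if idx.size < n_folds:
            raise ValidationError(
                f"class {c!r} has {idx.size} members, fewer than n_folds={n_folds}"
            )
        perm = rng.permutation(idx)
        assignment[perm] = np.arange(perm.size) % n_folds
    return assignment


def confusion_metrics(counts: ConfusionCounts) -> Dict[str, float]:
    """ACC/SEN/SPE in percent; undefined ratios reported as NaN with a warning."""
    if counts.total == 0:
        raise ValidationError("confusion counts are all zero")
    out = {"ACC": 100.0 * (counts.TP + counts.TN) / counts.total}
    for name, num, den in (
        ("SEN", counts.TP, counts.TP + counts.FN),
        ("SPE", counts.TN, counts.TN + counts.FP),
    ):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reporting NaN")
            out[name] = float("nan")
        else:
            out[name] = 100.0 * num / den
    return out


def roc_auc(scores, truth):
    """AUC by trapezoidal integration over the threshold sweep.

    Score ties are grouped into single threshold steps, so the trapezoids
    cut diagonally across tie blocks and the area equals the Mann–Whitney
    concordance probability with half-credit for ties.  Returns
    (auc, roc_points) where roc_points is a list of (fpr, tpr) pairs.
    """
    scores = np.asarray(scores, dtype=np.float64)
    truth = np.asarray(truth).astype(np.int64)
    if set(np.unique(truth)) - {0, 1}:
        raise ValidationError("truth must be binary 0/1")
    P = int(truth.sum())
    N = int(truth.size - P)
    if P == 0 or N == 0:
        raise ValidationError("both classes must be present for ROC analysis")
    order = np.argsort(-scores, kind="mergesort")
    s, t = scores[order], truth[order]
    # cumulative counts at each distinct-threshold boundary
    distinct = np.r_[np.flatnonzero(np.diff(s)), s.size - 1]
    tps = np.cumsum(t)[distinct]
    fps = distinct + 1 - tps
    tpr = np.r_[0.0, tps / P]
    fpr = np.r_[0.0, fps / N]
    auc = float(np.trapezoid(tpr, fpr))
    return auc, list(zip(fpr.tolist(), tpr.tolist()))


def _task_binary_view(dataset: LabeledDataset, task: Sequence[str], positive_class: str | None):
    """Restrict to the task's two classes; positive class becomes label 1."""
    if len(task) != 2:
        raise ValidationError("a task is an ordered pair of class names")
    for c in task:
        if c not in dataset.class_names:
            raise ValidationError(f"class {c!r} not in dataset classes {dataset.class_names}")
    pos = positive_class if positive_class is not None else task[0]
    if pos not in task:
        raise ValidationError(f"positive_class {pos!r} not in task {task}")
    neg = task[0] if task[1] == pos else task[1]
    codes = {dataset.class_names.index(neg): 0, dataset.class_names.index(pos): 1}
    rows = np.flatnonzero(np.isin(dataset.labels, list(codes)))
    sub = dataset.subset(rows)
    sub.labels = np.array([codes[l] for l in sub.labels], dtype=np.int64)
    sub.class_names = [neg, pos]
    return sub


def run_task_cv(dataset: LabeledDataset, task: Sequence[str], pipeline_config,
                cv: CVConfig) -> CVResult:
    """Repeated stratified k-fold CV of the full pipeline on one binary task.

    All fitting (normalization, PCA, SR-DBNs, ELM) uses only the training
    folds; the held-out fold is scored with the frozen bundle.  AUC is
    fold-averaged.  Identical configuration and seed give identical results.
    """
    from .pipeline import fit_pipeline, predict_pipeline  # local import, avoids cycle

    data = _task_binary_view(dataset, task, cv.positive_class)
    task_name = f"{data.class_names[1]}_vs_{data.class_names[0]}"

    metric_names = ("ACC", "SEN", "SPE", "AUC")
    repeat_means = {m: [] for m in metric_names}
    fold_records = []
    roc_points = []
    for rep in range(cv.n_repeats):
        rep_seed = int(substream(cv.seed, "repeat", rep).integers(2 ** 31))
        assignment = stratified_folds(data.labels, cv.n_folds, rep_seed)
        per_fold = {m: [] for m in metric_names}
        for fold in range(cv.n_folds):
            test_rows = np.flatnonzero(assignment == fold)
            train_rows = np.flatnonzero(assignment != fold)
            try:
                bundle = fit_pipeline(data.subset(train_rows), pipeline_config,
                                      seed_offset=rep_seed + fold)
                pred, scores, roc_score = predict_pipeline(bundle, data.subset(test_rows),
                                                           positive_class=1)
            except Exception as exc:
                raise RuntimeError(
                    f"pipeline failed at repeat {rep}, fold {fold}: {exc}"
                ) from exc
            truth = data.labels[test_rows]
            counts = ConfusionCounts(
                TP=int(np.sum((pred == 1) & (truth == 1))),
                FP=int(np.sum((pred == 1) & (truth == 0))),
                TN=int(np.sum((pred == 0) & (truth == 0))),
                FN=int(np.sum((pred == 0) & (truth == 1))),
            )
            rec = confusion_metrics(counts)
            rec["AUC"], pts = roc_auc(roc_score, truth)
            if rep == 0:
                roc_points.append(pts)
            for m in metric_names:
                per_fold[m].append(rec[m])
            fold_records.append({"repeat": rep, "fold": fold, **rec})
        for m in metric_names:
            repeat_means[m].append(float(np.nanmean(per_fold[m])))

    aggregate = {
        m: {"mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0}
        for m, v in repeat_means.items()
    }
    return CVResult(
        task=task_name,
        metrics=repeat_means,
        fold_records=fold_records,
        aggregate=aggregate,
        roc_points=roc_points,
        config={"n_folds": cv.n_folds, "n_repeats": cv.n_repeats, "seed": cv.seed,
                "positive_class": data.class_names[1]},
    )


KNOWN_VARIANTS = ("full", "no_sparsity", "pca_elm")


def run_experiment_suite(dataset: LabeledDataset, tasks, variants, cv: CVConfig,
                         pipeline_config=None) -> Dict[str, Dict[str, CVResult]]:
    """Run every task under every pipeline variant.

    ``full`` is PCA → SR-DBN per modality → ELM; ``no_sparsity`` is the
    same with λ=0 (a plain DBN); ``pca_elm`` feeds PCA scores straight into
    the ELM.  Returns results[task_name][variant].
    """
    from .pipeline import PipelineConfig

    if not variants:
        raise ValidationError("variants must be nonempty")
    for v in variants:
        if v not in KNOWN_VARIANTS:
            raise ValidationError(f"unknown variant {v!r}; known: {KNOWN_VARIANTS}")
    if pipeline_config is None:
        pipeline_config = PipelineConfig()

    results: Dict[str, Dict[str, CVResult]] = {}
    for task in tasks:
        key = f"{task[0]}_vs_{task[1]}"
        results[key] = {}
        for variant in variants:
            cfg = pipeline_config.with_variant(variant)
            results[key][variant] = run_task_cv(dataset, task, cfg, cv)
    return results


def results_table(results: Dict[str, Dict[str, CVResult]]) -> "object":
    """Flatten suite results into a tidy DataFrame (task, variant, metric, mean, sd)."""
    import pandas as pd

    rows = []
    for task, by_variant in results.items():
        for variant, res in by_variant.items():
            for metric, agg in res.aggregate.items():
                rows.append({"task": task, "variant": variant, "metric": metric,
                             "mean": agg["mean"], "sd": agg["sd"]})
    return pd.DataFrame(rows)
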