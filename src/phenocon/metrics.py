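"""Evaluation metrics: exact-match accuracy, macro PR AUC, class deconvolution.

Exact-match accuracy scores a prediction as correct only when the predicted
label *set* equals the ground-truth set.  Macro PR AUC is the mean, over
classes with at least one positive, of the per-class area under the
precision-recall curve (average-precision-style step integration).  The
deconvolution report breaks performance down per class: TP/FP/FN/TN per fold,
precision/recall/F1 per fold, and fold means, flagged against a minimum
precision threshold (default 10%).

Conventions: precision, recall and F1 are 0 when their denominators are 0;
metrics are computed per fold and then averaged across folds (pooling counts
first is available behind ``pooled=True``) — note the fold-mean of F1 is not
the harmonic mean of fold-mean precision and recall.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score

from .downstream import PredictionSet

logger = logging.getLogger(__name__)


def exact_match_accuracy(preds: PredictionSet | Sequence[PredictionSet]) -> float:
    """Fraction of images whose predicted label set equals the truth set."""
    sets = [preds] if isinstance(preds, PredictionSet) else list(preds)
    if not sets or sum(len(p.image_ids) for p in sets) == 0:
        raise ValueError("no predictions to score")
    hits = total = 0
    for p in sets:
        for pred, truth in zip(p.predicted, p.truths):
            hits += int(set(pred) == set(truth))
            total += 1
    return hits / total


def macro_pr_auc(
    scores: np.ndarray, truths: Sequence[Sequence[str]], classes: Sequence[str]
) -> float:
    """Mean per-class PR AUC over classes with >= 1 positive example.

    ``scores`` columns align with ``classes``; ``truths`` are per-image label
    sets.  Classes without positives are excluded (and logged).
    """
    scores = np.asarray(scores, dtype=float)
    Y = np.array([[c in set(t) for c in classes] for t in truths], dtype=int)
    aucs = []
    for j, c in enumerate(classes):
        if Y[:, j].sum() == 0:
            logger.info("class %r has no positives; excluded from macro PR AUC", c)
            continue
        aucs.append(average_precision_score(Y[:, j], scores[:, j]))
    if not aucs:
        raise ValueError("no class has a positive example")
    return float(np.mean(aucs))


@dataclass
class ClassReport:
    """Per-class confusion counts and P/R/F1, per fold and fold-averaged.

    Percentages are on the 0–100 scale.  ``passes_threshold`` flags classes
    whose fold-mean precision reaches the minimum-precision criterion.
    """

    class_name: str
    folds: list[int]
    tp: list[int]
    fp: list[int]
    fn: list[int]
    tn: list[int]
    precision: list[float] = field(default_factory=list)
    recall: list[float] = field(default_factory=list)
    f1: list[float] = field(default_factory=list)
    support: int = 0
    mean_precision: float = 0.0
    mean_recall: float = 0.0
    mean_f1: float = 0.0
    passes_threshold: bool = False

    def finalize(self, threshold: float) -> "ClassReport":
        for tp, fp, fn in zip(self.tp, self.fp, self.fn):
            p = 100.0 * tp / (tp + fp) if tp + fp else 0.0
            r = 100.0 * tp / (tp + fn) if tp + fn else 0.0
            f = 2 * p * r / (p + r) if p + r else 0.0
            self.precision.append(p)
            self.recall.append(r)
            self.f1.append(f)
        self.support = int(sum(self.tp) + sum(self.fn))
        self.mean_precision = float(np.mean(self.precision))
        self.mean_recall = float(np.mean(self.recall))
        self.mean_f1 = float(np.mean(self.f1))
        self.passes_threshold = self.mean_precision >= threshold
        return self


def _fold_counts(p: PredictionSet) -> dict[str, tuple[int, int, int, int]]:
    classes = set(p.classes)
    for t in p.truths:
        classes.update(t)
    for pr in p.predicted:
        classes.update(pr)
    counts = {c: [0, 0, 0, 0] for c in classes}  # tp, fp, fn, tn
    for pred, truth in zip(p.predicted, p.truths):
        ps, ts = set(pred), set(truth)
        for c in classes:
            inp, int_ = c in ps, c in ts
            if inp and int_:
                counts[c][0] += 1
            elif inp:
                counts[c][1] += 1
            elif int_:
                counts[c][2] += 1
            else:
                counts[c][3] += 1
    return {c: tuple(v) for c, v in counts.items()}


def class_deconvolution(
    per_fold_preds: Sequence[PredictionSet],
    precision_threshold: float = 10.0,
    pooled: bool = False,
) -> list[ClassReport]:
    """Per-class deconvolution of CV predictions, ranked by fold-mean F1.

    Metrics are computed per fold then averaged over the folds in which the
    class appears (in truths or predictions).  With ``pooled=True`` the
    TP/FP/FN/TN counts are summed across folds before computing a single
    precision/recall/F1 instead.
    """
    if not per_fold_preds:
        raise ValueError("need at least one fold")
    if not 0 <= precision_threshold <= 100:
        raise ValueError("precision_threshold must be in [0, 100]")
    fold_counts = [(p.fold, _fold_counts(p)) for p in per_fold_preds]
    all_classes = sorted(set().union(*(fc[1] for fc in fold_counts)))
    reports: list[ClassReport] = []
    for c in all_classes:
        folds, tp, fp, fn, tn = [], [], [], [], []
        for fold, counts in fold_counts:
            if c not in counts:
                continue
            t, f, n, tneg = counts[c]
            if t + f + n == 0:  # class absent from this fold's truths & preds
                continue
            folds.append(fold)
            tp.append(t)
            fp.append(f)
            fn.append(n)
            tn.append(tneg)
        if not folds:
            continue
        if pooled:
            folds, tp, fp, fn, tn = [-1], [sum(tp)], [sum(fp)], [sum(fn)], [sum(tn)]
        reports.append(
            ClassReport(c, folds, tp, fp, fn, tn).finalize(precision_threshold)
        )
    reports.sort(key=lambda r: (-r.mean_f1, r.class_name))
    return reports


def deconvolution_table(reports: Sequence[ClassReport]) -> pd.DataFrame:
    """Ranked per-class table (precision/recall/F1 fold means, percent)."""
    return pd.DataFrame(
        [
            {
                "class": r.class_name,
                "precision_pct": r.mean_precision,
                "recall_pct": r.mean_recall,
                "f1_pct": r.mean_f1,
                "support": r.support,
                "passes_threshold": r.passes_threshold,
            }
            for r in reports
        ]
    )


def grand_means(reports: Sequence[ClassReport]) -> dict[str, float]:
    """Mean precision/recall/F1 over all reported classes (percent)."""
    return {
        "mean_precision_pct": float(np.mean([r.mean_precision for r in reports])),
        "mean_recall_pct": float(np.mean([r.mean_recall for r in reports])),
        "mean_f1_pct": float(np.mean([r.mean_f1 for r in reports])),
        "n_classes": len(reports),
        "n_passing_threshold": int(sum(r.passes_threshold for r in reports)),
    }
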