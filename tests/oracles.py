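"""Independent brute-force oracles used by the unit and acceptance tests.

These are deliberately naive (explicit Python loops, direct formula
transcriptions) and share no code with the package implementation.
"""

from __future__ import annotations

import numpy as np


def brute_self_supervised_loss(Z: np.ndarray, pair_index, tau: float) -> float:
    """Double-loop InfoNCE: mean over anchors of -log softmax of the positive."""
    n = len(Z)
    total = 0.0
    for i in range(n):
        num = np.exp(Z[i] @ Z[pair_index[i]] / tau)
        den = sum(np.exp(Z[i] @ Z[a] / tau) for a in range(n) if a != i)
        total += -np.log(num / den)
    return total / n


def brute_supervised_loss(Z: np.ndarray, pair_index, labels, tau: float) -> float:
    """Triple-loop supervised contrastive loss with P(i) = same-label ∪ replicate."""
    n = len(Z)
    total = 0.0
    for i in range(n):
        pos = [p for p in range(n) if p != i and (labels[p] == labels[i] or p == pair_index[i])]
        den = sum(np.exp(Z[i] @ Z[a] / tau) for a in range(n) if a != i)
        inner = 0.0
        for p in pos:
            inner += np.log(np.exp(Z[i] @ Z[p] / tau) / den)
        total += -inner / len(pos)
    return total / n


def brute_exact_match(predicted: list, truths: list) -> float:
    """Per-image set-equality enumeration."""
    hits = 0
    for p, t in zip(predicted, truths):
        hits += 1 if sorted(set(p)) == sorted(set(t)) else 0
    return hits / len(predicted)


def brute_average_precision(y_true: np.ndarray, scores: np.ndarray) -> float:
    """PR staircase integration: AP = sum over positives of precision@k * dRecall."""
    order = np.argsort(-scores, kind="stable")
    y = np.asarray(y_true)[order]
    n_pos = y.sum()
    ap = 0.0
    tp = 0
    for k, yk in enumerate(y, start=1):
        if yk:
            tp += 1
            ap += (tp / k) / n_pos
    return ap


def brute_prf_counts(predicted: list, truths: list, cls: str) -> tuple[int, int, int, int]:
    """TP/FP/FN/TN for one class over per-image label sets."""
    tp = fp = fn = tn = 0
    for p, t in zip(predicted, truths):
        inp, int_ = cls in set(p), cls in set(t)
        if inp and int_:
            tp += 1
        elif inp:
            fp += 1
        elif int_:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn
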