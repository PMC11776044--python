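"""Embedding extraction and downstream bioactivity classifiers.

Learned latents z are used directly as image features.  Classifiers are
random forests (single-label multiclass, or binary-relevance one-vs-rest for
multilabel) and a 512/256 MLP head with 50% dropout and early stopping.
Evaluation is cross-validated at the treatment level: a compound's images are
always entirely in-train or entirely in-test for a fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from . import nn
from .contrastive import EncoderModel
from .io_data import AnnotationTable, ImageRecord, SplitPlan, primary_label

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingMatrix:
    """Per-image latent vectors with the image→compound mapping."""

    image_ids: list[str]
    compound_ids: list[str]
    features: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features)
        if len(self.image_ids) != len(self.compound_ids) or len(self.image_ids) != len(
            self.features
        ):
            raise ValueError("image_ids, compound_ids and features must align")
        if np.isnan(self.features).any():
            raise ValueError("embedding matrix contains NaN")

    def subset(self, mask: np.ndarray) -> "EmbeddingMatrix":
        idx = np.flatnonzero(mask)
        return EmbeddingMatrix(
            [self.image_ids[i] for i in idx],
            [self.compound_ids[i] for i in idx],
            self.features[idx],
        )

    def rows_for_compound(self, compound_id: str) -> np.ndarray:
        mask = np.array([c == compound_id for c in self.compound_ids])
        return self.features[mask]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.features, columns=[f"z{i}" for i in range(self.features.shape[1])])
        df.insert(0, "compound_id", self.compound_ids)
        df.insert(0, "image_id", self.image_ids)
        df.to_csv(path, index=False, float_format="%.8g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "EmbeddingMatrix":
        df = pd.read_csv(path)
        feat_cols = [c for c in df.columns if c.startswith("z")]
        return cls(
            df["image_id"].astype(str).tolist(),
            df["compound_id"].astype(str).tolist(),
            df[feat_cols].to_numpy(),
        )


@dataclass
class PredictionSet:
    """Per-image predictions, scores and truths for one evaluation fold."""

    image_ids: list[str]
    compound_ids: list[str]
    predicted: list[list[str]]
    truths: list[list[str]]
    scores: np.ndarray
    classes: list[str]
    task: str  # "single" | "multi"
    fold: int = 0

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.image_ids), len(self.classes)):
            raise ValueError("scores must be n_images × n_classes")
        if self.task == "single" and any(len(p) != 1 for p in self.predicted):
            raise ValueError("single-label predictions must have exactly one label")


def extract_embeddings(model: EncoderModel, records: Sequence[ImageRecord]) -> EmbeddingMatrix:
    """Project every image to its latent z, in input order (rows unit-norm)."""
    if len(records) == 0:
        raise ValueError("no records to embed")
    Z = model.project(records)
    return EmbeddingMatrix(
        [r.image_id for r in records], [r.compound_id for r in records], Z
    )


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

@dataclass
class TrainedClassifier:
    """Uniform facade over fitted single-/multilabel heads.

    ``predict_scores`` returns an M×C score matrix aligned to ``classes``;
    ``predict_labels`` applies argmax (single) or the per-class score
    threshold (multilabel, default 0.5).
    """

    task: str
    classes: list[str]
    kind: str
    threshold: float = 0.5
    _impl: object = field(default=None, repr=False)

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        return self._impl.scores(np.asarray(X))  # type: ignore[attr-defined]

    def predict_labels(self, X: np.ndarray) -> list[list[str]]:
        scores = self.predict_scores(X)
        if self.task == "single":
            return [[self.classes[i]] for i in scores.argmax(axis=1)]
        return [
            [c for c, s in zip(self.classes, row) if s >= self.threshold]
            for row in scores
        ]


class _RFSingle:
    def __init__(self, clf: RandomForestClassifier, classes: list[str]):
        self.clf, self.classes = clf, classes

    def scores(self, X: np.ndarray) -> np.ndarray:
        proba = self.clf.predict_proba(X)
        out = np.zeros((len(X), len(self.classes)))
        for j, c in enumerate(self.clf.classes_):
            out[:, self.classes.index(c)] = proba[:, j]
        return out


class _RFBinaryRelevance:
    def __init__(self, forests: dict[str, RandomForestClassifier], classes: list[str]):
        self.forests, self.classes = forests, classes

    def scores(self, X: np.ndarray) -> np.ndarray:
        out = np.zeros((len(X), len(self.classes)))
        for j, c in enumerate(self.classes):
            clf = self.forests[c]
            proba = clf.predict_proba(X)
            if proba.shape[1] == 1:  # class constant in training data
                out[:, j] = float(clf.classes_[0])
            else:
                out[:, j] = proba[:, list(clf.classes_).index(1)]
        return out


def _default_rf_params() -> dict:
    return {"n_estimators": 500, "max_features": "sqrt"}


def train_random_forest(
    train: EmbeddingMatrix,
    labels: Sequence[Sequence[str]] | Sequence[str],
    task: str = "single",
    rf_params: Mapping | None = None,
    seed: int = 0,
) -> TrainedClassifier:
    """Fit the downstream random forest(s) on embedding features.

    Single-label: one multiclass forest on primary labels.  Multilabel:
    binary-relevance one-vs-rest forests over the class vocabulary.  Classes
    with zero training examples are dropped with a warning.
    """
    params = {**_default_rf_params(), **dict(rf_params or {})}
    X = train.features
    if task == "single":
        y = np.array([l if isinstance(l, str) else l[0] for l in labels])
        classes = sorted(set(y))
        clf = RandomForestClassifier(random_state=seed, **params)
        clf.fit(X, y)
        return TrainedClassifier("single", classes, "rf", _impl=_RFSingle(clf, classes))
    label_sets = [set(l) for l in labels]
    vocab = sorted(set().union(*label_sets)) if label_sets else []
    forests: dict[str, RandomForestClassifier] = {}
    kept = []
    for c in vocab:
        y = np.array([int(c in s) for s in label_sets])
        if y.sum() == 0:
            logger.warning("class %r has no training examples; dropped", c)
            continue
        clf = RandomForestClassifier(random_state=seed, **params)
        clf.fit(X, y)
        forests[c] = clf
        kept.append(c)
    return TrainedClassifier("multi", kept, "rf", _impl=_RFBinaryRelevance(forests, kept))


class _MLPImpl:
    def __init__(self, net: nn.Sequential, task: str):
        self.net, self.task = net, task

    def scores(self, X: np.ndarray) -> np.ndarray:
        logits = self.net.forward(np.asarray(X, dtype=np.float32), train=False)
        if self.task == "single":
            e = np.exp(logits - logits.max(axis=1, keepdims=True))
            return e / e.sum(axis=1, keepdims=True)
        return 1.0 / (1.0 + np.exp(-logits))


def _default_mlp_params() -> dict:
    return {
        "hidden": (512, 256),
        "dropout": 0.5,
        "learning_rate": 10 ** -2.5,
        "max_epochs": 200,
        "batch_size": 32,
        "patience": 10,
        "val_fraction": 0.1,
    }


def train_mlp(
    train: EmbeddingMatrix,
    labels: Sequence[Sequence[str]] | Sequence[str],
    task: str = "multi",
    mlp_params: Mapping | None = None,
    seed: int = 0,
) -> TrainedClassifier:
    """Fit the 512/256 MLP head with 50% dropout and early stopping.

    Cross-entropy loss (softmax for single-label, per-class sigmoid for
    multilabel); a held-out slice of the training images drives early
    stopping (patience on validation loss, best weights restored).
    """
    p = {**_default_mlp_params(), **dict(mlp_params or {})}
    label_sets = [{l} if isinstance(l, str) else set(l) for l in labels]
    classes = sorted(set().union(*label_sets))
    if len(classes) < 2:
        raise ValueError("MLP head needs at least 2 classes")
    Y = np.array([[int(c in s) for c in classes] for s in label_sets], dtype=np.float64)
    X = np.asarray(train.features, dtype=np.float32)

    rng = np.random.default_rng(seed)
    n_val = int(round(p["val_fraction"] * len(X)))
    if n_val < 1:
        raise ValueError("validation slice is empty; need more training images")
    order = rng.permutation(len(X))
    val_idx, tr_idx = order[:n_val], order[n_val:]

    h1, h2 = p["hidden"]
    net = nn.Sequential(
        [
            nn.Dense(X.shape[1], h1, rng),
            nn.ReLU(),
            nn.Dropout(p["dropout"], rng),
            nn.Dense(h1, h2, rng),
            nn.ReLU(),
            nn.Dropout(p["dropout"], rng),
            nn.Dense(h2, len(classes), rng),
        ]
    )
    opt = nn.RMSProp(net, lr=p["learning_rate"])

    def loss_and_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
        m = len(logits)
        if task == "single":
            z = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(z)
            prob = e / e.sum(axis=1, keepdims=True)
            loss = -(y * np.log(np.maximum(prob, 1e-12))).sum() / m
            return loss, (prob - y) / m
        prob = 1.0 / (1.0 + np.exp(-logits))
        loss = -(
            y * np.log(np.maximum(prob, 1e-12))
            + (1 - y) * np.log(np.maximum(1 - prob, 1e-12))
        ).sum() / (m * len(classes))
        return loss, (prob - y) / (m * len(classes))

    best_loss, best_weights, since_best = np.inf, net.get_weights(), 0
    for _ in range(int(p["max_epochs"])):
        eorder = rng.permutation(tr_idx)
        for i in range(0, len(eorder), p["batch_size"]):
            idx = eorder[i : i + p["batch_size"]]
            logits = net.forward(X[idx], train=True)
            _, dlogits = loss_and_grad(logits.astype(np.float64), Y[idx])
            net.backward(dlogits.astype(np.float32))
            opt.step()
        val_logits = net.forward(X[val_idx], train=False)
        val_loss, _ = loss_and_grad(val_logits.astype(np.float64), Y[val_idx])
        if val_loss < best_loss - 1e-6:
            best_loss, best_weights, since_best = val_loss, net.get_weights(), 0
        else:
            since_best += 1
            if since_best >= p["patience"]:
                break
    net.set_weights(best_weights)
    return TrainedClassifier(task, classes, "mlp", _impl=_MLPImpl(net, task))


# ---------------------------------------------------------------------------
# cross-validated evaluation
# ---------------------------------------------------------------------------

def _targets_for(
    annotations: AnnotationTable, compound_ids: Sequence[str], task: str
) -> list:
    if task == "single":
        return [primary_label(annotations, c) for c in compound_ids]
    return [list(annotations.labels.get(c, [])) for c in compound_ids]


def cross_validate(
    embeddings: EmbeddingMatrix,
    annotations: AnnotationTable,
    plan: SplitPlan,
    model_spec: Mapping | None = None,
) -> list[PredictionSet]:
    """Train and evaluate the downstream classifier on every CV fold.

    ``model_spec`` keys: ``model`` ("rf"|"mlp"), ``task`` ("single"|"multi"),
    ``seed``, plus optional ``rf_params``/``mlp_params``.  Per fold the
    classifier trains on images of train-fold compounds and predicts every
    image of test-fold compounds; train/test compound disjointness is
    asserted on every fold.
    """
    spec = {"model": "rf", "task": "single", "seed": 0, **dict(model_spec or {})}
    task = spec["task"]
    covered = set(plan.assignments)
    missing = set(annotations.annotated_compounds) & set(embeddings.compound_ids) - covered
    if missing:
        raise ValueError(f"split plan does not cover compounds: {sorted(missing)[:5]}")

    out: list[PredictionSet] = []
    compound_arr = np.array(embeddings.compound_ids)
    for fold in range(plan.fold_count):
        test_c = set(plan.test_compounds(fold))
        train_c = set(plan.train_compounds(fold))
        assert not (test_c & train_c), "train/test compound leakage"
        tr = embeddings.subset(np.isin(compound_arr, sorted(train_c)))
        te = embeddings.subset(np.isin(compound_arr, sorted(test_c)))
        if not te.image_ids:
            raise ValueError(f"fold {fold} has an empty test set")
        y_tr = _targets_for(annotations, tr.compound_ids, task)
        if spec["model"] == "rf":
            clf = train_random_forest(
                tr, y_tr, task=task, rf_params=spec.get("rf_params"), seed=spec["seed"]
            )
        elif spec["model"] == "mlp":
            clf = train_mlp(
                tr, y_tr, task=task, mlp_params=spec.get("mlp_params"), seed=spec["seed"]
            )
        else:
            raise ValueError(f"unknown model {spec['model']!r}")
        truths = _targets_for(annotations, te.compound_ids, task)
        truths = [[t] if isinstance(t, str) else list(t) for t in truths]
        out.append(
            PredictionSet(
                image_ids=te.image_ids,
                compound_ids=te.compound_ids,
                predicted=clf.predict_labels(te.features),
                truths=truths,
                scores=clf.predict_scores(te.features),
                classes=clf.classes,
                task=task,
                fold=fold,
            )
        )
    return out


def predict_compound_classes(
    classifier: TrainedClassifier,
    replicate_embeddings: np.ndarray,
    top_k: int = 3,
) -> list[tuple[str, int]]:
    """Predict a class per replicate, tally, and return the top_k by count.

    Count ties are broken lexically by class name.
    """
    if len(replicate_embeddings) == 0:
        raise ValueError("need at least one replicate embedding")
    preds = classifier.predict_labels(np.asarray(replicate_embeddings))
    counts: dict[str, int] = {}
    for labs in preds:
        for lab in labs:
            counts[lab] = counts.get(lab, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top_k]
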