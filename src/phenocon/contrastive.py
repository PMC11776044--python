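"""Multiview batches, contrastive losses, and semisupervised training.

The representation learner follows the SupCon family: every minibatch pairs N
anchor images with one replicate each (the *multiviewed batch* of 2N entries).
The self-supervised InfoNCE loss pulls each anchor toward its replicate and
away from all other batch entries; the supervised contrastive loss widens the
positive set P(i) to every entry sharing the anchor's class label.  Training
alternates, within each epoch, a self-supervised pass over the full image set
and a supervised pass over the annotated subset (primary labels only).

Latents z = g(f(x)) are L2-normalized, so temperature-scaled dot products are
cosine similarities.  Losses are averaged over the 2N anchors.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import nn
from .io_data import AnnotationTable, ImageRecord, group_by_compound, primary_label

_NORM_TOL = 1e-3


# ---------------------------------------------------------------------------
# configuration and batch structure
# ---------------------------------------------------------------------------

@dataclass
class ContrastiveConfig:
    """Hyperparameters of the contrastive representation learner.

    Defaults follow the reference setup: temperature 0.07, learning rate
    10^-2.5, projector output width 224, batch size 40 anchor pairs, up to
    250 epochs.
    """

    temperature: float = 0.07
    learning_rate: float = 10 ** -2.5
    projector_dim: int = 224
    batch_size: int = 40
    max_epochs: int = 250
    seed: int = 0
    supervised_weight: float = 1.0
    backbone_name: str = "small_cnn"
    feature_dim: int = 128

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.backbone_name != "small_cnn":
            raise ValueError(f"unknown backbone {self.backbone_name!r}")


@dataclass
class MultiviewBatch:
    """2N batch entries with a mutual anchor↔replicate pairing.

    ``entries`` are indices into an external record/image collection.
    ``pair_index`` maps each position to its positive's position (an
    involution without fixed points).  When ``labels`` is present, paired
    entries must share a label.
    """

    entries: np.ndarray
    pair_index: np.ndarray
    N: int
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries)
        self.pair_index = np.asarray(self.pair_index)
        n = len(self.entries)
        if n != 2 * self.N:
            raise ValueError(f"expected 2N={2*self.N} entries, got {n}")
        if len(self.pair_index) != n:
            raise ValueError("pair_index length mismatch")
        idx = np.arange(n)
        if (self.pair_index == idx).any() or not (self.pair_index[self.pair_index] == idx).all():
            raise ValueError("pair_index must be an involution without fixed points")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if (self.labels != self.labels[self.pair_index]).any():
                raise ValueError("paired entries must share a label")


def build_multiview_batch(
    records: Sequence[ImageRecord] | int,
    compound_index: Mapping[str, list[int]] | None,
    N: int,
    seed: int | np.random.Generator = 0,
    anchors: np.ndarray | None = None,
    labels_by_index: Mapping[int, str] | None = None,
) -> MultiviewBatch:
    """Sample N anchors and one replicate each into a multiviewed batch.

    The replicate of an anchor is drawn uniformly from the other images of
    its compound; a compound with a single image is self-paired.  Entries are
    laid out ``[a_0, r_0, a_1, r_1, ...]``.  Deterministic given the seed.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(records, int):
        n_images = records
        by_compound = dict(compound_index or {})
    else:
        n_images = len(records)
        by_compound = group_by_compound(records) if compound_index is None else dict(compound_index)
    compound_of = {i: c for c, idxs in by_compound.items() for i in idxs}

    if anchors is None:
        replace = N > n_images
        anchors = rng.choice(n_images, size=N, replace=replace)
    entries = np.empty(2 * N, dtype=int)
    for k, a in enumerate(anchors):
        mates = [i for i in by_compound[compound_of[int(a)]] if i != int(a)]
        pos = int(rng.choice(mates)) if mates else int(a)
        entries[2 * k] = int(a)
        entries[2 * k + 1] = pos
    pair_index = np.arange(2 * N)
    pair_index[0::2] += 1
    pair_index[1::2] -= 1
    labels = None
    if labels_by_index is not None:
        labels = np.array([labels_by_index[int(e)] for e in entries])
    return MultiviewBatch(entries=entries, pair_index=pair_index, N=N, labels=labels)


# ---------------------------------------------------------------------------
# losses (with analytic gradients)
# ---------------------------------------------------------------------------

def _check_latents(Z: np.ndarray) -> np.ndarray:
    Z = np.asarray(Z, dtype=np.float64)
    if np.isnan(Z).any():
        raise ValueError("latents contain NaN")
    norms = np.linalg.norm(Z, axis=1)
    if np.abs(norms - 1.0).max() > _NORM_TOL:
        raise ValueError("latent rows must be unit-normalized")
    return Z


def _contrastive_terms(
    Z: np.ndarray,
    pair_index: np.ndarray,
    tau: float,
    labels: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-anchor losses and the gradient of their mean w.r.t. Z.

    With ``labels`` None this is the InfoNCE term: loss_i = LSE_i - s_{i,j(i)}.
    With labels, the positive target spreads 1/|P(i)| mass over P(i), the
    same-label entries (plus the replicate) excluding the anchor itself.
    Log-sum-exp uses max-subtraction.
    """
    Z = _check_latents(Z)
    if tau <= 0:
        raise ValueError("temperature must be > 0")
    n = len(Z)
    pair_index = np.asarray(pair_index)
    S = (Z @ Z.T) / tau
    neg_inf = np.finfo(np.float64).min
    np.fill_diagonal(S, neg_inf)  # A(i) excludes the anchor itself

    smax = S.max(axis=1, keepdims=True)
    expS = np.exp(S - smax)
    sumexp = expS.sum(axis=1, keepdims=True)
    lse = (smax + np.log(sumexp)).ravel()
    P = expS / sumexp  # softmax over A(i)

    target = np.zeros((n, n))
    if labels is None:
        target[np.arange(n), pair_index] = 1.0
        losses = lse - S[np.arange(n), pair_index]
    else:
        labels = np.asarray(labels)
        if (labels == None).any():  # noqa: E711  (object arrays)
            raise ValueError("every batch entry needs a label for the supervised loss")
        pos = labels[:, None] == labels[None, :]
        np.fill_diagonal(pos, False)
        pos[np.arange(n), pair_index] = True  # j(i) ∈ P(i) always
        sizes = pos.sum(axis=1)
        target[pos] = 1.0
        target /= sizes[:, None]
        losses = lse - (target * np.where(pos, S, 0.0)).sum(axis=1)

    G = (P - target) / n  # d(mean loss)/dS
    dZ = ((G + G.T) @ Z) / tau
    return losses, dZ


def per_anchor_self_loss(Z: np.ndarray, pair_index: np.ndarray, tau: float) -> np.ndarray:
    """Per-anchor InfoNCE terms (used for batchwise loss scoring)."""
    losses, _ = _contrastive_terms(Z, pair_index, tau, None)
    return losses


def self_supervised_loss(Z: np.ndarray, pair_index: np.ndarray, tau: float) -> float:
    """Mean InfoNCE loss over the 2N anchors of a multiviewed batch."""
    return float(per_anchor_self_loss(Z, pair_index, tau).mean())


def self_supervised_loss_grad(
    Z: np.ndarray, pair_index: np.ndarray, tau: float
) -> tuple[float, np.ndarray]:
    losses, dZ = _contrastive_terms(Z, pair_index, tau, None)
    return float(losses.mean()), dZ


def supervised_contrastive_loss(
    Z: np.ndarray, pair_index: np.ndarray, labels: Sequence[str], tau: float
) -> float:
    """Mean supervised contrastive loss; positives = same-label entries ∪ replicate."""
    losses, _ = _contrastive_terms(Z, pair_index, tau, np.asarray(labels))
    return float(losses.mean())


def supervised_contrastive_loss_grad(
    Z: np.ndarray, pair_index: np.ndarray, labels: Sequence[str], tau: float
) -> tuple[float, np.ndarray]:
    losses, dZ = _contrastive_terms(Z, pair_index, tau, np.asarray(labels))
    return float(losses.mean()), dZ


# ---------------------------------------------------------------------------
# encoder + projector model
# ---------------------------------------------------------------------------

class EncoderModel:
    """Encoder f and projector g; latents z = g(f(x)) are unit-normalized."""

    def __init__(self, config: ContrastiveConfig, in_channels: int, image_hw: tuple[int, int]):
        h, w = image_hw
        if h % 4 or w % 4:
            raise ValueError("image height/width must be divisible by 4")
        self.config = config
        self.in_channels = in_channels
        self.image_hw = (h, w)
        self.trained = False
        rng = np.random.default_rng(config.seed)
        flat = 16 * (h // 4) * (w // 4)
        encoder_layers: list[nn.Layer] = [
            nn.Conv2d(in_channels, 8, 3, 1, rng),
            nn.ReLU(),
            nn.AvgPool2(),
            nn.Conv2d(8, 16, 3, 1, rng),
            nn.ReLU(),
            nn.AvgPool2(),
            nn.Flatten(),
            nn.Dense(flat, config.feature_dim, rng),
            nn.ReLU(),
        ]
        projector_layers: list[nn.Layer] = [
            nn.Dense(config.feature_dim, config.feature_dim, rng),
            nn.ReLU(),
            nn.Dense(config.feature_dim, config.projector_dim, rng),
            nn.L2Norm(),
        ]
        self.net = nn.Sequential(encoder_layers + projector_layers)
        self._n_encoder_layers = len(encoder_layers)

    # -- data marshalling ---------------------------------------------------

    def _to_array(self, images) -> np.ndarray:
        if isinstance(images, np.ndarray):
            X = images
        else:
            X = np.stack([rec.pixels for rec in images])  # (M, H, W, C)
            X = np.moveaxis(X, -1, 1)
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4 or X.shape[1] != self.in_channels or X.shape[2:] != self.image_hw:
            raise ValueError(
                f"expected images of shape (M, {self.in_channels}, {self.image_hw[0]}, "
                f"{self.image_hw[1]}), got {X.shape}"
            )
        return X

    def project(self, images, train: bool = False) -> np.ndarray:
        """Latent representations z = g(f(x)), one unit-norm row per image."""
        return self.net.forward(self._to_array(images), train=train)

    def features(self, images) -> np.ndarray:
        """Encoder features f(x) without projection."""
        x = self._to_array(images)
        for layer in self.net.layers[: self._n_encoder_layers]:
            x = layer.forward(x, train=False)
        return x

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        weights = self.net.get_weights()
        np.savez(path.with_suffix(".npz"), *weights)
        sidecar = {
            "config": asdict(self.config),
            "in_channels": self.in_channels,
            "image_hw": list(self.image_hw),
            "trained": self.trained,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "EncoderModel":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        model = cls(
            ContrastiveConfig(**sidecar["config"]),
            sidecar["in_channels"],
            tuple(sidecar["image_hw"]),
        )
        with np.load(path.with_suffix(".npz")) as data:
            model.net.set_weights([data[k] for k in data.files])
        model.trained = sidecar["trained"]
        return model


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _chunk_indices(order: np.ndarray, n: int) -> list[np.ndarray]:
    """Split a permutation into batches of n anchors; a trailing singleton is
    folded into the previous batch (a 2-entry multiview batch needs 2 anchors
    to have any negatives, and a 1-anchor batch has loss identically 0)."""
    chunks = [order[i : i + n] for i in range(0, len(order), n)]
    if len(chunks) > 1 and len(chunks[-1]) == 1:
        chunks[-2] = np.concatenate([chunks[-2], chunks[-1]])
        chunks.pop()
    return chunks


def train_semisupervised(
    records: Sequence[ImageRecord],
    annotations: AnnotationTable,
    config: ContrastiveConfig,
) -> tuple[EncoderModel, pd.DataFrame]:
    """Train the encoder with alternating self-supervised / supervised phases.

    Each epoch runs (A) InfoNCE steps over multiview batches covering the
    full image set, then (B) supervised contrastive steps over batches drawn
    from the annotated images using primary labels, scaled by
    ``supervised_weight``.  With no annotated compounds phase B is skipped
    and the run reduces to pure self-supervised training with an identical
    parameter trajectory for the same seed.  Returns the model and a per-epoch
    loss history (columns ``epoch, self_loss, sup_loss``).
    """
    if not records:
        raise ValueError("no records to train on")
    X = np.moveaxis(np.stack([r.pixels for r in records]), -1, 1).astype(np.float32)
    by_compound = group_by_compound(records)
    model = EncoderModel(config, X.shape[1], X.shape[2:])
    opt = nn.RMSProp(model.net, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)

    labels_by_index: dict[int, str] = {}
    for i, rec in enumerate(records):
        lab = primary_label(annotations, rec.compound_id)
        if lab is not None:
            labels_by_index[i] = lab
    annotated_idx = np.array(sorted(labels_by_index), dtype=int)

    def run_phase(indices: np.ndarray, supervised: bool) -> float:
        order = rng.permutation(indices)
        total, count = 0.0, 0
        for anchors in _chunk_indices(order, config.batch_size):
            batch = build_multiview_batch(
                len(records), by_compound, len(anchors), rng, anchors=anchors,
                labels_by_index=labels_by_index if supervised else None,
            )
            Z = model.net.forward(X[batch.entries], train=True)
            if supervised:
                loss, dZ = supervised_contrastive_loss_grad(
                    Z, batch.pair_index, batch.labels, config.temperature
                )
                dZ = dZ * config.supervised_weight
            else:
                loss, dZ = self_supervised_loss_grad(Z, batch.pair_index, config.temperature)
            model.net.backward(dZ.astype(np.float32))
            opt.step()
            total += loss * len(anchors)
            count += len(anchors)
        return total / max(count, 1)

    history = []
    all_idx = np.arange(len(records))
    for epoch in range(config.max_epochs):
        self_loss = run_phase(all_idx, supervised=False)
        sup_loss = (
            run_phase(annotated_idx, supervised=True) if len(annotated_idx) else np.nan
        )
        history.append({"epoch": epoch, "self_loss": self_loss, "sup_loss": sup_loss})
    model.trained = True
    return model, pd.DataFrame(history)


# ---------------------------------------------------------------------------
# batchwise contrastive-loss scoring
# ---------------------------------------------------------------------------

def batchwise_contrastive_loss(
    model: EncoderModel,
    records: Sequence[ImageRecord],
    batch_size: int = 40,
    seed: int = 0,
    aggregate: str = "min",
    n_rounds: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score each image by its per-anchor InfoNCE term within fixed batches.

    Images are shuffled (seeded) into batches of ``batch_size`` anchors; each
    image is scored, as an anchor, by its per-anchor term of the
    self-supervised loss.  The score depends on which negatives share the
    batch, so with ``n_rounds > 1`` the batching is repeated with fresh
    seeded shuffles and each image's score is the mean over rounds (reduces
    batch-composition sensitivity).  Compound scores aggregate replicate
    scores with ``min`` (default: the most self-consistent replicate) or
    ``mean``.

    Returns ``(image_table, compound_table)``; the compound table is sorted
    ascending by score with ties broken by compound_id.
    """
    if not model.trained:
        raise ValueError("model must be trained before batchwise scoring")
    if aggregate not in {"min", "mean"}:
        raise ValueError("aggregate must be 'min' or 'mean'")
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    by_compound = group_by_compound(records)
    Z_all = model.project(records)  # eval mode, deterministic

    acc = np.zeros(len(records))
    for rnd in range(n_rounds):
        rng = np.random.default_rng([seed, rnd])
        order = rng.permutation(len(records))
        for anchors in _chunk_indices(order, batch_size):
            batch = build_multiview_batch(
                len(records), by_compound, len(anchors), rng, anchors=anchors
            )
            losses = per_anchor_self_loss(
                Z_all[batch.entries], batch.pair_index, model.config.temperature
            )
            acc[anchors] += losses[0::2]  # anchors sit at even positions
    image_df = (
        pd.DataFrame(
            {
                "image_id": [r.image_id for r in records],
                "compound_id": [r.compound_id for r in records],
                "loss": acc / n_rounds,
            }
        )
        .sort_values("image_id")
        .reset_index(drop=True)
    )
    agg_fn = "min" if aggregate == "min" else "mean"
    compound_df = (
        image_df.groupby("compound_id")["loss"]
        .agg(score=agg_fn, n_replicates="size")
        .reset_index()
        .sort_values(["score", "compound_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    return image_df, compound_df
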