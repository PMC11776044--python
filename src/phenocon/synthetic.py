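"""Synthetic Cell-Painting-like image sets with known latent class structure.

The generator emulates the structure of a high-content screen: K latent
phenotype classes, each shifting per-channel image statistics (Gaussian-blob
density/size/amplitude and sinusoidal texture frequency); compounds belonging
to a class, each with its own stable parameter jitter (compound identity);
replicate images per compound spread over synthetic plates/batches with
multiplicative+additive batch shifts; a class-free DMSO control population;
and partial, possibly multilabel, annotation.

Generative model per channel c of a compound's image::

    params(compound)  = base + signal_strength * class_delta[class, c]
                             + compound_jitter
    params(replicate) = (1 - a) * params(compound) + a * params(confounder),
                        a = min(replicate_noise * 3, 1)
    image = baseline + tex_amp * sin(2*pi*freq*(x*cos th + y*sin th)/H + phase)
            + sum_blobs amp * exp(-r^2 / (2*radius^2))
            + N(0, replicate_noise)           # pixel noise, per replicate
    image = clip(gain_batch * image + offset_batch, 0, 1)

``replicate_noise`` models the *consistency of a treatment's phenotype*
across replicate wells.  An inconsistent treatment in a real screen does not
produce arbitrary images — each failed replicate drifts toward some other
phenotype present in the assay (vehicle reversion on failed dosing, other
classes on off-target response), a *different* one per replicate.  The
generator therefore mixes each replicate's parameters toward a freshly drawn
confounder phenotype (random class or control, with its own jitter) by a
fraction proportional to ``replicate_noise``, besides adding pixel noise and
blob-position jitter.  Blob positions and counts come
from a compound-level stream, so with ``replicate_noise = 0`` the replicates
of a compound are identical up to batch effects — the regime a
contrastive-loss ranking should put first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_data import CONTROL_SENTINEL, AnnotationTable, ImageRecord

# per-channel base parameters: baseline, blob rate, blob radius (fraction of H),
# blob amplitude, texture frequency (cycles), texture amplitude
_BASE = dict(baseline=0.25, rate=10.0, radius=0.06, amp=0.45, freq=3.0, tex=0.08)
# scale of the class-driven delta for each parameter at signal_strength = 1
_CLASS_SCALE = dict(baseline=0.05, rate=7.0, radius=0.03, amp=0.20, freq=2.0, tex=0.05)
# compound-identity jitter, as a fraction of the class scale
_COMPOUND_JITTER = 0.3
# mixing fraction toward the confounder phenotype per unit replicate_noise
_REPLICATE_MIX = 3.0


@dataclass
class SynthSpec:
    """Parameters of one synthetic screen; fully determines the dataset given seed."""

    n_classes: int = 10
    n_compounds: int = 80
    replicates_per_compound: int = 4
    image_hw: tuple[int, int] = (48, 48)
    n_channels: int = 5
    signal_strength: float = 1.0
    replicate_noise: float = 0.05
    batch_effect: float = 0.15
    annotation_fraction: float = 0.5
    multilabel_fraction: float = 0.2
    n_controls: int = 8
    n_batches: int = 2
    seed: int = 0
    #: optional cycle of per-compound replicate-noise levels (overrides
    #: ``replicate_noise``); compound i receives level i mod len(levels)
    replicate_noise_levels: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if min(self.n_classes, self.n_compounds, self.replicates_per_compound) < 0:
            raise ValueError("counts must be non-negative")
        if self.annotation_fraction > 0 and self.n_classes == 0:
            raise ValueError("annotation requires n_classes >= 1")
        if self.annotation_fraction > 0 and self.n_compounds < self.n_classes:
            raise ValueError("need n_compounds >= n_classes when annotating")
        for name in ("annotation_fraction", "multilabel_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


def compound_ids(spec: SynthSpec) -> list[str]:
    return [f"cpd_{i:04d}" for i in range(spec.n_compounds)]


def assigned_noise_levels(spec: SynthSpec) -> dict[str, float]:
    """Replicate-noise level of each compound under this spec."""
    ids = compound_ids(spec)
    if spec.replicate_noise_levels is None:
        return {c: spec.replicate_noise for c in ids}
    levels = spec.replicate_noise_levels
    return {c: levels[i % len(levels)] for i, c in enumerate(ids)}


def _class_name(k: int) -> str:
    return f"class_{k:02d}"


def _render_channel(
    hw: tuple[int, int],
    p: Mapping[str, float],
    blob_xy: np.ndarray,
    theta: float,
    phase: float,
    noise: np.ndarray | None,
) -> np.ndarray:
    h, w = hw
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    img = p["baseline"] + p["tex"] * np.sin(
        2 * np.pi * p["freq"] * (xx * np.cos(theta) + yy * np.sin(theta)) / h + phase
    )
    radius = max(p["radius"] * h, 0.75)
    for bx, by in blob_xy:
        d2 = (xx - bx) ** 2 + (yy - by) ** 2
        img += p["amp"] * np.exp(-d2 / (2 * radius**2))
    if noise is not None:
        img = img + noise
    return img


def generate_dataset(
    spec: SynthSpec,
) -> tuple[list[ImageRecord], AnnotationTable, dict[str, str]]:
    """Generate a synthetic screen: image records, annotations, ground truth.

    Returns ``(records, annotations, truth)`` where ``truth`` maps every
    non-control compound to its latent class name.  Deterministic given
    ``spec.seed``: identical specs yield bit-identical pixel data.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_hw
    n_batches = max(1, min(spec.n_batches, max(spec.replicates_per_compound, 1)))
    params_keys = list(_BASE)

    # class-level parameter deltas, one signed direction per class and channel
    class_delta = {
        k: rng.normal(0.0, 1.0, size=(spec.n_channels, len(params_keys)))
        for k in range(spec.n_classes)
    }
    # batch-level gain/offset per channel
    gains = 1.0 + spec.batch_effect * rng.normal(size=(n_batches, spec.n_channels))
    offsets = 0.5 * spec.batch_effect * rng.normal(size=(n_batches, spec.n_channels))

    ids = compound_ids(spec)
    classes = (
        rng.integers(0, spec.n_classes, size=spec.n_compounds)
        if spec.n_classes > 0
        else np.zeros(spec.n_compounds, dtype=int)
    )
    truth = {c: _class_name(int(k)) for c, k in zip(ids, classes)}
    noise_levels = assigned_noise_levels(spec)
    channel_names = [f"ch{i}" for i in range(spec.n_channels)]
    scale_vec = np.array([_CLASS_SCALE[k] for k in params_keys])
    base_vec = np.array([_BASE[k] for k in params_keys])

    records: list[ImageRecord] = []

    def make_images(cid: str, pvec: np.ndarray, comp_rng: np.random.Generator,
                    n_rep: int, rep_noise: float) -> None:
        # compound-level structure shared by all replicates
        thetas = comp_rng.uniform(0, np.pi, size=spec.n_channels)
        phases = comp_rng.uniform(0, 2 * np.pi, size=spec.n_channels)
        blob_sets = []
        for ch in range(spec.n_channels):
            rate = max(float(pvec[ch, params_keys.index("rate")]), 0.0)
            n_blobs = int(comp_rng.poisson(rate))
            blob_sets.append(comp_rng.uniform(0, [w, h], size=(n_blobs, 2)))
        for j in range(n_rep):
            batch = j % n_batches
            # phenotype inconsistency: mix this replicate's parameters toward
            # a freshly drawn confounder phenotype from the same assay
            alpha = min(rep_noise * _REPLICATE_MIX, 1.0)
            if alpha > 0:
                # each failed replicate drifts toward a different confounder:
                # a freshly jittered phenotype of a random class (or control)
                kc = int(comp_rng.integers(-1, spec.n_classes))
                delta_c = class_delta[kc] if kc >= 0 else 0.0
                jitter_c = comp_rng.normal(
                    0, _COMPOUND_JITTER, size=(spec.n_channels, len(params_keys))
                )
                target = base_vec + scale_vec * (
                    spec.signal_strength * delta_c + jitter_c
                )
                pj = (1 - alpha) * pvec + alpha * target
            else:
                pj = pvec
            chans = []
            for ch in range(spec.n_channels):
                p = dict(zip(params_keys, pj[ch]))
                pos = blob_sets[ch]
                if rep_noise > 0 and len(pos):
                    pos = pos + comp_rng.normal(0, rep_noise * 10.0, size=pos.shape)
                noise = (
                    comp_rng.normal(0, rep_noise, size=(h, w)) if rep_noise > 0 else None
                )
                img = _render_channel((h, w), p, pos, thetas[ch], phases[ch], noise)
                img = gains[batch, ch] * img + offsets[batch, ch]
                chans.append(img)
            pixels = np.clip(np.stack(chans, axis=-1), 0.0, 1.0).astype(np.float32)
            records.append(
                ImageRecord(
                    image_id=f"{cid}_r{j}",
                    compound_id=cid,
                    plate_id=f"plate_{batch:02d}",
                    well=f"{cid}",
                    site=j // n_batches + 1,
                    pixels=pixels,
                    channel_names=list(channel_names),
                )
            )

    for i, cid in enumerate(ids):
        k = int(classes[i])
        comp_rng = np.random.default_rng(rng.integers(0, 2**31))
        jitter = comp_rng.normal(0, _COMPOUND_JITTER, size=(spec.n_channels, len(params_keys)))
        delta = class_delta[k] if spec.n_classes > 0 else 0.0
        pvec = base_vec + scale_vec * (spec.signal_strength * delta + jitter)
        make_images(cid, pvec, comp_rng, spec.replicates_per_compound, noise_levels[cid])

    # DMSO controls: class-free background, one image each
    for j in range(spec.n_controls):
        comp_rng = np.random.default_rng(rng.integers(0, 2**31))
        jitter = comp_rng.normal(0, _COMPOUND_JITTER, size=(spec.n_channels, len(params_keys)))
        pvec = base_vec + scale_vec * jitter
        thetas = comp_rng.uniform(0, np.pi, size=spec.n_channels)
        phases = comp_rng.uniform(0, 2 * np.pi, size=spec.n_channels)
        batch = j % n_batches
        chans = []
        for ch in range(spec.n_channels):
            p = dict(zip(params_keys, pvec[ch]))
            rate = max(float(p["rate"]), 0.0)
            pos = comp_rng.uniform(0, [w, h], size=(int(comp_rng.poisson(rate)), 2))
            noise = comp_rng.normal(0, spec.replicate_noise, size=(h, w))
            img = _render_channel((h, w), p, pos, thetas[ch], phases[ch], noise)
            img = gains[batch, ch] * img + offsets[batch, ch]
            chans.append(img)
        pixels = np.clip(np.stack(chans, axis=-1), 0.0, 1.0).astype(np.float32)
        records.append(
            ImageRecord(
                image_id=f"{CONTROL_SENTINEL}_r{j}",
                compound_id=CONTROL_SENTINEL,
                plate_id=f"plate_{batch:02d}",
                well=f"ctrl_{j:03d}",
                site=1,
                pixels=pixels,
                channel_names=list(channel_names),
            )
        )

    # annotations: a seeded subset of compounds receives its true class as
    # first label; a further subset gets one correlated extra label
    ann_rng = np.random.default_rng(spec.seed + 1)
    n_annot = int(round(spec.annotation_fraction * spec.n_compounds))
    annotated = sorted(ann_rng.choice(ids, size=n_annot, replace=False).tolist())
    labels: dict[str, list[str]] = {}
    n_multi = int(round(spec.multilabel_fraction * n_annot))
    multi = set(ann_rng.choice(annotated, size=n_multi, replace=False).tolist()) if n_annot else set()
    for cid in annotated:
        k = int(classes[ids.index(cid)])
        lab = [_class_name(k)]
        if cid in multi and spec.n_classes > 1:
            lab.append(_class_name((k + 1) % spec.n_classes))  # correlated second label
        labels[cid] = lab
    annotations = AnnotationTable(system_name="custom", labels=labels)
    return records, annotations, truth


def generate_embedding_fixture(
    n_pairs: int,
    dim: int,
    label_spec: Mapping[str, object] | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Random unit-norm multiview embedding fixtures for loss oracle tests.

    Entries ``2i`` and ``2i+1`` form pair ``i``.  ``label_spec`` options:
    ``{"n_classes": k}`` assigns pair labels round-robin over k classes;
    ``{"identical_rows": True}`` forces every row to one shared unit vector;
    ``{"distinct_labels": True}`` gives every pair its own label.
    """
    if n_pairs < 1 or dim < 2:
        raise ValueError("need n_pairs >= 1 and dim >= 2")
    label_spec = dict(label_spec or {})
    rng = np.random.default_rng(seed)
    n = 2 * n_pairs
    if label_spec.get("identical_rows"):
        v = rng.normal(size=dim)
        Z = np.tile(v / np.linalg.norm(v), (n, 1))
    else:
        Z = rng.normal(size=(n, dim))
        Z /= np.linalg.norm(Z, axis=1, keepdims=True)
    pair_index = np.arange(n)
    pair_index[0::2] += 1
    pair_index[1::2] -= 1
    labels: np.ndarray | None = None
    if label_spec.get("distinct_labels"):
        labels = np.repeat([f"L{i}" for i in range(n_pairs)], 2)
    elif "n_classes" in label_spec:
        k = int(label_spec["n_classes"])  # type: ignore[arg-type]
        labels = np.repeat([f"L{i % k}" for i in range(n_pairs)], 2)
    return Z, pair_index, labels
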