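"""Image and metadata I/O, channel preprocessing and treatment-level splits.

Images are multi-channel fluorescence fields of view (typically the five
Cell Painting channels) stored as TIFF, one multi-page file or one file per
channel, described by a CSV metadata table.  Annotations map compounds to
ordered lists of bioactivity class labels (MeSH / MoA / target style); the
first label of a compound is its *primary* label.  All train/test splitting
happens at the treatment (compound) level so that no compound ever straddles
a train/test boundary.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from skimage.transform import resize as _skimage_resize

#: compound_id sentinel marking vehicle-control (DMSO) wells
CONTROL_SENTINEL = "DMSO"

#: metadata CSV columns that are always required
METADATA_COLUMNS = ("image_id", "compound_id", "plate_id", "well", "site")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ImageRecord:
    """One microscopy field of view with its plate/well/compound metadata.

    ``pixels`` is an H×W×C array of non-negative intensities; channel order
    follows ``channel_names``.
    """

    image_id: str
    compound_id: str
    plate_id: str
    well: str
    site: int
    pixels: np.ndarray
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3:
            raise ValueError(
                f"pixels for {self.image_id!r} must be H×W×C, got shape {self.pixels.shape}"
            )
        if self.pixels.shape[2] != len(self.channel_names):
            raise ValueError(
                f"{self.image_id!r}: {self.pixels.shape[2]} channels but "
                f"{len(self.channel_names)} channel names"
            )
        if self.site < 1:
            raise ValueError(f"{self.image_id!r}: site must be >= 1")

    @property
    def is_control(self) -> bool:
        return self.compound_id == CONTROL_SENTINEL


@dataclass
class AnnotationTable:
    """Compound → ordered class-label lists for one annotation system.

    Compounds absent from ``labels`` are *unannotated*.  Label order is
    meaningful: the first entry is the primary label used for supervised
    contrastive training and single-label classification.
    """

    system_name: str
    labels: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.system_name not in {"MeSH", "MoA", "target", "custom"}:
            raise ValueError(f"unknown annotation system {self.system_name!r}")

    def is_annotated(self, compound_id: str) -> bool:
        return bool(self.labels.get(compound_id))

    @property
    def annotated_compounds(self) -> list[str]:
        return sorted(c for c, ls in self.labels.items() if ls)

    @property
    def class_vocabulary(self) -> list[str]:
        vocab: set[str] = set()
        for ls in self.labels.values():
            vocab.update(ls)
        return sorted(vocab)

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"compound_id": c, "labels": "|".join(ls)}
            for c, ls in sorted(self.labels.items())
        ]
        pd.DataFrame(rows, columns=["compound_id", "labels"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, system_name: str = "custom") -> "AnnotationTable":
        df = pd.read_csv(path, dtype=str).fillna("")
        labels = {
            row["compound_id"]: [l for l in row["labels"].split("|") if l]
            for _, row in df.iterrows()
        }
        return cls(system_name=system_name, labels=labels)


@dataclass
class SplitPlan:
    """Assignment of annotated compounds to cross-validation folds."""

    fold_count: int
    assignments: dict[str, int]
    train_fraction: float
    seed: int

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction <= 1:
            raise ValueError("train_fraction must be in (0, 1]")
        bad = [f for f in self.assignments.values() if not 0 <= f < self.fold_count]
        if bad:
            raise ValueError(f"fold indices out of range: {sorted(set(bad))}")

    def test_compounds(self, fold: int) -> list[str]:
        return sorted(c for c, f in self.assignments.items() if f == fold)

    def train_compounds(self, fold: int) -> list[str]:
        return sorted(c for c, f in self.assignments.items() if f != fold)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["compound_id", "fold"])
            for c in sorted(self.assignments):
                w.writerow([c, self.assignments[c]])

    @classmethod
    def from_csv(
        cls, path: str | Path, fold_count: int, train_fraction: float = 0.8, seed: int = 0
    ) -> "SplitPlan":
        df = pd.read_csv(path, dtype={"compound_id": str, "fold": int})
        return cls(
            fold_count=fold_count,
            assignments=dict(zip(df["compound_id"], df["fold"])),
            train_fraction=train_fraction,
            seed=seed,
        )


# ---------------------------------------------------------------------------
# image set I/O
# ---------------------------------------------------------------------------

def load_image_set(
    metadata_table_path: str | Path, image_root: str | Path
) -> list[ImageRecord]:
    """Load a set of multi-channel images described by a CSV metadata table.

    The table must carry the columns ``image_id, compound_id, plate_id, well,
    site`` plus either a single ``path`` column (multi-page TIFF, one page
    per channel) or one ``path_<channel>`` column per channel.  Channels are
    stacked in metadata column order; intensities are preserved exactly as
    stored (no rescaling at load time).
    """
    image_root = Path(image_root)
    df = pd.read_csv(metadata_table_path, dtype={c: str for c in METADATA_COLUMNS[:-1]})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata table missing columns: {missing}")

    path_cols = [c for c in df.columns if c == "path" or c.startswith("path_")]
    if not path_cols:
        raise ValueError("metadata table has no 'path' or 'path_<channel>' columns")
    multipage = path_cols == ["path"]
    channel_names = (
        None if multipage else [c.removeprefix("path_") for c in path_cols]
    )

    records: list[ImageRecord] = []
    n_channels: int | None = None
    for _, row in df.iterrows():
        image_id = row["image_id"]
        planes = []
        for col in path_cols:
            p = image_root / row[col]
            if not p.exists():
                raise FileNotFoundError(
                    f"image file missing for image_id={image_id!r}: {p}"
                )
            arr = tifffile.imread(p)
            planes.append(arr)
        if multipage:
            stack = planes[0]
            if stack.ndim == 2:
                stack = stack[None]
            pixels = np.moveaxis(stack, 0, -1)
            names = [f"ch{i}" for i in range(pixels.shape[2])]
        else:
            pixels = np.stack(planes, axis=-1)
            names = list(channel_names)  # type: ignore[arg-type]
        if n_channels is None:
            n_channels = pixels.shape[2]
        elif pixels.shape[2] != n_channels:
            raise ValueError(
                f"inconsistent channel count: {image_id!r} has {pixels.shape[2]}, "
                f"expected {n_channels}"
            )
        records.append(
            ImageRecord(
                image_id=image_id,
                compound_id=row["compound_id"],
                plate_id=row["plate_id"],
                well=row["well"],
                site=int(row["site"]),
                pixels=pixels,
                channel_names=names,
            )
        )
    return records


def write_image_set(
    records: Sequence[ImageRecord], out_dir: str | Path, metadata_name: str = "metadata.csv"
) -> Path:
    """Write records as multi-page TIFFs plus a metadata CSV; returns the CSV path.

    The layout written here is exactly the layout :func:`load_image_set`
    reads, so a write→load round trip reproduces pixel data bit-for-bit.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        rel = Path("images") / f"{rec.image_id}.tiff"
        # pages = channels
        tifffile.imwrite(out_dir / rel, np.moveaxis(rec.pixels, -1, 0))
        rows.append(
            {
                "image_id": rec.image_id,
                "compound_id": rec.compound_id,
                "plate_id": rec.plate_id,
                "well": rec.well,
                "site": rec.site,
                "path": str(rel),
            }
        )
    meta_path = out_dir / metadata_name
    pd.DataFrame(rows).to_csv(meta_path, index=False)
    return meta_path


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def default_rgb_mixing(n_channels: int) -> np.ndarray:
    """Default C×3 channel→RGB mixing: channels partitioned over R/G/B.

    Channels are split into three contiguous groups; channels sharing a band
    are averaged (weights 1/group size).  For C=3 this is the identity.
    """
    if n_channels < 1:
        raise ValueError("need at least one channel")
    mixing = np.zeros((n_channels, 3))
    bounds = np.linspace(0, n_channels, 4).round().astype(int)
    for band in range(3):
        group = range(bounds[band], bounds[band + 1])
        for ch in group:
            mixing[ch, band] = 1.0 / max(len(group), 1)
    return mixing


def convert_channels_to_rgb(record: ImageRecord, mixing: np.ndarray | None = None) -> ImageRecord:
    """Mix C fluorescence channels into 3 RGB bands via a C×3 weight matrix.

    Output pixel = (input pixel vector)ᵀ·mixing, clipped below at 0 and above
    at the input's dtype ceiling (1.0 for floats).  Linear in intensities
    whenever no clipping occurs.
    """
    mixing = default_rgb_mixing(record.pixels.shape[2]) if mixing is None else np.asarray(mixing)
    if mixing.shape != (record.pixels.shape[2], 3):
        raise ValueError(
            f"mixing must be {(record.pixels.shape[2], 3)}, got {mixing.shape}"
        )
    if (mixing < 0).any():
        raise ValueError("mixing weights must be non-negative")
    rgb = record.pixels.astype(np.float64) @ mixing
    hi = 1.0 if np.issubdtype(record.pixels.dtype, np.floating) else float(
        np.iinfo(record.pixels.dtype).max
    )
    rgb = np.clip(rgb, 0.0, hi).astype(np.float32)
    return ImageRecord(
        image_id=record.image_id,
        compound_id=record.compound_id,
        plate_id=record.plate_id,
        well=record.well,
        site=record.site,
        pixels=rgb,
        channel_names=["R", "G", "B"],
    )


def resize_image(record: ImageRecord, target_hw: tuple[int, int] = (224, 224)) -> ImageRecord:
    """Bilinearly resample an image to ``target_hw``; channel count unchanged."""
    th, tw = target_hw
    if th < 1 or tw < 1:
        raise ValueError(f"target size must be positive, got {target_hw}")
    if record.pixels.shape[:2] == (th, tw):
        return record
    out = _skimage_resize(
        record.pixels.astype(np.float64),
        (th, tw, record.pixels.shape[2]),
        order=1,  # bilinear, fixed
        mode="edge",
        anti_aliasing=True,
        preserve_range=True,
    ).astype(np.float32)
    return ImageRecord(
        image_id=record.image_id,
        compound_id=record.compound_id,
        plate_id=record.plate_id,
        well=record.well,
        site=record.site,
        pixels=out,
        channel_names=list(record.channel_names),
    )


def normalize_intensity(record: ImageRecord) -> ImageRecord:
    """Scale intensities to [0, 1] by the per-image maximum (constant images → 0)."""
    px = record.pixels.astype(np.float64)
    mx = px.max()
    px = px / mx if mx > 0 else px
    return ImageRecord(
        image_id=record.image_id,
        compound_id=record.compound_id,
        plate_id=record.plate_id,
        well=record.well,
        site=record.site,
        pixels=px.astype(np.float32),
        channel_names=list(record.channel_names),
    )


def preprocess_records(
    records: Sequence[ImageRecord],
    target_hw: tuple[int, int] | None = None,
    mixing: np.ndarray | None = None,
    to_rgb: bool = True,
    normalize: bool = True,
) -> list[ImageRecord]:
    """Standard preprocessing chain: max-normalize → RGB conversion → resize."""
    out = []
    for rec in records:
        if normalize:
            rec = normalize_intensity(rec)
        if to_rgb and rec.pixels.shape[2] != 3:
            rec = convert_channels_to_rgb(rec, mixing)
        if target_hw is not None:
            rec = resize_image(rec, target_hw)
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# labels and splits
# ---------------------------------------------------------------------------

def primary_label(table: AnnotationTable, compound_id: str) -> str | None:
    """First annotation of a compound; ``None`` when unannotated."""
    labels = table.labels.get(compound_id)
    return labels[0] if labels else None


def group_by_compound(records: Iterable[ImageRecord]) -> dict[str, list[int]]:
    """Map compound_id → indices of its replicate images (input order)."""
    idx: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        idx.setdefault(rec.compound_id, []).append(i)
    return idx


def make_splits(
    table: AnnotationTable,
    records: Sequence[ImageRecord],
    fold_count: int = 5,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> SplitPlan:
    """Partition annotated compounds into CV folds, stratified by primary label.

    Splitting operates on treatments (compounds), never images: all replicates
    of a compound land in one fold.  Classes with at least ``fold_count``
    annotated compounds are stratified; the rest are spread round-robin after
    a seeded shuffle.  Deterministic for a given seed.
    """
    if fold_count < 2:
        raise ValueError("fold_count must be >= 2")
    present = {rec.compound_id for rec in records}
    annotated = [c for c in table.annotated_compounds if c in present]
    if len(annotated) < fold_count:
        raise ValueError(
            f"only {len(annotated)} annotated compounds for {fold_count} folds"
        )
    rng = np.random.default_rng(seed)

    by_class: dict[str, list[str]] = {}
    for c in annotated:
        by_class.setdefault(primary_label(table, c), []).append(c)  # type: ignore[arg-type]

    assignments: dict[str, int] = {}
    leftovers: list[str] = []
    for cls in sorted(by_class):
        members = sorted(by_class[cls])
        rng.shuffle(members)
        if len(members) >= fold_count:
            for i, c in enumerate(members):
                assignments[c] = i % fold_count
        else:
            leftovers.extend(members)
    rng.shuffle(leftovers)
    # continue filling from the emptiest folds so sizes stay balanced
    counts = np.bincount(list(assignments.values()), minlength=fold_count)
    for c in leftovers:
        fold = int(np.argmin(counts))
        assignments[c] = fold
        counts[fold] += 1
    return SplitPlan(
        fold_count=fold_count,
        assignments=assignments,
        train_fraction=train_fraction,
        seed=seed,
    )
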