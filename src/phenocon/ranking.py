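"""Contrastive-loss ranking of unannotated compounds with class predictions.

Unannotated (non-control) compounds are scored by batchwise self-supervised
contrastive loss — low loss marks treatments whose replicates map to
self-consistent latents — and the lowest-loss compounds are annotated de novo
by tallying single-label classifier predictions over all their replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .contrastive import EncoderModel, batchwise_contrastive_loss
from .downstream import EmbeddingMatrix, TrainedClassifier, extract_embeddings, predict_compound_classes
from .io_data import AnnotationTable, ImageRecord


@dataclass
class RankedPrediction:
    """One ranked unannotated compound with its top predicted classes."""

    compound_id: str
    score: float
    rank: int
    top_classes: list[tuple[str, int]]
    n_replicates: int


def rank_unannotated(
    model: EncoderModel,
    classifier: TrainedClassifier,
    records: Sequence[ImageRecord],
    annotations: AnnotationTable,
    top_n: int = 10,
    top_k: int = 3,
    aggregate: str = "min",
    batch_size: int = 40,
    seed: int = 0,
    n_rounds: int = 1,
) -> list[RankedPrediction]:
    """Rank unannotated compounds by aggregated batchwise contrastive loss.

    Controls and annotated compounds are excluded; the ``top_n`` compounds
    with the lowest aggregated loss (``min`` over replicates by default,
    ``mean`` available) are returned with their ``top_k`` most frequently
    predicted classes across all replicates.  Deterministic given the seed.
    """
    unannotated = [
        r
        for r in records
        if not r.is_control and not annotations.is_annotated(r.compound_id)
    ]
    if not unannotated:
        raise ValueError("no unannotated non-control compounds to rank")
    _, compound_df = batchwise_contrastive_loss(
        model, unannotated, batch_size=batch_size, seed=seed, aggregate=aggregate,
        n_rounds=n_rounds,
    )
    emb = extract_embeddings(model, unannotated)
    out: list[RankedPrediction] = []
    for rank, row in enumerate(compound_df.head(top_n).itertuples(), start=1):
        reps = emb.rows_for_compound(row.compound_id)
        out.append(
            RankedPrediction(
                compound_id=row.compound_id,
                score=float(row.score),
                rank=rank,
                top_classes=predict_compound_classes(classifier, reps, top_k=top_k),
                n_replicates=int(row.n_replicates),
            )
        )
    return out


def ranking_table(ranked: Sequence[RankedPrediction]) -> pd.DataFrame:
    """Flat CSV-ready view of a ranking report."""
    rows = []
    for r in ranked:
        rows.append(
            {
                "rank": r.rank,
                "compound_id": r.compound_id,
                "score": r.score,
                "n_replicates": r.n_replicates,
                "top_classes": "|".join(f"{c}:{n}" for c, n in r.top_classes),
            }
        )
    return pd.DataFrame(rows)


def write_ranking_report(ranked: Sequence[RankedPrediction], csv_path: str | Path) -> None:
    ranking_table(ranked).to_csv(csv_path, index=False, float_format="%.8g")
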