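"""Per-contig embeddings from the trained encoder, and their reduction.

A contig longer than one model segment is embedded as the unweighted mean of
its segments' final-layer [CLS] vectors; the resulting N x hidden matrix is
then projected to a small dimension (default 24) with UMAP before feature
fusion.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mlm import ModelCheckpoint
from .tokenizer import TokenizedSegment

DEFAULT_REDUCED_DIM = 24


@dataclass
class EmbeddingMatrix:
    contig_ids: list[str]
    vectors: np.ndarray  # (N, d)
    d_meta: str = "encoder"  # "encoder" (raw width) or "reduced"

    def __post_init__(self) -> None:
        if len(self.contig_ids) != len(self.vectors):
            raise ValueError("row count must match contig count")
        if not np.isfinite(self.vectors).all():
            raise ValueError("embedding matrix contains non-finite values")

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.vectors, index=self.contig_ids)
        df.columns = [f"dim_{j}" for j in range(self.vectors.shape[1])]
        df.to_csv(path, sep="\t", index_label="contig_id")


def embed_contig(checkpoint: ModelCheckpoint, segments: Sequence[TokenizedSegment]) -> np.ndarray:
    """One contig's vector: mean of its segments' final-layer [CLS] vectors."""
    if not segments:
        raise ValueError("contig has no segments")
    ids = {s.contig_id for s in segments}
    if len(ids) != 1:
        raise ValueError(f"segments span multiple contigs: {sorted(ids)}")
    token_ids = np.stack([s.token_ids for s in segments])
    masks = np.stack([s.attention_flags for s in segments])
    cls = checkpoint.encoder.cls_vectors(token_ids, masks)
    return cls.mean(axis=0)


def embed_contigs(
    checkpoint: ModelCheckpoint,
    segments_by_contig: Mapping[str, Sequence[TokenizedSegment]],
    batch_size: int = 64,
) -> EmbeddingMatrix:
    """Embed every contig, batching segment forward passes across contigs."""
    contig_ids = list(segments_by_contig)
    flat: list[TokenizedSegment] = []
    owner: list[int] = []
    for row, cid in enumerate(contig_ids):
        segs = segments_by_contig[cid]
        if not segs:
            raise ValueError(f"contig {cid!r} has no segments")
        flat.extend(segs)
        owner.extend([row] * len(segs))

    d = checkpoint.encoder.config.hidden_size
    sums = np.zeros((len(contig_ids), d))
    counts = np.zeros(len(contig_ids))
    for start in range(0, len(flat), batch_size):
        chunk = flat[start : start + batch_size]
        ids = np.stack([s.token_ids for s in chunk])
        masks = np.stack([s.attention_flags for s in chunk])
        cls = checkpoint.encoder.cls_vectors(ids, masks)
        for j, row in enumerate(owner[start : start + batch_size]):
            sums[row] += cls[j]
            counts[row] += 1
    return EmbeddingMatrix(contig_ids=contig_ids, vectors=sums / counts[:, None])


def reduce_embeddings(
    emb: EmbeddingMatrix, target_dim: int = DEFAULT_REDUCED_DIM, seed: int = 0
) -> EmbeddingMatrix:
    """Project embeddings to ``target_dim`` with UMAP (fixed seed).

    UMAP's other knobs stay at the algorithm's common defaults
    (n_neighbors=15, min_dist=0.1, Euclidean).
    """
    n = len(emb.vectors)
    if target_dim < 2:
        raise ValueError("target_dim must be >= 2")
    if n <= target_dim:
        raise ValueError(
            f"need more rows ({n}) than target_dim ({target_dim}); pick a smaller target_dim"
        )
    import umap  # deferred: heavy import

    reducer = umap.UMAP(
        n_components=target_dim,
        n_neighbors=15,
        min_dist=0.1,
        metric="euclidean",
        random_state=seed,
    )
    reduced = np.asarray(reducer.fit_transform(emb.vectors), dtype=np.float64)
    return EmbeddingMatrix(contig_ids=list(emb.contig_ids), vectors=reduced, d_meta="reduced")
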