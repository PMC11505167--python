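"""End-to-end binning workflow.

contigs (FASTA) -> length filter -> two feature branches:
  (a) 4-mer tokenization -> span-MLM pre-training -> [CLS] mean-pool per
      contig -> UMAP to c dims (default 24);
  (b) canonical TNF (136 cols) -> NMF of V = T^T at rank s (default 10)
      -> per-contig coefficients H^T;
then column-wise fusion into an N x (c+s) matrix (default N x 34), adaptive
DBSCAN clustering, bin TSV output and, when a ground truth is supplied,
evaluation. Every stage writes its artifact into the work directory and a
manifest records parameters, seeds and file hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cluster import (
    DEFAULT_KDIST_K, DEFAULT_MINPTS_GRID, DEFAULT_N_TREES, BinningResult, cluster,
)
from .embed import DEFAULT_REDUCED_DIM, EmbeddingMatrix, embed_contigs, reduce_embeddings
from .evaluate import EvalReport, evaluate
from .io import GroundTruth, read_contigs, write_bins
from .mlm import MLMConfig, ModelCheckpoint, pretrain
from .nmf import NMFFactors, nmf_decompose
from .tnf import TNFMatrix, tnf_matrix
from .tokenizer import DEFAULT_SEGMENT_LENGTH, build_vocabulary, tokenize_contig

logger = logging.getLogger("tetrabin")

FEATURE_MODES = ("TNF", "Dec_TNF", "embedding", "embedding+Dec_TNF")


@dataclass
class FeatureMatrix:
    """Fused clustering input: reduced-embedding block then NMF block."""

    contig_ids: list[str]
    values: np.ndarray
    mode: str = "embedding+Dec_TNF"

    @property
    def width(self) -> int:
        return int(self.values.shape[1])


@dataclass
class PipelineConfig:
    """One configuration for the whole run.

    The encoder settings are the desk profile (tiny, CPU-trainable); the
    feature dimensions and clustering settings are the method's defaults
    (c=24, s=10, n_trees=15, MinPts grid {5,10,15,20,25}).
    """

    min_length: int = 2000
    segment_length: int = DEFAULT_SEGMENT_LENGTH
    mlm: MLMConfig = field(default_factory=lambda: MLMConfig(epochs=2, batch_size=16))
    pretrain_max_segments: int | None = 512  # subsample cap for desk-scale training
    target_dim: int = DEFAULT_REDUCED_DIM  # c
    nmf_rank: int = 10  # s
    nmf_max_iter: int = 200
    nmf_tol: float = 1e-4
    kdist_k: int = DEFAULT_KDIST_K
    n_trees: int = DEFAULT_N_TREES
    minpts_grid: tuple[int, ...] = DEFAULT_MINPTS_GRID
    eps: float | None = None  # manual override of knee detection
    exact_neighbors: bool = False
    mode: str = "embedding+Dec_TNF"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in FEATURE_MODES:
            raise ValueError(f"mode must be one of {FEATURE_MODES}, got {self.mode!r}")


def assemble_features(
    emb_reduced: EmbeddingMatrix | None,
    nmf_coefficients: tuple[list[str], np.ndarray] | None,
    mode: str = "embedding+Dec_TNF",
    tnf: TNFMatrix | None = None,
) -> FeatureMatrix:
    """Build the clustering input for one feature mode.

    ``nmf_coefficients`` is (contig_ids, H^T). In the fused mode the
    embedding block comes first, then the NMF coefficient block, width c+s.
    """
    if mode not in FEATURE_MODES:
        raise ValueError(f"unknown feature mode {mode!r}")
    if mode == "TNF":
        if tnf is None:
            raise ValueError("mode 'TNF' needs the TNF matrix")
        return FeatureMatrix(list(tnf.contig_ids), tnf.values.copy(), mode)
    if mode == "Dec_TNF":
        if nmf_coefficients is None:
            raise ValueError("mode 'Dec_TNF' needs the NMF coefficients")
        ids, H_T = nmf_coefficients
        return FeatureMatrix(list(ids), np.asarray(H_T, dtype=np.float64).copy(), mode)
    if mode == "embedding":
        if emb_reduced is None:
            raise ValueError("mode 'embedding' needs the reduced embeddings")
        return FeatureMatrix(list(emb_reduced.contig_ids), emb_reduced.vectors.copy(), mode)

    if emb_reduced is None or nmf_coefficients is None:
        raise ValueError("fused mode needs both feature blocks")
    ids, H_T = nmf_coefficients
    if list(emb_reduced.contig_ids) != list(ids):
        first = next(
            (i for i, (a, b) in enumerate(zip(emb_reduced.contig_ids, ids)) if a != b),
            min(len(ids), len(emb_reduced.contig_ids)),
        )
        raise ValueError(f"contig id mismatch between feature blocks at row {first}")
    fused = np.hstack([emb_reduced.vectors, np.asarray(H_T, dtype=np.float64)])
    return FeatureMatrix(list(ids), fused, mode)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class PipelineResult:
    features: FeatureMatrix
    binning: BinningResult
    checkpoint: ModelCheckpoint | None
    tnf: TNFMatrix
    nmf: NMFFactors | None
    embeddings: EmbeddingMatrix | None
    report: EvalReport | None
    manifest_path: Path


def run_all(
    fasta_path: str | Path,
    work_dir: str | Path,
    config: PipelineConfig | None = None,
    truth: GroundTruth | None = None,
    reuse_checkpoint: bool = True,
) -> PipelineResult:
    """Execute the full workflow, writing every stage artifact to ``work_dir``."""
    config = config or PipelineConfig()
    work_dir = Path(work_dir)
    work_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    logger.info("reading contigs from %s (min length %d)", fasta_path, config.min_length)
    contigs = read_contigs(fasta_path, min_length=config.min_length)
    if not contigs:
        raise RuntimeError("stage read_contigs: no contigs survive the length filter")
    contig_ids = [c.id for c in contigs]
    lengths = {c.id: c.length for c in contigs}

    needs_embedding = config.mode in ("embedding", "embedding+Dec_TNF")
    needs_nmf = config.mode in ("Dec_TNF", "embedding+Dec_TNF")

    # ---- composition branch -------------------------------------------------
    logger.info("computing canonical TNF for %d contigs", len(contigs))
    tnf = tnf_matrix(contigs)
    tnf.to_tsv(work_dir / "tnf.tsv")

    factors = None
    nmf_block = None
    if needs_nmf:
        logger.info("NMF of the 136 x %d transposed TNF at rank %d", len(contigs), config.nmf_rank)
        factors = nmf_decompose(
            tnf.values.T, k=config.nmf_rank,
            max_iter=config.nmf_max_iter, tol=config.nmf_tol, seed=config.seed,
        )
        nmf_block = (tnf.contig_ids, factors.coefficients)
        pd.DataFrame(
            factors.coefficients, index=tnf.contig_ids,
            columns=[f"nmf_{j}" for j in range(config.nmf_rank)],
        ).to_csv(work_dir / "nmf_coefficients.tsv", sep="\t", index_label="contig_id")

    # ---- embedding branch ---------------------------------------------------
    checkpoint = None
    reduced = None
    if needs_embedding:
        vocab = build_vocabulary()
        logger.info("tokenizing %d contigs into %d-length segments", len(contigs), config.segment_length)
        segments_by_contig = {
            c.id: tokenize_contig(c.sequence, c.id, vocab, config.segment_length)
            for c in contigs
        }
        ckpt_dir = work_dir / "checkpoint"
        if reuse_checkpoint and (ckpt_dir / "weights.npz").exists():
            logger.info("loading cached checkpoint from %s", ckpt_dir)
            checkpoint = ModelCheckpoint.load(ckpt_dir)
        else:
            corpus = [s for segs in segments_by_contig.values() for s in segs]
            if config.pretrain_max_segments and len(corpus) > config.pretrain_max_segments:
                pick = rng.choice(len(corpus), size=config.pretrain_max_segments, replace=False)
                corpus = [corpus[i] for i in sorted(pick)]
            mlm_config = MLMConfig(**{**asdict(config.mlm), "seed": config.seed})
            logger.info("pre-training span-MLM on %d segments (%d epochs)", len(corpus), mlm_config.epochs)
            checkpoint = pretrain(corpus, vocab, mlm_config, progress=True)
            checkpoint.save(ckpt_dir)
        logger.info("embedding contigs ([CLS] mean-pooling)")
        embeddings = embed_contigs(checkpoint, segments_by_contig)
        embeddings.to_tsv(work_dir / "embeddings_raw.tsv")
        logger.info("reducing embeddings to %d dims with UMAP", config.target_dim)
        reduced = reduce_embeddings(embeddings, target_dim=config.target_dim, seed=config.seed)
        reduced.to_tsv(work_dir / "embeddings_reduced.tsv")
    else:
        embeddings = None

    # ---- fusion and clustering ----------------------------------------------
    features = assemble_features(reduced, nmf_block, mode=config.mode, tnf=tnf)
    logger.info("clustering %d x %d feature matrix (mode %s)", len(features.contig_ids),
                features.width, config.mode)
    binning = cluster(
        features.values,
        contig_ids=features.contig_ids,
        k=config.kdist_k,
        n_trees=config.n_trees,
        grid=config.minpts_grid,
        eps=config.eps,
        seed=config.seed,
        exact=config.exact_neighbors,
    )
    write_bins(binning.assignments, work_dir / "bins.tsv")
    logger.info("found %d bins (%d noise contigs)", binning.n_bins,
                int((binning.labels == -1).sum()))

    report = None
    if truth is not None:
        report = evaluate(binning, truth, contig_lengths=lengths)
        report.to_tsv(work_dir / "evaluation.tsv")
        logger.info("evaluation:\n%s", report.summary())

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "n_contigs": len(contig_ids),
        "feature_width": features.width,
        "n_bins": binning.n_bins,
        "cluster_params": {
            "eps": binning.params.eps, "min_pts": binning.params.min_pts,
            "quality": binning.quality,
        },
        "artifacts": {
            p.name: _sha256(p)
            for p in sorted(work_dir.glob("*.tsv"))
        },
    }
    manifest_path = work_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))

    return PipelineResult(
        features=features, binning=binning, checkpoint=checkpoint, tnf=tnf,
        nmf=factors, embeddings=embeddings, report=report, manifest_path=manifest_path,
    )


def mode_sweep(
    result: PipelineResult,
    truth: GroundTruth,
    contig_lengths: Mapping[str, int],
    config: PipelineConfig | None = None,
    modes: Sequence[str] = FEATURE_MODES,
) -> dict[str, EvalReport]:
    """Re-cluster each feature mode from a finished run's cached blocks.

    The expensive stages (pre-training, embedding, NMF) are reused; only
    feature assembly, clustering and evaluation run per mode, giving four
    directly comparable reports. A mode whose density structure defeats the
    adaptive parameter search is scored as all-noise rather than dropped.
    """
    config = config or PipelineConfig()
    nmf_block = None
    if result.nmf is not None:
        nmf_block = (result.tnf.contig_ids, result.nmf.coefficients)
    reduced_block = None
    if result.features.mode in ("embedding", "embedding+Dec_TNF"):
        # reduced embeddings are the leading block of the fused matrix
        c = result.features.width - (result.nmf.k if result.nmf is not None else 0) \
            if result.features.mode == "embedding+Dec_TNF" else result.features.width
        reduced_block = EmbeddingMatrix(
            contig_ids=list(result.features.contig_ids),
            vectors=result.features.values[:, :c].copy(),
            d_meta="reduced",
        )

    reports: dict[str, EvalReport] = {}
    for mode in modes:
        features = assemble_features(reduced_block, nmf_block, mode=mode, tnf=result.tnf)
        try:
            binning = cluster(
                features.values, contig_ids=features.contig_ids,
                k=config.kdist_k, n_trees=config.n_trees, grid=config.minpts_grid,
                seed=config.seed, exact=config.exact_neighbors,
            )
        except ValueError as exc:
            logger.warning("mode %s: clustering degenerate (%s); scoring as all-noise", mode, exc)
            binning = BinningResult(
                contig_ids=list(features.contig_ids),
                labels=np.full(len(features.contig_ids), -1, dtype=np.int64),
            )
        reports[mode] = evaluate(binning, truth, contig_lengths=contig_lengths)
    return reports
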