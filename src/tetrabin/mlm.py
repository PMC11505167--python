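"""Span-masked language-model pre-training over 4-mer token segments.

Instead of masking isolated tokens, contiguous spans of k-mers are hidden:
overlapping windows make any single 4-mer trivially recoverable from its
neighbours, so single-token masking teaches almost nothing. Span lengths are
drawn from a multi-scale set (default {1, 2, 4}); 15% of content tokens are
covered per segment, and each span is processed by the classic 80/10/10 rule
(replace with [MASK] / replace with random 4-mers / keep unchanged), with
the model trained by cross-entropy to restore the original tokens at all
in-span positions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .encoder import AdamW, EncoderConfig, TransformerEncoder
from .tokenizer import TokenizedSegment, Vocabulary


@dataclass(frozen=True)
class MLMConfig:
    """Hyperparameters of the masking objective and the encoder.

    The encoder defaults are desk-scale (2 layers, width 64): the masking
    mechanism, not model scale, is what the pipeline depends on. The
    optimizer defaults (batch 64, lr 2e-5, AdamW, 10 epochs) match standard
    BERT-style pre-training practice for this task.
    """

    layers: int = 2
    hidden_size: int = 64
    attention_heads: int = 2
    mask_rate: float = 0.15
    branch_probs: tuple[float, float, float] = (0.8, 0.1, 0.1)
    scales: tuple[int, ...] = (1, 2, 4)
    batch_size: int = 64
    learning_rate: float = 2e-5
    weight_decay: float = 0.01
    epochs: int = 10
    warmup_steps: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.mask_rate < 1.0):
            raise ValueError(f"mask_rate must be in (0,1), got {self.mask_rate}")
        if abs(sum(self.branch_probs) - 1.0) > 1e-9:
            raise ValueError(f"branch_probs must sum to 1, got {self.branch_probs}")
        if not self.scales or any(s < 1 for s in self.scales):
            raise ValueError(f"scales must be non-empty positive ints, got {self.scales}")


BRANCHES = ("mask", "random", "keep")


@dataclass
class MaskingPlan:
    """Where and how one segment is masked.

    ``spans`` is a list of (positions, branch) pairs; positions are absolute
    indices into the segment. ``target_positions``/``target_ids`` cover every
    in-span position regardless of branch.
    """

    spans: list[tuple[np.ndarray, str]]
    target_positions: np.ndarray
    target_ids: np.ndarray

    @property
    def n_targets(self) -> int:
        return int(self.target_positions.size)


def plan_masking(
    segment: TokenizedSegment, config: MLMConfig, rng: np.random.Generator, vocab: Vocabulary
) -> MaskingPlan:
    """Draw a multi-scale span-masking plan for one segment.

    Span centers are drawn uniformly without replacement from content
    positions ([UNK] positions are never centers); each accepted center gets
    a span length uniform over ``config.scales``, centered and clipped to the
    content region. Candidates overlapping an accepted span are rejected.
    Drawing stops when the covered token count first reaches
    ``mask_rate * n_content``.
    """
    content = segment.content_slice
    n_content = segment.n_content
    if n_content <= 0:
        raise ValueError(f"segment of contig {segment.contig_id!r} has no content tokens")

    lo, hi = content.start, content.stop  # content positions are [lo, hi)
    eligible = np.arange(lo, hi)
    eligible = eligible[segment.token_ids[eligible] != vocab.unk_id]
    budget = config.mask_rate * n_content

    covered = np.zeros(hi, dtype=bool)
    spans: list[tuple[np.ndarray, str]] = []
    n_covered = 0
    scales = np.asarray(config.scales)
    for center in rng.permutation(eligible):
        if n_covered >= budget:
            break
        length = int(scales[rng.integers(len(scales))])
        start = max(lo, center - (length - 1) // 2)
        stop = min(hi, start + length)
        if covered[start:stop].any():
            continue  # overlapping candidate rejected; next draw
        positions = np.arange(start, stop)
        branch = BRANCHES[rng.choice(3, p=config.branch_probs)]
        covered[start:stop] = True
        n_covered += positions.size
        spans.append((positions, branch))

    if spans:
        target_positions = np.concatenate([pos for pos, _ in spans])
        target_positions.sort()
    else:
        target_positions = np.empty(0, dtype=np.int64)
    return MaskingPlan(
        spans=spans,
        target_positions=target_positions,
        target_ids=segment.token_ids[target_positions].astype(np.int64),
    )


def apply_plan(
    segment: TokenizedSegment, plan: MaskingPlan, rng: np.random.Generator, vocab: Vocabulary
) -> np.ndarray:
    """Produce the corrupted input ids for one segment under a plan."""
    ids = segment.token_ids.copy()
    for positions, branch in plan.spans:
        if branch == "mask":
            ids[positions] = vocab.mask_id
        elif branch == "random":
            ids[positions] = rng.integers(0, vocab.n_kmers, size=positions.size)
        # "keep": unchanged
    return ids


@dataclass
class ModelCheckpoint:
    """Trained encoder weights plus everything needed to reuse them."""

    encoder: TransformerEncoder
    vocab: Vocabulary
    config: MLMConfig
    loss_history: list[float] = field(default_factory=list)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz", **self.encoder.params)
        self.vocab.save(directory / "vocab.tsv")
        snapshot = {
            "mlm_config": asdict(self.config),
            "encoder_config": asdict(self.encoder.config),
        }
        (directory / "config.json").write_text(json.dumps(snapshot, indent=2))
        with open(directory / "loss.csv", "w") as fh:
            fh.write("epoch,mean_loss\n")
            for epoch, loss in enumerate(self.loss_history, start=1):
                fh.write(f"{epoch},{loss:.6f}\n")

    @classmethod
    def load(cls, directory: str | Path) -> "ModelCheckpoint":
        directory = Path(directory)
        snapshot = json.loads((directory / "config.json").read_text())
        mlm_config = MLMConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in snapshot["mlm_config"].items()
        })
        enc_config = EncoderConfig(**snapshot["encoder_config"])
        encoder = TransformerEncoder(enc_config, seed=mlm_config.seed)
        with np.load(directory / "weights.npz") as data:
            encoder.params = {k: data[k] for k in data.files}
        vocab = Vocabulary.load(directory / "vocab.tsv")
        history: list[float] = []
        loss_path = directory / "loss.csv"
        if loss_path.exists():
            for line in loss_path.read_text().splitlines()[1:]:
                history.append(float(line.split(",")[1]))
        return cls(encoder=encoder, vocab=vocab, config=mlm_config, loss_history=history)


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def pretrain(
    corpus: Sequence[TokenizedSegment],
    vocab: Vocabulary,
    config: MLMConfig | None = None,
    progress: bool = False,
) -> ModelCheckpoint:
    """Pre-train the encoder on a segment corpus with the span-MLM objective.

    Loss is cross-entropy over exactly the in-span positions of each
    segment's fresh masking plan (plans are redrawn every epoch). Returns a
    checkpoint carrying per-epoch mean loss; with a fixed seed the loss
    trajectory is reproducible.
    """
    if not corpus:
        raise ValueError("empty training corpus")
    config = config or MLMConfig()
    seg_len = int(corpus[0].token_ids.size)
    enc_config = EncoderConfig(
        vocab_size=len(vocab),
        max_len=seg_len,
        layers=config.layers,
        hidden_size=config.hidden_size,
        attention_heads=config.attention_heads,
    )
    encoder = TransformerEncoder(enc_config, seed=config.seed)
    optimizer = AdamW(
        encoder.params, lr=config.learning_rate, weight_decay=config.weight_decay
    )
    rng = np.random.default_rng(config.seed)

    all_ids = np.stack([s.token_ids for s in corpus])
    all_masks = np.stack([s.attention_flags for s in corpus])

    history: list[float] = []
    for epoch in range(config.epochs):
        losses: list[float] = []
        for batch_idx in _batches(len(corpus), config.batch_size, rng):
            batch_rows, batch_cols, batch_targets = [], [], []
            corrupt = all_ids[batch_idx].copy()
            for row, seg_i in enumerate(batch_idx):
                seg = corpus[seg_i]
                plan = plan_masking(seg, config, rng, vocab)
                if plan.n_targets == 0:
                    continue
                corrupt[row] = apply_plan(seg, plan, rng, vocab)
                batch_rows.append(np.full(plan.n_targets, row))
                batch_cols.append(plan.target_positions)
                batch_targets.append(plan.target_ids)
            if not batch_rows:
                continue
            positions = (np.concatenate(batch_rows), np.concatenate(batch_cols))
            targets = np.concatenate(batch_targets)
            loss, grads = encoder.loss_and_grads(
                corrupt, all_masks[batch_idx], positions, targets
            )
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged (loss={loss}) at epoch {epoch + 1}"
                )
            if config.warmup_steps and optimizer.t < config.warmup_steps:
                optimizer.lr = config.learning_rate * (optimizer.t + 1) / config.warmup_steps
            else:
                optimizer.lr = config.learning_rate
            optimizer.step(encoder.params, grads)
            losses.append(loss)
        mean_loss = float(np.mean(losses)) if losses else float("nan")
        history.append(mean_loss)
        if progress:
            print(f"epoch {epoch + 1}/{config.epochs}: mean masked-LM loss {mean_loss:.4f}")

    return ModelCheckpoint(encoder=encoder, vocab=vocab, config=config, loss_history=history)
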