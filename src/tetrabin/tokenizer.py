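"""k-mer tokenization of contigs for the masked-language-model encoder.

A contig is turned into overlapping 4-mers by a stride-1 sliding window
(``ATTCGA`` -> ``ATTC, TTCG, TCGA``), mapped to integer ids through a fixed
261-entry vocabulary (256 4-mers + 5 special tokens), and packed into
fixed-length model segments of the form ``[CLS] tokens... [SEP] [PAD]...``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Sequence

import numpy as np

BASES = "ACGT"
CLS, SEP, PAD, MASK, UNK = "[CLS]", "[SEP]", "[PAD]", "[MASK]", "[UNK]"
SPECIAL_TOKENS = (CLS, SEP, PAD, MASK, UNK)

DEFAULT_SEGMENT_LENGTH = 512


@dataclass(frozen=True)
class Vocabulary:
    """Fixed token inventory: all k-mers in lexicographic order, then specials."""

    k: int
    token_to_id: dict[str, int]

    @property
    def id_to_token(self) -> list[str]:
        inv = [""] * len(self.token_to_id)
        for tok, i in self.token_to_id.items():
            inv[i] = tok
        return inv

    def __len__(self) -> int:
        return len(self.token_to_id)

    @property
    def n_kmers(self) -> int:
        return len(BASES) ** self.k

    # special-token ids, in vocabulary order after the k-mer block
    @property
    def cls_id(self) -> int:
        return self.token_to_id[CLS]

    @property
    def sep_id(self) -> int:
        return self.token_to_id[SEP]

    @property
    def pad_id(self) -> int:
        return self.token_to_id[PAD]

    @property
    def mask_id(self) -> int:
        return self.token_to_id[MASK]

    @property
    def unk_id(self) -> int:
        return self.token_to_id[UNK]

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for tok, i in sorted(self.token_to_id.items(), key=lambda kv: kv[1]):
                fh.write(f"{tok}\t{i}\n")

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        mapping: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                tok, i = line.rstrip("\n").split("\t")
                mapping[tok] = int(i)
        n_kmers = sum(1 for t in mapping if not t.startswith("["))
        k = round(np.log(n_kmers) / np.log(4))
        return cls(k=k, token_to_id=mapping)


def build_vocabulary(k: int = 4) -> Vocabulary:
    """Build the deterministic vocabulary: 4**k k-mers + [CLS],[SEP],[PAD],[MASK],[UNK].

    For k=4 this is the standard 261-entry inventory (256 + 5).
    """
    tokens = ["".join(p) for p in product(BASES, repeat=k)]  # lexicographic
    tokens.extend(SPECIAL_TOKENS)
    return Vocabulary(k=k, token_to_id={tok: i for i, tok in enumerate(tokens)})


@dataclass(frozen=True)
class TokenizedSegment:
    """One model input: ``[CLS] content [SEP]`` right-padded to a fixed length.

    ``attention_flags`` is 1 over real tokens ([CLS], content, [SEP]) and 0
    over the [PAD] suffix.
    """

    contig_id: str
    token_ids: np.ndarray  # (segment_length,) int32
    attention_flags: np.ndarray  # (segment_length,) uint8

    @property
    def content_slice(self) -> slice:
        """Positions holding real content tokens (excludes [CLS]/[SEP]/[PAD])."""
        n_real = int(self.attention_flags.sum())
        return slice(1, n_real - 1)

    @property
    def n_content(self) -> int:
        return int(self.attention_flags.sum()) - 2


def kmerize(sequence: str, vocab: Vocabulary, k: int = 4) -> np.ndarray:
    """Sliding-window k-merization with stride 1, returning token ids.

    A window containing any non-ACGT base maps to [UNK]; everything else maps
    to its literal k-mer id. A sequence of length L yields L-k+1 tokens.
    """
    if len(sequence) < k:
        raise ValueError(f"sequence of length {len(sequence)} is shorter than k={k}")
    # base codes: A,C,G,T -> 0..3; anything else -> -1 (poisons its windows)
    codes = np.full(len(sequence), -1, dtype=np.int64)
    for value, base in enumerate(BASES):
        codes[np.frombuffer(sequence.encode(), dtype=np.uint8) == ord(base)] = value
    n = len(sequence) - k + 1
    ids = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for offset in range(k):
        window = codes[offset : offset + n]
        ids = ids * 4 + np.maximum(window, 0)
        bad |= window < 0
    ids[bad] = vocab.unk_id
    return ids.astype(np.int32)


def segmentize(
    token_ids: Sequence[int] | np.ndarray,
    contig_id: str,
    vocab: Vocabulary,
    segment_length: int = DEFAULT_SEGMENT_LENGTH,
) -> list[TokenizedSegment]:
    """Pack a token stream into consecutive non-overlapping model segments.

    Each segment holds at most ``segment_length - 2`` content tokens wrapped
    as ``[CLS] chunk [SEP]`` and right-padded with [PAD]; the number of
    segments is ``ceil(n_tokens / (segment_length - 2))``.
    """
    if segment_length < 8:
        raise ValueError(f"segment_length must be >= 8, got {segment_length}")
    token_ids = np.asarray(token_ids, dtype=np.int32)
    if token_ids.size == 0:
        raise ValueError(f"empty token stream for contig {contig_id!r}")

    capacity = segment_length - 2
    segments: list[TokenizedSegment] = []
    for start in range(0, token_ids.size, capacity):
        chunk = token_ids[start : start + capacity]
        ids = np.full(segment_length, vocab.pad_id, dtype=np.int32)
        ids[0] = vocab.cls_id
        ids[1 : 1 + chunk.size] = chunk
        ids[1 + chunk.size] = vocab.sep_id
        flags = np.zeros(segment_length, dtype=np.uint8)
        flags[: chunk.size + 2] = 1
        segments.append(TokenizedSegment(contig_id=contig_id, token_ids=ids, attention_flags=flags))
    return segments


def tokenize_contig(
    sequence: str,
    contig_id: str,
    vocab: Vocabulary,
    segment_length: int = DEFAULT_SEGMENT_LENGTH,
) -> list[TokenizedSegment]:
    """kmerize + segmentize in one call."""
    return segmentize(kmerize(sequence, vocab, k=vocab.k), contig_id, vocab, segment_length)
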