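"""Canonical tetranucleotide frequency (TNF) features.

Because sequenced contigs come from double-stranded DNA, a 4-mer and its
reverse complement are the same observation; collapsing the 256 4-mers by
reverse-complement identity leaves 136 equivalence classes (16 palindromic
singletons + 120 pairs). Each contig is summarized by the length-normalized
count vector over those classes: row i is f_i / sum_j f_ij, so rows sum to 1
and contigs of different lengths are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ContigRecord
from .tokenizer import BASES

N_CANONICAL = 136

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CanonicalIndex:
    """Maps every 4-mer to its canonical feature column in [0, 135]."""

    representatives: tuple[str, ...]  # 136 sorted canonical 4-mers
    column_of: dict[str, int]  # all 256 4-mers -> column

    def __getitem__(self, kmer: str) -> int:
        return self.column_of[kmer]


def canonical_index() -> CanonicalIndex:
    """Build the deterministic canonical 4-mer index.

    The representative of {kmer, revcomp(kmer)} is the lexicographically
    smaller member; columns are ordered by sorted representatives.
    """
    reps = sorted({min(kmer, revcomp(kmer)) for kmer in ("".join(p) for p in product(BASES, repeat=4))})
    rep_col = {rep: i for i, rep in enumerate(reps)}
    column_of = {
        kmer: rep_col[min(kmer, revcomp(kmer))]
        for kmer in ("".join(p) for p in product(BASES, repeat=4))
    }
    return CanonicalIndex(representatives=tuple(reps), column_of=column_of)


# vectorized lookup table: literal 4-mer id (base-4 over ACGT) -> canonical column
def _column_lut(index: CanonicalIndex) -> np.ndarray:
    lut = np.empty(256, dtype=np.int64)
    for kmer, col in index.column_of.items():
        code = 0
        for base in kmer:
            code = code * 4 + BASES.index(base)
        lut[code] = col
    return lut


@dataclass
class TNFMatrix:
    """Row-normalized canonical 4-mer frequencies, one row per contig."""

    contig_ids: list[str]
    values: np.ndarray  # (N, 136) float64, rows sum to 1

    def to_tsv(self, path: str | Path) -> None:
        index = canonical_index()
        df = pd.DataFrame(self.values, index=self.contig_ids, columns=index.representatives)
        df.to_csv(path, sep="\t", index_label="contig_id")


def tnf_matrix(contigs: Sequence[ContigRecord]) -> TNFMatrix:
    """Count every stride-1 ACGT window into its canonical column and normalize.

    Windows containing N are skipped. A contig whose every window contains N
    cannot be normalized and raises, naming the contig.
    """
    if not contigs:
        raise ValueError("no contigs given")
    lut = _column_lut(canonical_index())
    values = np.zeros((len(contigs), N_CANONICAL), dtype=np.float64)
    for i, contig in enumerate(contigs):
        seq = contig.sequence
        if len(seq) < 4:
            raise ValueError(f"contig {contig.id!r} shorter than 4 bp")
        codes = np.full(len(seq), -1, dtype=np.int64)
        raw = np.frombuffer(seq.encode(), dtype=np.uint8)
        for value, base in enumerate(BASES):
            codes[raw == ord(base)] = value
        n = len(seq) - 3
        ids = np.zeros(n, dtype=np.int64)
        bad = np.zeros(n, dtype=bool)
        for offset in range(4):
            window = codes[offset : offset + n]
            ids = ids * 4 + np.maximum(window, 0)
            bad |= window < 0
        cols = lut[ids[~bad]]
        if cols.size == 0:
            raise ValueError(
                f"contig {contig.id!r} has no N-free 4-mer window; cannot normalize"
            )
        np.add.at(values[i], cols, 1.0)
        values[i] /= values[i].sum()
    return TNFMatrix(contig_ids=[c.id for c in contigs], values=values)
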