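"""Scoring binning results against a known contig-to-genome truth.

Two complementary views:

* contig-level precision/recall/F1 — each bin is matched to the genome
  contributing the plurality of its contigs, and P = TP/(TP+FP),
  R = TP/(TP+FN), F1 = 2TP/(2TP+FP+FN) are computed per bin, plus macro
  (per-bin average) and micro (pooled counts) summaries;
* base-pair-level near-complete (NC) genome counting — a genome counts as
  recovered at recall threshold r if some bin covers at least r of the
  genome's base pairs (bp-recall) while at least ``precision_min`` of the
  bin's base pairs belong to that genome (bp-precision).

Noise contigs (label −1) are unassigned: they belong to no bin and count as
false negatives for their genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cluster import BinningResult
from .io import NOISE_LABEL, GroundTruth

DEFAULT_RECALL_GRID = (0.5, 0.6, 0.7, 0.8, 0.9, 0.95, 0.99)
DEFAULT_PRECISION_MIN = 0.95


@dataclass
class BinScore:
    bin_id: int
    genome: str
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / denom if denom else 0.0


@dataclass
class EvalReport:
    per_bin: list[BinScore]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    micro_precision: float
    micro_recall: float
    micro_f1: float
    nc_table: dict[float, int] = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {
                "bin_id": s.bin_id, "matched_genome": s.genome,
                "TP": s.tp, "FP": s.fp, "FN": s.fn,
                "precision": s.precision, "recall": s.recall, "f1": s.f1,
            }
            for s in self.per_bin
        ]
        rows.append({
            "bin_id": "macro", "matched_genome": "",
            "precision": self.macro_precision, "recall": self.macro_recall,
            "f1": self.macro_f1,
        })
        rows.append({
            "bin_id": "micro", "matched_genome": "",
            "precision": self.micro_precision, "recall": self.micro_recall,
            "f1": self.micro_f1,
        })
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        lines = [
            f"bins evaluated: {len(self.per_bin)}",
            f"macro P/R/F1: {self.macro_precision:.4f} / {self.macro_recall:.4f} / {self.macro_f1:.4f}",
            f"micro P/R/F1: {self.micro_precision:.4f} / {self.micro_recall:.4f} / {self.micro_f1:.4f}",
        ]
        if self.nc_table:
            nc = "  ".join(f"r>={r:g}: {n}" for r, n in sorted(self.nc_table.items()))
            lines.append(f"NC genomes ({nc})")
        return "\n".join(lines)


def confusion_metrics(result: BinningResult, truth: GroundTruth) -> EvalReport:
    """Contig-level per-bin precision/recall/F1 with macro and micro averages.

    Every evaluated contig must appear in the truth; offenders are listed.
    """
    missing = [cid for cid in result.contig_ids if cid not in truth.contig_to_genome]
    if missing:
        raise ValueError(f"contigs absent from ground truth: {missing[:10]}"
                         + ("..." if len(missing) > 10 else ""))

    genome_of = truth.contig_to_genome
    genome_total: dict[str, int] = {}
    for cid in result.contig_ids:
        g = genome_of[cid]
        genome_total[g] = genome_total.get(g, 0) + 1

    members: dict[int, list[str]] = {}
    for cid, label in zip(result.contig_ids, result.labels):
        if label != NOISE_LABEL:
            members.setdefault(int(label), []).append(cid)

    per_bin: list[BinScore] = []
    for bin_id in sorted(members):
        counts: dict[str, int] = {}
        for cid in members[bin_id]:
            g = genome_of[cid]
            counts[g] = counts.get(g, 0) + 1
        # plurality match; deterministic tie-break by genome id
        genome = max(sorted(counts), key=counts.get)
        tp = counts[genome]
        fp = len(members[bin_id]) - tp
        fn = genome_total[genome] - tp
        per_bin.append(BinScore(bin_id=bin_id, genome=genome, tp=tp, fp=fp, fn=fn))

    if per_bin:
        macro_p = float(np.mean([s.precision for s in per_bin]))
        macro_r = float(np.mean([s.recall for s in per_bin]))
        macro_f = float(np.mean([s.f1 for s in per_bin]))
        tp = sum(s.tp for s in per_bin)
        fp = sum(s.fp for s in per_bin)
        fn = sum(s.fn for s in per_bin)
        micro_p = tp / (tp + fp) if tp + fp else 0.0
        micro_r = tp / (tp + fn) if tp + fn else 0.0
        micro_f = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    else:  # everything noise
        macro_p = macro_r = macro_f = micro_p = micro_r = micro_f = 0.0

    return EvalReport(
        per_bin=per_bin,
        macro_precision=macro_p, macro_recall=macro_r, macro_f1=macro_f,
        micro_precision=micro_p, micro_recall=micro_r, micro_f1=micro_f,
    )


def _merge_by_label(truth: GroundTruth) -> GroundTruth:
    """Collapse genomes sharing a taxonomic label into one unit."""
    if not truth.genome_labels:
        return truth
    relabel = {g: truth.genome_labels.get(g, g) for g in set(truth.contig_to_genome.values())}
    contig_to = {cid: relabel[g] for cid, g in truth.contig_to_genome.items()}
    sizes: dict[str, int] = {}
    for g, size in truth.genome_sizes.items():
        merged = relabel.get(g, g)
        sizes[merged] = sizes.get(merged, 0) + size
    return GroundTruth(contig_to_genome=contig_to, genome_sizes=sizes)


def nc_counts(
    result: BinningResult,
    truth: GroundTruth,
    contig_lengths: Mapping[str, int],
    precision_min: float = DEFAULT_PRECISION_MIN,
    recall_grid: Sequence[float] = DEFAULT_RECALL_GRID,
    merge_labels: bool = False,
    use_assembled_sizes: bool = True,
) -> dict[float, int]:
    """Count genomes recovered near-completely at each recall threshold.

    bp-recall of a (genome, bin) pair is their overlapping base pairs over
    the genome size; bp-precision is the overlap over the bin's total base
    pairs. With ``use_assembled_sizes`` (default) the genome size is the sum
    of its evaluated contigs' lengths — the base pairs a binner could
    possibly recover; set it False to use ``truth.genome_sizes``.
    """
    if merge_labels:
        truth = _merge_by_label(truth)
    missing = [cid for cid in result.contig_ids if cid not in contig_lengths]
    if missing:
        raise ValueError(f"contig lengths missing for: {missing[:10]}")

    genome_of = truth.contig_to_genome
    overlap: dict[tuple[str, int], int] = {}
    bin_size: dict[int, int] = {}
    genome_size: dict[str, int] = {}
    for cid, label in zip(result.contig_ids, result.labels):
        length = int(contig_lengths[cid])
        g = genome_of[cid]
        genome_size[g] = genome_size.get(g, 0) + length
        if label == NOISE_LABEL:
            continue
        b = int(label)
        bin_size[b] = bin_size.get(b, 0) + length
        overlap[(g, b)] = overlap.get((g, b), 0) + length
    if not use_assembled_sizes:
        if not truth.genome_sizes:
            raise ValueError("truth has no genome sizes; use use_assembled_sizes=True")
        genome_size = dict(truth.genome_sizes)

    # best qualifying bp-recall per genome (among bins meeting precision_min)
    best_recall: dict[str, float] = {g: 0.0 for g in genome_size}
    for (g, b), bp in overlap.items():
        if bp / bin_size[b] >= precision_min:
            best_recall[g] = max(best_recall[g], bp / genome_size[g])
    return {
        float(r): sum(1 for g in best_recall if best_recall[g] >= r)
        for r in recall_grid
    }


def evaluate(
    result: BinningResult,
    truth: GroundTruth,
    contig_lengths: Mapping[str, int] | None = None,
    precision_min: float = DEFAULT_PRECISION_MIN,
    recall_grid: Sequence[float] = DEFAULT_RECALL_GRID,
) -> EvalReport:
    """Contig-level report, with the NC table attached when lengths are given."""
    report = confusion_metrics(result, truth)
    if contig_lengths is not None:
        report.nc_table = nc_counts(
            result, truth, contig_lengths,
            precision_min=precision_min, recall_grid=recall_grid,
        )
    return report
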