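"""Reading and writing the formats the binning pipeline touches.

Contigs come in as FASTA (single- or multi-line); binning results and
ground-truth contig-to-genome maps travel as two-column TSV. All ambiguity
handling is centralized here: any base outside {A, C, G, T} is normalized
to ``N`` on read, and downstream stages decide how to treat ``N``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

#: Bins labelled with this id are noise (unassigned contigs).
NOISE_LABEL = -1

_NON_ACGT = re.compile(r"[^ACGT]")


@dataclass(frozen=True)
class ContigRecord:
    """One assembled sequence: unique ``id`` plus bases over {A,C,G,T,N}."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GroundTruth:
    """Known contig-to-genome assignment used for evaluation.

    ``genome_sizes`` maps genome id to its total base pairs; when absent it
    can be derived from the mapped contigs' lengths. ``genome_labels``
    optionally maps genome id to a coarser taxonomic label (e.g. species or
    genus) so genomes sharing a label can be merged before evaluation.
    """

    contig_to_genome: dict[str, str]
    genome_sizes: dict[str, int] = field(default_factory=dict)
    genome_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for genome, size in self.genome_sizes.items():
            if size <= 0:
                raise ValueError(f"genome size for {genome!r} must be positive, got {size}")

    @property
    def genomes(self) -> list[str]:
        return sorted(set(self.contig_to_genome.values()))


def read_contigs(fasta_path: str | Path, min_length: int = 2000) -> list[ContigRecord]:
    """Read contigs from FASTA, keeping only records of ``length >= min_length``.

    Bases are uppercased and everything outside {A,C,G,T} becomes ``N``.
    The id is the header token before the first whitespace. Duplicate ids
    raise; an empty result (after filtering) only warns.
    """
    if min_length < 4:
        raise ValueError(f"min_length must be >= 4, got {min_length}")
    fasta_path = Path(fasta_path)
    if not fasta_path.exists():
        raise FileNotFoundError(f"FASTA file not found: {fasta_path}")

    records: list[ContigRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate contig id in {fasta_path}: {rec.id!r}")
        seen.add(rec.id)
        seq = _NON_ACGT.sub("N", str(rec.seq).upper())
        if len(seq) >= min_length:
            records.append(ContigRecord(id=rec.id, sequence=seq))
    if not records:
        warnings.warn(f"no contigs of length >= {min_length} in {fasta_path}", stacklevel=2)
    return records


def write_contigs(records: Iterable[ContigRecord], fasta_path: str | Path, width: int = 70) -> None:
    """Write contigs as wrapped FASTA."""
    with open(fasta_path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def write_bins(assignments: Mapping[str, int], out_path: str | Path) -> None:
    """Write a contig-to-bin assignment as TSV with header ``contig_id\\tbin_id``.

    Noise contigs carry bin id ``-1``. Refuses an empty assignment.
    """
    if not assignments:
        raise ValueError("refusing to write an empty binning result")
    with open(out_path, "w") as fh:
        fh.write("contig_id\tbin_id\n")
        for contig_id, bin_id in assignments.items():
            fh.write(f"{contig_id}\t{int(bin_id)}\n")


def read_bins(path: str | Path) -> dict[str, int]:
    """Read a contig-to-bin TSV written by :func:`write_bins`."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line:
                continue
            contig_id, bin_id = line.split("\t")
            if line_no == 0 and contig_id == "contig_id":
                continue
            out[contig_id] = int(bin_id)
    return out


def read_ground_truth(
    truth_path: str | Path,
    sizes_path: str | Path | None = None,
    labels_path: str | Path | None = None,
) -> GroundTruth:
    """Read a ground-truth ``contig_id\\tgenome_id`` TSV (header optional).

    ``sizes_path`` optionally supplies ``genome_id\\tsize_bp`` rows and
    ``labels_path`` supplies ``genome_id\\tlabel`` rows for taxonomic merging.
    """
    mapping: dict[str, str] = {}
    with open(truth_path) as fh:
        for line_no, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line:
                continue
            contig_id, genome_id = line.split("\t")[:2]
            if line_no == 0 and contig_id.lower() in {"contig_id", "contig"}:
                continue
            if contig_id in mapping:
                raise ValueError(f"contig {contig_id!r} mapped twice in {truth_path}")
            mapping[contig_id] = genome_id

    sizes: dict[str, int] = {}
    if sizes_path is not None:
        with open(sizes_path) as fh:
            for line_no, line in enumerate(fh):
                line = line.rstrip("\n")
                if not line:
                    continue
                genome_id, size = line.split("\t")[:2]
                if line_no == 0 and genome_id.lower() in {"genome_id", "genome"}:
                    continue
                sizes[genome_id] = int(size)

    labels: dict[str, str] = {}
    if labels_path is not None:
        with open(labels_path) as fh:
            for line_no, line in enumerate(fh):
                line = line.rstrip("\n")
                if not line:
                    continue
                genome_id, label = line.split("\t")[:2]
                if line_no == 0 and genome_id.lower() in {"genome_id", "genome"}:
                    continue
                labels[genome_id] = label

    return GroundTruth(contig_to_genome=mapping, genome_sizes=sizes, genome_labels=labels)
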