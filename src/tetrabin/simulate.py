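"""Synthetic multi-genome communities with known ground truth.

Real microbial genomes carry genome-specific oligonucleotide usage — the
compositional signal that tetranucleotide-frequency binning exploits. The
generator emulates exactly that: each genome is an order-2 Markov chain over
{A,C,G,T} whose transition rows are drawn from a Dirichlet with a small
concentration parameter, so different genomes get distinct 4-mer spectra
without any being hardcoded. Contigs are uniformly placed substrings with
log-normal lengths floored at the pipeline's 2000 bp minimum, optionally hit
by substitution noise. Everything is reproducible from the seed.

What it does not emulate: repeats, mobile elements, strain mixtures, GC
skew along the replichore, coverage/abundance structure, or assembly
artifacts — so passing tests show the pipeline recovers compositional
structure, not that it handles every hardness of real assemblies.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import ContigRecord, GroundTruth, write_contigs

BASES = "ACGT"


@dataclass(frozen=True)
class CommunityConfig:
    """Study conditions for one synthetic community.

    Defaults give three clearly divergent ~100 kbp genomes fragmented into
    50 contigs each (150 total) with mild substitution noise — a desk-scale
    stand-in for the multi-genome, >=2000 bp regime the pipeline targets.
    """

    n_genomes: int = 3
    genome_length_range: tuple[int, int] = (80_000, 120_000)
    markov_order: int = 2
    concentration: float = 0.1  # Dirichlet concentration; lower = more divergent genomes
    contigs_per_genome: int = 50
    contig_length_median: int = 3000
    contig_length_sigma: float = 0.4  # log-space sd of the log-normal length law
    contig_length_floor: int = 2000
    substitution_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 1 or self.contigs_per_genome < 1:
            raise ValueError("counts must be positive")
        if not (0.0 <= self.substitution_rate <= 0.2):
            raise ValueError("substitution_rate must be in [0, 0.2]")
        if self.markov_order not in (0, 2):
            raise ValueError("markov_order must be 0 or 2")
        if self.contig_length_floor > min(self.genome_length_range):
            raise ValueError("contig length floor exceeds the shortest possible genome")


def _sample_genome(length: int, order: int, concentration: float,
                   rng: np.random.Generator) -> str:
    """Emit one genome from a random order-0 or order-2 Markov chain."""
    if order == 0:
        probs = rng.dirichlet(np.full(4, concentration))
        seq = rng.choice(4, size=length, p=probs)
    else:
        trans = rng.dirichlet(np.full(4, concentration), size=16)  # 16 dinucleotide contexts
        seq = np.empty(length, dtype=np.int64)
        seq[0] = rng.integers(4)
        seq[1] = rng.integers(4)
        # cumulative-probability inversion with one uniform draw per base
        cum = np.cumsum(trans, axis=1)
        u = rng.random(length)
        for i in range(2, length):
            ctx = seq[i - 2] * 4 + seq[i - 1]
            seq[i] = np.searchsorted(cum[ctx], u[i])
    return "".join(BASES[b] for b in seq)


def simulate_community(
    config: CommunityConfig | None = None,
    out_dir: str | Path | None = None,
) -> tuple[list[ContigRecord], GroundTruth]:
    """Generate a community; optionally write FASTA/truth/sizes/config files.

    Returns the contig records and the ground truth (contig->genome mapping,
    true genome sizes). When ``out_dir`` is given, writes ``contigs.fasta``,
    ``truth.tsv``, ``genome_sizes.tsv`` and ``config.txt`` there.
    """
    config = config or CommunityConfig()
    rng = np.random.default_rng(config.seed)

    contigs: list[ContigRecord] = []
    mapping: dict[str, str] = {}
    sizes: dict[str, int] = {}
    for g in range(config.n_genomes):
        genome_id = f"genome_{g}"
        length = int(rng.integers(*config.genome_length_range, endpoint=True))
        genome = _sample_genome(length, config.markov_order, config.concentration, rng)
        sizes[genome_id] = length
        for c in range(config.contigs_per_genome):
            raw = rng.lognormal(np.log(config.contig_length_median), config.contig_length_sigma)
            clen = int(min(max(raw, config.contig_length_floor), length))
            start = int(rng.integers(0, length - clen, endpoint=True))
            seq = genome[start : start + clen]
            if config.substitution_rate > 0:
                arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
                hits = np.nonzero(rng.random(clen) < config.substitution_rate)[0]
                # substitute with a uniformly different base
                for i in hits:
                    current = BASES.index(chr(arr[i]))
                    arr[i] = ord(BASES[(current + 1 + rng.integers(3)) % 4])
                seq = arr.tobytes().decode()
            contig_id = f"{genome_id}_c{c}"
            contigs.append(ContigRecord(id=contig_id, sequence=seq))
            mapping[contig_id] = genome_id

    truth = GroundTruth(contig_to_genome=mapping, genome_sizes=sizes)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_contigs(contigs, out_dir / "contigs.fasta")
        with open(out_dir / "truth.tsv", "w") as fh:
            fh.write("contig_id\tgenome_id\n")
            for cid, gid in mapping.items():
                fh.write(f"{cid}\t{gid}\n")
        with open(out_dir / "genome_sizes.tsv", "w") as fh:
            fh.write("genome_id\tsize_bp\n")
            for gid, size in sizes.items():
                fh.write(f"{gid}\t{size}\n")
        (out_dir / "config.txt").write_text(
            "\n".join(f"{k} = {v}" for k, v in vars(config).items()) + "\n"
        )
    return contigs, truth
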