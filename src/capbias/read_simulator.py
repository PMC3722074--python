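"""Single-end exome-capture read simulator with an allelic capture-bias model.

Each read is drawn by (1) choosing a (target, allele) source with probability
proportional to the source interval length times an allele-specific capture
weight, (2) choosing a start uniformly over the positions at which a read of
the configured length fits inside the extended target interval, (3) a fair
strand coin, and (4) copying the error-free sequence from the chosen parental
genome (reverse-complemented on '-'), with all base qualities Q40.  With both
bias betas at zero the source probabilities are exactly length over cumulative
length, i.e. an unbiased capture.

A uniform whole-genome channel with the same read format serves as control.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from capbias.io import _open_text
from capbias.synthetic_genomes import ConfigurationError, Genome, Target, revcomp

DEFAULT_READ_LENGTH = 101


@dataclass
class BiasModel:
    """Log-linear per-variant capture penalty against the strain-B allele.

    The strain-B copy of a target is selected with weight
    exp(-beta_snv * nSNV - beta_indel * nIndel) relative to the strain-A copy;
    (0, 0) reproduces the unbiased simulator exactly.
    """

    beta_snv: float = 0.0
    beta_indel: float = 0.0

    def validate(self) -> None:
        if self.beta_snv < 0 or self.beta_indel < 0:
            raise ConfigurationError("bias betas must be >= 0")


@dataclass
class Read:
    id: str
    sequence: str
    qualities: str
    strain: str  # "A" | "B"
    source: str  # target id (exome) or chromosome (WGS)
    start: int  # 0-based start on the source genome
    strand: str  # "+" | "-"


class ReadSet:
    """Column-oriented container of simulated reads with truth labels."""

    def __init__(
        self,
        ids: list[str],
        seqs: list[str],
        strain: np.ndarray,
        source: list[str],
        chrom: list[str],
        start: np.ndarray,
        strand: np.ndarray,
        read_length: int,
    ):
        self.ids = ids
        self.seqs = seqs
        self.strain = strain  # array of "A"/"B"
        self.source = source  # target id or chrom per read
        self.chrom = chrom  # chromosome on the source genome
        self.start = start
        self.strand = strand  # array of "+"/"-"
        self.read_length = read_length

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        q = "I" * self.read_length
        for i in range(len(self.ids)):
            yield Read(
                self.ids[i], self.seqs[i], q, str(self.strain[i]), self.source[i],
                int(self.start[i]), str(self.strand[i]),
            )


def _make_ids(strain, source, start, strand) -> list[str]:
    return [
        f"r{i:07d}|{s}|{src}|{st}|{sd}"
        for i, (s, src, st, sd) in enumerate(zip(strain, source, start, strand))
    ]


def parse_read_id(read_id: str) -> tuple[str, str, int, str]:
    """Truth labels (strain, source, start, strand) encoded after '|' in the id."""
    _, strain, source, start, strand = read_id.split("|")
    return strain, source, int(start), strand


def simulate_exome_reads(
    targets: list[Target],
    genomeA: Genome,
    genomeB: Genome,
    n_reads: int,
    read_length: int = DEFAULT_READ_LENGTH,
    bias: BiasModel | None = None,
    seed: int = 0,
) -> ReadSet:
    """Draw n_reads single-end capture reads from the extended target set."""
    if n_reads < 1:
        raise ConfigurationError("n_reads must be >= 1")
    bias = bias or BiasModel()
    bias.validate()
    if not targets:
        raise ConfigurationError("no targets to simulate from")
    for t in targets:
        if t.startB is None or t.nSNV < 0:
            raise ValueError(f"target {t.id} lacks orthologous interval or annotation")

    rng = np.random.default_rng(seed)
    n_t = len(targets)
    # source s in [0, 2*n_t): s < n_t -> strain A copy of targets[s]; else strain B
    lenA = np.array([t.lengthA for t in targets], dtype=float)
    lenB = np.array([t.lengthB for t in targets], dtype=float)
    wB = np.exp(-bias.beta_snv * np.array([t.nSNV for t in targets])
                - bias.beta_indel * np.array([t.nIndel for t in targets]))
    weights = np.concatenate([lenA, lenB * wB])
    weights /= weights.sum()

    starts0 = np.array([t.startA for t in targets] + [t.startB for t in targets])
    n_starts = np.concatenate([lenA, lenB]).astype(int) - read_length + 1
    if np.any(n_starts < 1):
        raise ConfigurationError("some target interval is shorter than the read length")

    src = rng.choice(2 * n_t, size=n_reads, p=weights)
    offs = (rng.random(n_reads) * n_starts[src]).astype(int)
    start = starts0[src] + offs
    strand_bits = rng.integers(0, 2, size=n_reads)

    t_chrom = [t.chrom for t in targets]
    t_id = [t.id for t in targets]
    seqs: list[str] = []
    chroms: list[str] = []
    sources: list[str] = []
    strain = np.where(src < n_t, "A", "B")
    chrA = genomeA.chromosomes
    chrB = genomeB.chromosomes
    for i in range(n_reads):
        ti = src[i] % n_t
        c = t_chrom[ti]
        s = int(start[i])
        seq = (chrA if src[i] < n_t else chrB)[c][s : s + read_length]
        if strand_bits[i]:
            seq = revcomp(seq)
        seqs.append(seq)
        chroms.append(c)
        sources.append(t_id[ti])
    strand = np.where(strand_bits == 1, "-", "+")
    ids = _make_ids(strain, sources, start, strand)
    return ReadSet(ids, seqs, strain, sources, chroms, start, strand, read_length)


def simulate_wgs_reads(
    genomeA: Genome,
    genomeB: Genome,
    n_reads: int,
    read_length: int = DEFAULT_READ_LENGTH,
    seed: int = 0,
) -> ReadSet:
    """Uniform whole-genome reads: fair strain coin, uniform start, fair strand."""
    if n_reads < 1:
        raise ConfigurationError("n_reads must be >= 1")
    rng = np.random.default_rng(seed)
    genomes = {"A": genomeA, "B": genomeB}
    strain = np.where(rng.integers(0, 2, size=n_reads) == 0, "A", "B")
    strand_bits = rng.integers(0, 2, size=n_reads)

    valid = {}
    for label, g in genomes.items():
        names = list(g.chromosomes)
        counts = np.array([len(g.chromosomes[c]) - read_length + 1 for c in names])
        if np.any(counts < 1):
            raise ConfigurationError("chromosome shorter than read length")
        valid[label] = (names, counts, counts.cumsum())

    seqs: list[str] = []
    chroms: list[str] = []
    starts = np.zeros(n_reads, dtype=int)
    for i in range(n_reads):
        label = str(strain[i])
        names, counts, cum = valid[label]
        u = int(rng.integers(0, cum[-1]))
        ci = int(np.searchsorted(cum, u, side="right"))
        s = u - (cum[ci - 1] if ci > 0 else 0)
        seq = genomes[label].chromosomes[names[ci]][s : s + read_length]
        if strand_bits[i]:
            seq = revcomp(seq)
        seqs.append(seq)
        chroms.append(names[ci])
        starts[i] = s
    strand = np.where(strand_bits == 1, "-", "+")
    ids = _make_ids(strain, chroms, starts, strand)
    return ReadSet(ids, seqs, strain, list(chroms), chroms, starts, strand, read_length)


def write_fastq(reads: ReadSet, path: str | Path) -> None:
    """Standard 4-line FASTQ; truth labels live in the read id; Q40 = 'I'."""
    q = "I" * reads.read_length
    with _open_text(path, "w") as fh:
        for i, seq in zip(reads.ids, reads.seqs):
            fh.write(f"@{i}\n{seq}\n+\n{q}\n")
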