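"""Readers/writers for the standard interchange formats used by the pipeline.

FASTA and FASTQ go through Biopython, SAM through pysam; BED, VCF and the
liftover TSV are simple enough to be written directly.  Everything is plain
text so external tools (samtools, bedtools, real aligners) can be substituted
at any stage.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from capbias.synthetic_genomes import Genome, LiftoverMap, Target, TruthVariant


def _open_text(path: str | Path, mode: str) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


# ---------------------------------------------------------------- FASTA

def write_fasta(genome: Genome, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description=f"strain={genome.strain_label}")
        for name, seq in genome.chromosomes.items()
    ]
    with _open_text(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path: str | Path, strain_label: str = "?") -> Genome:
    with _open_text(path, "r") as fh:
        chroms = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
    return Genome(strain_label=strain_label, chromosomes=chroms)


# ---------------------------------------------------------------- BED

def write_targets_bed(targets: Iterable[Target], path: str | Path) -> None:
    """6+ column BED: A interval, id, nSNV as score, strand '+', then B interval/nIndel."""
    with _open_text(path, "w") as fh:
        for t in targets:
            b_chrom = t.chrom if t.startB is not None else "."
            b_start = t.startB if t.startB is not None else -1
            b_end = t.endB if t.endB is not None else -1
            fh.write(
                f"{t.chrom}\t{t.startA}\t{t.endA}\t{t.id}\t{max(t.nSNV, 0)}\t+"
                f"\t{b_chrom}\t{b_start}\t{b_end}\t{max(t.nIndel, 0)}\t{int(t.extended)}\n"
            )


def read_targets_bed(path: str | Path) -> list[Target]:
    targets: list[Target] = []
    with _open_text(path, "r") as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            t = Target(id=f[3], chrom=f[0], startA=int(f[1]), endA=int(f[2]))
            if len(f) >= 5:
                t.nSNV = int(f[4])
            if len(f) >= 11:
                if int(f[7]) >= 0:
                    t.startB, t.endB = int(f[7]), int(f[8])
                t.nIndel = int(f[9])
                t.extended = bool(int(f[10]))
            targets.append(t)
    return targets


# ---------------------------------------------------------------- VCF (truth table)

_VCF_HEADER = """##fileformat=VCFv4.2
##source=capbias
{contigs}##INFO=<ID=KIND,Number=1,Type=String,Description="Variant kind">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tF1
"""


def write_truth_vcf(truth: Iterable[TruthVariant], genome: Genome, path: str | Path) -> None:
    """Truth variants with strain A as REF; the F1 hybrid is heterozygous 1|0."""
    contigs = "".join(
        f"##contig=<ID={name},length={len(seq)}>\n" for name, seq in genome.chromosomes.items()
    )
    with _open_text(path, "w") as fh:
        fh.write(_VCF_HEADER.format(contigs=contigs))
        for v in truth:
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref_allele}\t{v.alt_allele}\t.\tPASS"
                f"\tKIND={v.kind}\tGT\t1|0\n"
            )


def read_truth_vcf(path: str | Path) -> list[TruthVariant]:
    truth: list[TruthVariant] = []
    with _open_text(path, "r") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            kind = "SNV"
            for kv in f[7].split(";"):
                if kv.startswith("KIND="):
                    kind = kv[5:]
            truth.append(TruthVariant(f[0], int(f[1]) - 1, kind, f[3], f[4]))
    return truth


# ---------------------------------------------------------------- liftover TSV

def write_liftover_tsv(lift: LiftoverMap, path: str | Path) -> None:
    rows = []
    for chrom, (starts, ends, offs) in lift.segments.items():
        for s, e, o in zip(starts, ends, offs):
            rows.append((chrom, int(s), int(e), int(o)))
    pd.DataFrame(rows, columns=["chrom", "A_start", "A_end", "offset"]).to_csv(
        path, sep="\t", index=False
    )


def read_liftover_tsv(path: str | Path) -> LiftoverMap:
    import numpy as np

    df = pd.read_csv(path, sep="\t")
    segments = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        segments[str(chrom)] = (
            np.asarray(sub["A_start"]),
            np.asarray(sub["A_end"]),
            np.asarray(sub["offset"]),
        )
    return LiftoverMap(segments)


# ---------------------------------------------------------------- FASTQ

def read_fastq_records(path: str | Path) -> list[tuple[str, str, str]]:
    """(id, sequence, quality-string) triples; id keeps the truth-label suffix."""
    out = []
    with _open_text(path, "r") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            quals = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            out.append((rec.id, str(rec.seq), quals))
    return out
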