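"""Seed-and-extend read aligner with dual-genome mapping and duplicate removal.

This is the contract stand-in for the BWA + Picard stages of a conventional
resequencing pipeline, at desk scale: exact k-mer seeds locate candidate
loci, each locus is extended by banded edit-distance alignment (edlib), all
loci at the minimal edit distance <= max_edit are reported, and a read is
unique iff exactly one such locus exists.  Reads mapping equally well to
several loci are flagged and discarded downstream, and reads needing more
than max_edit (default 5) edits are unmappable — reproducing the mappability
cliff at >5 variants per read against a single reference.

Duplicate removal collapses records sharing (genome, chromosome, leftmost
position, strand) to the lexicographically smallest read id, the same
read-level outcome as MarkDuplicates on single-end data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import edlib
import numpy as np
import pandas as pd

from capbias.read_simulator import ReadSet
from capbias.synthetic_genomes import Genome, revcomp

DEFAULT_MAX_EDIT = 5
DEFAULT_SEED_K = 20
DEFAULT_N_SEEDS = 4

ALN_COLUMNS = ["read_idx", "chrom", "pos", "end", "strand", "edit", "n_best"]


@dataclass
class AlignmentRecord:
    read_id: str
    genome_label: str
    chrom: str
    pos: int  # 0-based leftmost on the reference
    end: int  # half-open reference end
    strand: str
    edit_distance: int
    is_unique: bool


@dataclass
class DualMapping:
    read_id: str
    best_A: AlignmentRecord | None
    best_B: AlignmentRecord | None
    multi_A: bool = False
    multi_B: bool = False


class GenomeIndex:
    """Exact k-mer position table over one genome (concatenated with N spacers)."""

    def __init__(self, genome: Genome, k: int = DEFAULT_SEED_K):
        if not 8 <= k <= 32:
            raise ValueError("seed length k must be in [8, 32]")
        self.genome = genome
        self.k = k
        spacer = "N" * (k + 8)
        names = list(genome.chromosomes)
        offsets = []
        pos = 0
        parts = []
        for name in names:
            offsets.append(pos)
            seq = genome.chromosomes[name]
            parts.append(seq)
            pos += len(seq) + len(spacer)
            parts.append(spacer)
        self.concat = "".join(parts)
        self.chrom_names = names
        self.chrom_offsets = np.array(offsets)
        self.chrom_lengths = np.array([len(genome.chromosomes[n]) for n in names])
        table: dict[str, list[int]] = {}
        concat = self.concat
        for i in range(len(concat) - k + 1):
            kmer = concat[i : i + k]
            if "N" in kmer:
                continue
            table.setdefault(kmer, []).append(i)
        self.table = table

    def lookup(self, kmer: str) -> list[int]:
        return self.table.get(kmer, [])

    def to_chrom(self, gpos: int) -> tuple[str, int]:
        ci = int(np.searchsorted(self.chrom_offsets, gpos, side="right")) - 1
        return self.chrom_names[ci], gpos - int(self.chrom_offsets[ci])


def build_index(genome: Genome, k: int = DEFAULT_SEED_K) -> GenomeIndex:
    return GenomeIndex(genome, k)


def _seed_offsets(read_len: int, k: int, n_seeds: int) -> list[int]:
    n_seeds = min(n_seeds, max(1, read_len // k))
    if n_seeds == 1:
        return [0]
    return [round(i * (read_len - k) / (n_seeds - 1)) for i in range(n_seeds)]


def _candidate_hits(
    q: str, index: GenomeIndex, max_edit: int, offsets: list[int]
) -> list[tuple[int, int, int]]:
    """All (edit, gstart, gend) placements of q with edit <= max_edit near any seed hit."""
    k = index.k
    table = index.table
    diags: set[int] = set()
    for off in offsets:
        for p in table.get(q[off : off + k], ()):
            diags.add(p - off)
    if not diags:
        return []
    concat = index.concat
    n = len(concat)
    qlen = len(q)
    hits: list[tuple[int, int, int]] = []
    sorted_diags = sorted(diags)
    i = 0
    while i < len(sorted_diags):
        j = i
        while j + 1 < len(sorted_diags) and sorted_diags[j + 1] - sorted_diags[j] <= max_edit:
            j += 1
        lo = max(sorted_diags[i] - max_edit, 0)
        hi = min(sorted_diags[j] + qlen + max_edit, n)
        res = edlib.align(q, concat[lo:hi], mode="HW", task="locations", k=max_edit)
        if res["editDistance"] >= 0:
            for s, e in res["locations"]:
                hits.append((res["editDistance"], lo + s, lo + e + 1))
        i = j + 1
    return hits


def _map_sequence(
    seq: str, index: GenomeIndex, max_edit: int, n_seeds: int
) -> list[tuple[int, int, int, str]]:
    """Best placements of a read: list of (edit, gstart, gend, strand), minimal edit only.

    Equal-score placements whose starts lie within half a read length on the
    same strand are one locus (optimal alignments around indels are ambiguous
    by a few bases); the leftmost representative is kept.
    """
    qlen = len(seq)
    offsets = _seed_offsets(qlen, index.k, n_seeds)
    all_hits: list[tuple[int, int, int, str]] = []
    for strand, q in (("+", seq), ("-", revcomp(seq))):
        for ed, s, e in _candidate_hits(q, index, max_edit, offsets):
            all_hits.append((ed, s, e, strand))
    if not all_hits:
        return []
    best = min(h[0] for h in all_hits)
    kept: list[tuple[int, int, int, str]] = []
    for h in sorted(h for h in all_hits if h[0] == best):
        if any(h[3] == g[3] and abs(h[1] - g[1]) <= qlen // 2 for g in kept):
            continue
        kept.append(h)
    return kept


def map_read(
    read, index: GenomeIndex, max_edit: int = DEFAULT_MAX_EDIT, n_seeds: int = DEFAULT_N_SEEDS
) -> list[AlignmentRecord]:
    """Map one read; returns all minimal-edit-distance loci (empty if unmappable)."""
    seq = read.sequence if hasattr(read, "sequence") else str(read)
    read_id = getattr(read, "id", "")
    hits = _map_sequence(seq, index, max_edit, n_seeds)
    unique = len(hits) == 1
    records = []
    for ed, s, e, strand in hits:
        chrom, pos = index.to_chrom(s)
        records.append(
            AlignmentRecord(
                read_id=read_id,
                genome_label=index.genome.strain_label,
                chrom=chrom,
                pos=pos,
                end=pos + (e - s),
                strand=strand,
                edit_distance=ed,
                is_unique=unique,
            )
        )
    return records


def map_read_dual(
    read, indexA: GenomeIndex, indexB: GenomeIndex, max_edit: int = DEFAULT_MAX_EDIT
) -> DualMapping:
    """Map one read to both parental genomes; multi-mapping on either side is flagged."""
    recsA = map_read(read, indexA, max_edit)
    recsB = map_read(read, indexB, max_edit)
    return DualMapping(
        read_id=getattr(read, "id", ""),
        best_A=recsA[0] if len(recsA) == 1 else None,
        best_B=recsB[0] if len(recsB) == 1 else None,
        multi_A=len(recsA) > 1,
        multi_B=len(recsB) > 1,
    )


def map_readset(
    reads: ReadSet, index: GenomeIndex, max_edit: int = DEFAULT_MAX_EDIT,
    n_seeds: int = DEFAULT_N_SEEDS,
) -> pd.DataFrame:
    """Batch-map a ReadSet; one row per read that maps, best locus with n_best count.

    Columns: read_idx, chrom, pos, end, strand, edit, n_best.  n_best > 1
    means the read multi-maps on this genome (the row carries the leftmost
    best locus for reference, but such reads are discarded downstream).
    """
    rows_idx: list[int] = []
    rows: list[tuple] = []
    for i, seq in enumerate(reads.seqs):
        hits = _map_sequence(seq, index, max_edit, n_seeds)
        if not hits:
            continue
        ed, s, e, strand = hits[0]
        chrom, pos = index.to_chrom(s)
        rows_idx.append(i)
        rows.append((chrom, pos, pos + (e - s), strand, ed, len(hits)))
    df = pd.DataFrame(rows, columns=ALN_COLUMNS[1:])
    df.insert(0, "read_idx", np.asarray(rows_idx, dtype=int))
    return df


def remove_duplicates(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse records sharing (chrom, pos, strand) to the lowest read index.

    Operates on a single-genome alignment table (as from map_readset).  A
    'genome_label' column, if present, participates in the key.
    """
    key = [c for c in ("genome_label", "chrom", "pos", "strand") if c in records.columns]
    return records.sort_values("read_idx", kind="stable").drop_duplicates(subset=key, keep="first")


def unique_only(records: pd.DataFrame) -> pd.DataFrame:
    return records[records["n_best"] == 1]


def cigar_for(
    seq: str, strand: str, genome: Genome, chrom: str, pos: int, end: int
) -> str:
    """CIGAR of the read (oriented as aligned) against its reference window."""
    q = seq if strand == "+" else revcomp(seq)
    res = edlib.align(q, genome.chromosomes[chrom][pos:end], mode="NW", task="path")
    return res["cigar"]


# ---------------------------------------------------------------- SAM interface

def write_sam(
    records: pd.DataFrame, reads: ReadSet, genome: Genome, path: str | Path
) -> None:
    """Minimal SAM with NM (edit distance) tags; MAPQ 60 unique / 0 multi."""
    import pysam

    names = list(genome.chromosomes)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": n, "LN": len(genome.chromosomes[n])} for n in names],
        }
    )
    tid = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for row in records.itertuples(index=False):
            i = int(row.read_idx)
            a = pysam.AlignedSegment(header)
            a.query_name = reads.ids[i]
            seq = reads.seqs[i] if row.strand == "+" else revcomp(reads.seqs[i])
            a.query_sequence = seq
            a.flag = 16 if row.strand == "-" else 0
            a.reference_id = tid[row.chrom]
            a.reference_start = int(row.pos)
            a.mapping_quality = 60 if row.n_best == 1 else 0
            a.cigarstring = _sam_cigar(
                cigar_for(reads.seqs[i], row.strand, genome, row.chrom, int(row.pos), int(row.end))
            )
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            a.set_tag("NM", int(row.edit))
            out.write(a)


def _sam_cigar(edlib_cigar: str) -> str:
    # pysam accepts =/X but some downstream tools prefer M; keep =/X (SAM 1.6 legal)
    return edlib_cigar


def read_sam(path: str | Path) -> pd.DataFrame:
    """Read a SAM written by write_sam back into the internal alignment table."""
    import pysam

    rows = []
    ids = []
    with pysam.AlignmentFile(str(path), "r") as fh:
        for a in fh:
            ids.append(a.query_name)
            rows.append(
                (
                    a.reference_name,
                    a.reference_start,
                    a.reference_end,
                    "-" if a.is_reverse else "+",
                    a.get_tag("NM"),
                    1 if a.mapping_quality == 60 else 2,
                )
            )
    df = pd.DataFrame(rows, columns=ALN_COLUMNS[1:])
    df.insert(0, "read_idx", np.arange(len(rows)))
    df["read_id"] = ids
    return df
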