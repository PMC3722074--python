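"""One-to-one orthologous target mapping onto strain B with the retention filters.

The probe-design intervals live on strain A; each target's sequence is
aligned to strain B (seed-and-extend with a short seed, full-chromosome scan
as fallback, standing in for BLAST), then four filters are applied in order:

1. uniqueness + chromosome identity — a target must place exactly once, on
   the chromosome of the same name;
2. synteny — within each chromosome, targets must preserve the strain-A
   5'-to-3' order on strain B (longest strictly increasing subsequence of
   B starts; everything off it is dropped).  Reverse-strand placements are
   treated as non-syntenic;
3. extension — both intervals grow 100 nt on each side; targets whose
   extension would cross a chromosome boundary are dropped;
4. N filter — any N inside either extended interval drops the target.

Drop reasons: multi_or_unmapped | wrong_chrom | non_syntenic | n_extension.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import edlib

from capbias.aligner import GenomeIndex, _candidate_hits, _seed_offsets
from capbias.synthetic_genomes import Genome, Target, revcomp

EXTENSION = 100
ORTHOLOGY_SEED_K = 12


@dataclass
class Placement:
    chrom: str
    start: int
    end: int
    strand: str
    edit: int


@dataclass
class OrthologyResult:
    retained: list[Target]
    dropped: dict[str, str]  # target id -> reason


def map_targets_to_alt_genome(
    targets: list[Target],
    genomeA: Genome,
    genomeB: Genome,
    max_edit_fraction: float = 0.25,
    indexB: GenomeIndex | None = None,
) -> dict[str, list[Placement]]:
    """All strain-B placements of each target sequence within the edit budget.

    Placements overlapping a better placement are merged (one locus); distinct
    loci within the budget are all reported, so near-verbatim duplications
    show up as multi-mapping.
    """
    if indexB is None:
        indexB = GenomeIndex(genomeB, k=ORTHOLOGY_SEED_K)
    out: dict[str, list[Placement]] = {}
    for t in targets:
        seq = genomeA.chromosomes[t.chrom][t.startA : t.endA]
        max_edit = int(max_edit_fraction * len(seq))
        hits: list[tuple[int, int, int, str]] = []
        offsets = _seed_offsets(len(seq), indexB.k, n_seeds=len(seq) // indexB.k)
        for strand, q in (("+", seq), ("-", revcomp(seq))):
            for ed, s, e in _candidate_hits(q, indexB, max_edit, offsets):
                hits.append((ed, s, e, strand))
        if not hits:
            hits = _full_scan(seq, indexB, max_edit)
        placements: list[Placement] = []
        for ed, s, e, strand in sorted(hits):
            if any(
                p.strand == strand and p.chrom == indexB.to_chrom(s)[0]
                and abs(p.start - indexB.to_chrom(s)[1]) <= len(seq) // 2
                for p in placements
            ):
                continue
            chrom, pos = indexB.to_chrom(s)
            placements.append(Placement(chrom, pos, pos + (e - s), strand, ed))
        out[t.id] = placements
    return out


def _full_scan(seq: str, indexB: GenomeIndex, max_edit: int) -> list[tuple[int, int, int, str]]:
    """Fallback when every seed is broken: scan the whole concatenated genome."""
    hits = []
    for strand, q in (("+", seq), ("-", revcomp(seq))):
        res = edlib.align(q, indexB.concat, mode="HW", task="locations", k=max_edit)
        if res["editDistance"] >= 0:
            for s, e in res["locations"]:
                hits.append((res["editDistance"], s, e + 1, strand))
    return hits


def filter_unique_same_chrom(
    targets: list[Target], placements: dict[str, list[Placement]]
) -> tuple[list[Target], dict[str, str]]:
    """Keep targets placing exactly once, on the same-named chromosome."""
    survivors: list[Target] = []
    dropped: dict[str, str] = {}
    for t in targets:
        ps = placements.get(t.id, [])
        if len(ps) != 1:
            dropped[t.id] = "multi_or_unmapped"
            continue
        p = ps[0]
        if p.chrom != t.chrom:
            dropped[t.id] = "wrong_chrom"
            continue
        if p.strand != "+":
            dropped[t.id] = "non_syntenic"  # inversion: orientation breaks synteny
            continue
        survivors.append(replace(t, startB=p.start, endB=p.end))
    return survivors, dropped


def filter_syntenic_order(
    survivors: list[Target],
) -> tuple[list[Target], dict[str, str]]:
    """Drop targets off the longest strictly-increasing subsequence of B starts.

    Processed per chromosome over targets in strain-A order; this is the
    global-consistent formalization of "same 5'-to-3' order as the
    neighbouring targets".
    """
    kept: list[Target] = []
    dropped: dict[str, str] = {}
    by_chrom: dict[str, list[Target]] = {}
    for t in sorted(survivors, key=lambda t: (t.chrom, t.startA)):
        by_chrom.setdefault(t.chrom, []).append(t)
    for ts in by_chrom.values():
        starts = [t.startB for t in ts]
        keep_idx = set(_lis_indices(starts))
        for i, t in enumerate(ts):
            if i in keep_idx:
                kept.append(t)
            else:
                dropped[t.id] = "non_syntenic"
    kept.sort(key=lambda t: (t.chrom, t.startA))
    return kept, dropped


def _lis_indices(seq: list[int]) -> list[int]:
    """Indices of one longest strictly increasing subsequence (leftmost tails)."""
    import bisect

    tails: list[int] = []  # values
    tails_idx: list[int] = []
    prev = [-1] * len(seq)
    for i, x in enumerate(seq):
        j = bisect.bisect_left(tails, x)
        if j == len(tails):
            tails.append(x)
            tails_idx.append(i)
        else:
            tails[j] = x
            tails_idx[j] = i
        prev[i] = tails_idx[j - 1] if j > 0 else -1
    out: list[int] = []
    i = tails_idx[-1] if tails_idx else -1
    while i >= 0:
        out.append(i)
        i = prev[i]
    return out[::-1]


def extend_and_filter_N(
    survivors: list[Target],
    genomeA: Genome,
    genomeB: Genome,
    dropped: dict[str, str] | None = None,
    extension: int = EXTENSION,
) -> OrthologyResult:
    """Extend both intervals by `extension` nt per side; drop on boundary or N."""
    dropped = dict(dropped or {})
    retained: list[Target] = []
    for t in survivors:
        sA, eA = t.startA - extension, t.endA + extension
        sB, eB = t.startB - extension, t.endB + extension
        lenA = len(genomeA.chromosomes[t.chrom])
        lenB = len(genomeB.chromosomes[t.chrom])
        if sA < 0 or eA > lenA or sB < 0 or eB > lenB:
            dropped[t.id] = "n_extension"  # missing flank: no comparable capture context
            continue
        if "N" in genomeA.chromosomes[t.chrom][sA:eA] or "N" in genomeB.chromosomes[t.chrom][sB:eB]:
            dropped[t.id] = "n_extension"
            continue
        retained.append(
            replace(t, startA=sA, endA=eA, startB=sB, endB=eB, extended=True)
        )
    retained.sort(key=lambda t: (t.chrom, t.startA))
    return OrthologyResult(retained=retained, dropped=dropped)


def establish_orthology(
    targets: list[Target],
    genomeA: Genome,
    genomeB: Genome,
    max_edit_fraction: float = 0.25,
    extension: int = EXTENSION,
) -> OrthologyResult:
    """Full orthology stage: map, uniqueness/chrom filter, synteny, extension+N."""
    placements = map_targets_to_alt_genome(targets, genomeA, genomeB, max_edit_fraction)
    survivors, dropped1 = filter_unique_same_chrom(targets, placements)
    survivors, dropped2 = filter_syntenic_order(survivors)
    result = extend_and_filter_N(survivors, genomeA, genomeB, {**dropped1, **dropped2}, extension)
    return result
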