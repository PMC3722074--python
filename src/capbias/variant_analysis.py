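"""Heterozygous SNV calling from strain-A alignments and sensitivity vs depth.

A bespoke pileup caller stands in for a full GATK pipeline: per-position
A/C/G/T counts are accumulated from uniquely mapped, deduplicated strain-A
alignments (CIGAR-aware, so indel-carrying reads contribute at the correct
reference positions), and a heterozygous SNV is emitted where a single
non-reference base reaches the depth, count and fraction thresholds.  Reads
are subsampled i.i.d. to a grid of mean target depths, and sensitivity is
the fraction of truth SNVs (inside the core probe intervals of the
mapping-bias-free targets) recovered at each depth, per nSNV group.

Thresholds default to min_depth 5, min_alt_count 3, min_alt_fraction 0.2 —
a regime in which a balanced heterozygote at mean depth 10 is detected most
of the time, so depth-10 sensitivities are informative about capture bias.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from capbias.aligner import cigar_for
from capbias.synthetic_genomes import Genome, Target, TruthVariant, revcomp

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class VariantCall:
    chrom: str
    pos: int  # 0-based
    ref_base: str
    alt_base: str
    depth: int
    alt_count: int
    multi_allelic: bool = False


@dataclass
class CallerParams:
    min_depth: int = 5
    min_alt_count: int = 3
    min_alt_fraction: float = 0.2
    max_alt_fraction_without_ref: float = 0.8


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for b, c in _BASE_CODE.items():
    _CODE_LUT[ord(b)] = c


class PileupEngine:
    """Precomputed per-read pileup contributions over strain-A alignments.

    Built once from an alignment table plus the read sequences; each
    subsampling pass then only needs a boolean mask over reads.  Reads whose
    alignment has no indels contribute a contiguous block (fast path); reads
    with indels get explicit per-base reference positions from their CIGAR.
    """

    def __init__(self, alignments: pd.DataFrame, reads, genomeA: Genome):
        self.chrom_names = list(genomeA.chromosomes)
        self.chrom_len = {c: len(s) for c, s in genomeA.chromosomes.items()}
        self.ref_codes = {c: _CODE_LUT[_encode(s)] for c, s in genomeA.chromosomes.items()}
        aln = alignments.reset_index(drop=True)
        n = len(aln)
        self.n_reads = n
        self.chrom = aln["chrom"].to_numpy()
        pos = aln["pos"].to_numpy(dtype=int)
        end = aln["end"].to_numpy(dtype=int)
        edit = aln["edit"].to_numpy(dtype=int)
        strand = aln["strand"].to_numpy()
        ridx = aln["read_idx"].to_numpy(dtype=int)
        self.start = pos
        self.codes: list[np.ndarray] = []
        self.custom: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for i in range(n):
            seq = reads.seqs[ridx[i]]
            q = seq if strand[i] == "+" else revcomp(seq)
            qcodes = _CODE_LUT[_encode(q)]
            self.codes.append(qcodes)
            if edit[i] == 0:
                continue  # exact match: contiguous block at pos
            span = int(end[i]) - int(pos[i])
            if span == len(q):
                continue  # substitutions only: still a contiguous block
            # indel read: realign with leftmost single-gap placement (the
            # desk-scale analogue of indel realignment; the unit-cost optimum
            # is ambiguous around gaps and the raw path can hide an adjacent
            # SNV inside the gap)
            ref_win = self.ref_codes[self.chrom[i]][int(pos[i]) : int(end[i])]
            realigned = _leftmost_single_gap(qcodes, ref_win, int(pos[i]), int(edit[i]))
            if realigned is not None:
                self.custom[i] = realigned
            else:
                cigar = cigar_for(seq, strand[i], genomeA, self.chrom[i], int(pos[i]), int(end[i]))
                rpos, ccodes = _cigar_positions(cigar, int(pos[i]), qcodes)
                self.custom[i] = (rpos, ccodes)

    def counts(self, mask: np.ndarray | None = None) -> dict[str, np.ndarray]:
        """Per-chromosome (4, L) base-count matrices for the masked read subset."""
        out = {c: np.zeros((4, L), dtype=np.int32) for c, L in self.chrom_len.items()}
        flat = {c: m.reshape(-1) for c, m in out.items()}
        idx = range(self.n_reads) if mask is None else np.nonzero(mask)[0]
        for c in self.chrom_len:
            L = self.chrom_len[c]
            simple_pos = []
            simple_codes = []
            for i in idx:
                if self.chrom[i] != c:
                    continue
                if i in self.custom:
                    rpos, ccodes = self.custom[i]
                    np.add.at(flat[c], ccodes.astype(np.int64) * L + rpos, 1)
                else:
                    codes = self.codes[i]
                    simple_pos.append(int(self.start[i]))
                    simple_codes.append(codes)
            if simple_pos:
                starts = np.asarray(simple_pos, dtype=np.int64)
                codes = np.stack(simple_codes).astype(np.int64)
                rl = codes.shape[1]
                positions = starts[:, None] + np.arange(rl, dtype=np.int64)[None, :]
                np.add.at(flat[c], codes * L + positions, 1)
        return out


def _leftmost_single_gap(
    qcodes: np.ndarray, ref_win: np.ndarray, pos: int, edit: int
) -> tuple[np.ndarray, np.ndarray] | None:
    """Realign a read whose window length differs from its length by one gap.

    Enumerates every placement of a single contiguous gap of length
    |window - read| (deletion when the window is longer, insertion when the
    read is longer) via prefix/suffix mismatch sums, and keeps the leftmost
    placement with the fewest substitutions.  Returns (reference positions,
    base codes) for the pileup, or None when no single-gap alignment attains
    the known edit distance (e.g. reads spanning two separate indels).
    """
    m, n = len(qcodes), len(ref_win)
    g = n - m
    if g > 0:  # deletion in the read relative to the reference
        pre = np.zeros(m + 1, dtype=np.int32)
        np.cumsum(qcodes != ref_win[:m], out=pre[1:])
        suf = np.zeros(m + 1, dtype=np.int32)
        suf[:-1] = np.cumsum((qcodes != ref_win[g:])[::-1])[::-1]
        mism = pre + suf
        d = int(np.argmin(mism))
        if g + int(mism[d]) != edit:
            return None
        rpos = np.concatenate([np.arange(pos, pos + d), np.arange(pos + d + g, pos + n)])
        return rpos, qcodes
    if g < 0:  # insertion in the read relative to the reference
        g = -g
        pre = np.zeros(n + 1, dtype=np.int32)
        np.cumsum(qcodes[:n] != ref_win, out=pre[1:])
        suf = np.zeros(n + 1, dtype=np.int32)
        suf[:-1] = np.cumsum((qcodes[g:] != ref_win)[::-1])[::-1]
        mism = pre + suf
        q = int(np.argmin(mism))
        if g + int(mism[q]) != edit:
            return None
        rpos = np.arange(pos, pos + n)
        codes = np.concatenate([qcodes[:q], qcodes[q + g :]])
        return rpos, codes
    return None


def _cigar_positions(cigar: str, pos: int, qcodes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Reference positions and base codes contributed by a CIGAR-aligned read."""
    rpos: list[np.ndarray] = []
    codes: list[np.ndarray] = []
    ri = pos
    qi = 0
    for m in _CIGAR_RE.finditer(cigar):
        ln, op = int(m.group(1)), m.group(2)
        if op in "=XM":
            rpos.append(np.arange(ri, ri + ln))
            codes.append(qcodes[qi : qi + ln])
            ri += ln
            qi += ln
        elif op == "D":
            ri += ln
        elif op == "I":
            qi += ln
    return np.concatenate(rpos), np.concatenate(codes)


def pileup(
    alignments: pd.DataFrame, reads, genomeA: Genome, mask: np.ndarray | None = None
) -> dict[str, np.ndarray]:
    """Per-position A/C/G/T counts over the whole genome from the alignments."""
    return PileupEngine(alignments, reads, genomeA).counts(mask)


def call_het_snvs(
    counts: dict[str, np.ndarray],
    genomeA: Genome,
    intervals: list[tuple[str, int, int]],
    params: CallerParams | None = None,
) -> list[VariantCall]:
    """Emit heterozygous SNV calls inside the given intervals."""
    params = params or CallerParams()
    calls: list[VariantCall] = []
    seen: set[tuple[str, int]] = set()
    for chrom, start, end in intervals:
        mat = counts[chrom][:, start:end]
        depth = mat.sum(axis=0)
        ref_codes = _CODE_LUT[_encode(genomeA.chromosomes[chrom][start:end])]
        valid_ref = ref_codes < 4
        alt_mat = mat.copy()
        cols = np.arange(end - start)
        alt_mat[ref_codes[valid_ref], cols[valid_ref]] = 0
        alt_best = alt_mat.argmax(axis=0)
        alt_count = alt_mat.max(axis=0)
        ref_count = np.where(valid_ref, mat[np.clip(ref_codes, 0, 3), cols], 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(depth > 0, alt_count / np.maximum(depth, 1), 0.0)
        ok = (
            valid_ref
            & (depth >= params.min_depth)
            & (alt_count >= params.min_alt_count)
            & (frac >= params.min_alt_fraction)
            & ((ref_count > 0) | (frac <= params.max_alt_fraction_without_ref))
        )
        for j in np.nonzero(ok)[0]:
            p = start + int(j)
            if (chrom, p) in seen:
                continue
            seen.add((chrom, p))
            second = int(np.sort(alt_mat[:, j])[-2])
            calls.append(
                VariantCall(
                    chrom=chrom,
                    pos=p,
                    ref_base="ACGT"[ref_codes[j]],
                    alt_base="ACGT"[int(alt_best[j])],
                    depth=int(depth[j]),
                    alt_count=int(alt_count[j]),
                    multi_allelic=second >= params.min_alt_count,
                )
            )
    calls.sort(key=lambda v: (v.chrom, v.pos))
    return calls


def subsample_to_depth(
    current_mean_depth: float, requested: float, n_reads: int, seed: int
) -> np.ndarray:
    """Bernoulli read-keep mask with p = requested / current (global, unstratified)."""
    if requested > current_mean_depth * (1 + 1e-9):
        raise ValueError(
            f"requested depth {requested} exceeds current mean {current_mean_depth:.2f}"
        )
    p = min(1.0, requested / current_mean_depth)
    rng = np.random.default_rng(seed)
    return rng.random(n_reads) < p


@dataclass
class SensitivityResult:
    mean_depth_level: float
    nSNV_group: int
    n_truth: int
    n_detected: int

    @property
    def sensitivity(self) -> float:
        return self.n_detected / self.n_truth if self.n_truth else float("nan")


def truth_snvs_in_targets(
    truth: list[TruthVariant], targets: list[Target], core_pad: int = 100
) -> pd.DataFrame:
    """Truth SNVs inside the core probe intervals, with per-target nSNV group.

    The group label is the number of truth SNVs in the target's core
    interval (what the probe region actually contains and what the caller
    can see at uniform coverage).
    """
    rows = []
    for t in targets:
        lo, hi = t.startA + core_pad, t.endA - core_pad
        inside = [
            v for v in truth if v.kind == "SNV" and v.chrom == t.chrom and lo <= v.pos < hi
        ]
        for v in inside:
            rows.append((t.id, v.chrom, v.pos, v.ref_allele, v.alt_allele, len(inside)))
    return pd.DataFrame(
        rows, columns=["target_id", "chrom", "pos", "ref", "alt", "nSNV_group"]
    )


def sensitivity_from_calls(
    calls: list[VariantCall], truth_df: pd.DataFrame, depth_level: float
) -> list[SensitivityResult]:
    called = {(c.chrom, c.pos, c.alt_base) for c in calls}
    out = []
    for g, sub in truth_df.groupby("nSNV_group"):
        detected = sum(
            1 for r in sub.itertuples() if (r.chrom, r.pos, r.alt) in called
        )
        out.append(SensitivityResult(depth_level, int(g), len(sub), detected))
    return out


def sensitivity_by_depth(
    engine: PileupEngine,
    genomeA: Genome,
    truth_df: pd.DataFrame,
    core_intervals: list[tuple[str, int, int]],
    current_mean_depth: float,
    depth_grid: list[float],
    params: CallerParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Subsample -> pileup -> call -> per-group sensitivity, per depth level."""
    rows = []
    for level_i, level in enumerate(depth_grid):
        mask = subsample_to_depth(current_mean_depth, level, engine.n_reads, seed * 1009 + level_i)
        counts = engine.counts(mask)
        calls = call_het_snvs(counts, genomeA, core_intervals, params)
        for r in sensitivity_from_calls(calls, truth_df, level):
            rows.append(
                {
                    "mean_depth_level": r.mean_depth_level,
                    "nSNV_group": r.nSNV_group,
                    "n_truth": r.n_truth,
                    "n_detected": r.n_detected,
                    "sensitivity": r.sensitivity,
                }
            )
    return pd.DataFrame(rows)


def compare_callsets(
    callsets: list[list[VariantCall]], truth_df: pd.DataFrame
) -> dict[str, int]:
    """Replicate-concordance counts and truth recovery at >=1 / >=2 / =3 levels."""
    keys = [{(c.chrom, c.pos, c.alt_base) for c in cs} for cs in callsets]
    all_calls: dict[tuple, int] = {}
    for ks in keys:
        for k in ks:
            all_calls[k] = all_calls.get(k, 0) + 1
    truth_keys = {(r.chrom, r.pos, r.alt) for r in truth_df.itertuples()}
    n_reps = len(callsets)
    counts = {f"calls_in_{i}": sum(1 for v in all_calls.values() if v == i) for i in range(1, n_reps + 1)}
    for level in range(1, n_reps + 1):
        counts[f"truth_in_ge{level}"] = sum(
            1 for k in truth_keys if all_calls.get(k, 0) >= level
        )
    counts["false_calls"] = sum(1 for k in all_calls if k not in truth_keys)
    counts["n_truth"] = len(truth_keys)
    return counts


def write_vcf(calls: list[VariantCall], genomeA: Genome, path: str | Path) -> None:
    """Minimal VCF 4.2 with GT 0/1 and DP/AD per call."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=capbias-caller\n")
        for name, seq in genomeA.chromosomes.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tF1\n")
        for c in calls:
            ref_depth = c.depth - c.alt_count
            fh.write(
                f"{c.chrom}\t{c.pos + 1}\t.\t{c.ref_base}\t{c.alt_base}\t.\tPASS\t.\t"
                f"GT:DP:AD\t0/1:{c.depth}:{ref_depth},{c.alt_count}\n"
            )


def read_vcf_calls(path: str | Path) -> list[VariantCall]:
    calls = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            fmt = dict(zip(f[8].split(":"), f[9].split(":")))
            dp = int(fmt.get("DP", 0))
            ad = fmt.get("AD", "0,0").split(",")
            calls.append(VariantCall(f[0], int(f[1]) - 1, f[3], f[4], dp, int(ad[1])))
    return calls
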