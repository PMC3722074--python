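"""Allelic-origin assignment, per-target counts, log2 bias ratios, and filters.

A read's allelic origin is decided from its dual mapping: discarded when it
multi-maps on either genome, the single mapped genome when only one side
maps, the smaller edit distance when both map, and ambiguous on a tie (no
allelic information — for error-free reads that is exactly the case of a
read covering no variant).  Per-target counts of A- vs B-origin reads give
the capture-bias statistic log2((count_A + c) / (count_B + c)).

Quantile outlier filters (simulation replicates and a WGS control) remove
targets whose ratios are extreme for reasons other than capture chemistry;
divergence-group summaries and the SNV-spacing analysis quantify how bias
grows with the number of SNVs/indels per target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from capbias.aligner import DualMapping, remove_duplicates, unique_only
from capbias.synthetic_genomes import Target

PSEUDOCOUNT = 0.5
REFERENCE_GROUP = (0, False)


# ---------------------------------------------------------------- origin assignment

def assign_allelic_origin(dm: DualMapping) -> str:
    """Origin of one read: 'A' | 'B' | 'ambiguous' | 'discarded'."""
    if dm.multi_A or dm.multi_B:
        return "discarded"
    if dm.best_A is None and dm.best_B is None:
        return "discarded"
    if dm.best_B is None:
        return "A"
    if dm.best_A is None:
        return "B"
    if dm.best_A.edit_distance < dm.best_B.edit_distance:
        return "A"
    if dm.best_A.edit_distance > dm.best_B.edit_distance:
        return "B"
    return "ambiguous"


def assign_origins(alnA: pd.DataFrame, alnB: pd.DataFrame) -> pd.DataFrame:
    """Batch origin assignment from per-genome alignment tables (map_readset output).

    Multi-mapping reads (n_best > 1 on either genome) are discarded outright;
    the remaining unique records are deduplicated per genome (PCR-duplicate
    rule), then merged.  Returns one row per surviving read with columns
    origin ('A'|'B'|'ambiguous'), and the placement on each mapped genome
    (chrom/pos/end/strand suffixed _A and _B; NaN where unmapped).
    """
    multi = set(alnA.loc[alnA["n_best"] > 1, "read_idx"]) | set(
        alnB.loc[alnB["n_best"] > 1, "read_idx"]
    )
    dedupA = remove_duplicates(unique_only(alnA))
    dedupB = remove_duplicates(unique_only(alnB))
    a = dedupA[~dedupA["read_idx"].isin(multi)].set_index("read_idx")
    b = dedupB[~dedupB["read_idx"].isin(multi)].set_index("read_idx")
    merged = a.join(b, how="outer", lsuffix="_A", rsuffix="_B")

    editA = merged["edit_A"].to_numpy(dtype=float)
    editB = merged["edit_B"].to_numpy(dtype=float)
    origin = np.full(len(merged), "ambiguous", dtype=object)
    origin[np.isnan(editB) & ~np.isnan(editA)] = "A"
    origin[np.isnan(editA) & ~np.isnan(editB)] = "B"
    both = ~np.isnan(editA) & ~np.isnan(editB)
    origin[both & (editA < editB)] = "A"
    origin[both & (editA > editB)] = "B"
    merged = merged.reset_index()
    merged["origin"] = origin
    return merged


# ---------------------------------------------------------------- per-target counting

def _interval_index(targets: list[Target], side: str):
    """Per-chromosome sorted (starts, ends, target row) arrays for one genome side."""
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for i, t in enumerate(targets):
        if side == "A":
            s, e = t.startA, t.endA
        else:
            if t.startB is None:
                raise ValueError(f"target {t.id} has no strain-B interval")
            s, e = t.startB, t.endB
        by_chrom.setdefault(t.chrom, []).append((s, e, i))
    out = {}
    for chrom, rows in by_chrom.items():
        rows.sort()
        arr = np.array(rows)
        out[chrom] = (arr[:, 0], arr[:, 1], arr[:, 2])
    return out


def _count_overlaps(
    reads: pd.DataFrame, index, n_targets: int, suffix: str = ""
) -> tuple[np.ndarray, int]:
    """Counts of reads overlapping each target by >=1 base, plus off-target count."""
    counts = np.zeros(n_targets, dtype=int)
    off_target = 0
    if reads.empty:
        return counts, 0
    ccol, pcol, ecol = "chrom" + suffix, "pos" + suffix, "end" + suffix
    for chrom, sub in reads.groupby(ccol):
        if chrom not in index:
            off_target += len(sub)
            continue
        starts, ends, idxs = index[chrom]
        p = sub[pcol].to_numpy(dtype=int)
        e = sub[ecol].to_numpy(dtype=int)
        j = np.searchsorted(starts, p, side="right") - 1
        hit0 = (j >= 0) & (p < ends[np.clip(j, 0, None)])
        jn = j + 1
        hit1 = (jn < len(starts)) & (starts[np.clip(jn, None, len(starts) - 1)] < e)
        any_hit = hit0 | hit1
        off_target += int((~any_hit).sum())
        if hit0.any():
            counts += np.bincount(idxs[j[hit0]], minlength=n_targets)
        if hit1.any():
            counts += np.bincount(idxs[jn[hit1]], minlength=n_targets)
    return counts, off_target


def log2_ratio(count_a, count_b, c: float = PSEUDOCOUNT):
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.log2(
            (np.asarray(count_a, dtype=float) + c) / (np.asarray(count_b, dtype=float) + c)
        )


def count_reads_per_target(
    origins: pd.DataFrame, targets: list[Target], pseudocount: float = PSEUDOCOUNT
) -> pd.DataFrame:
    """Per-target allele-specific read counts and log2 bias ratio.

    A-origin reads are matched against the targets' strain-A (extended)
    intervals, B-origin reads against the strain-B intervals; ambiguous reads
    carry no allelic information and count to neither.  Returns a DataFrame
    indexed by target id with count_A, count_B, sum, log2_ratio and the
    off-target assigned-read count in .attrs["off_target"].
    """
    idxA = _interval_index(targets, "A")
    idxB = _interval_index(targets, "B")
    a_reads = origins[origins["origin"] == "A"]
    b_reads = origins[origins["origin"] == "B"]
    countA, offA = _count_overlaps(a_reads, idxA, len(targets), "_A")
    countB, offB = _count_overlaps(b_reads, idxB, len(targets), "_B")
    df = pd.DataFrame(
        {
            "target_id": [t.id for t in targets],
            "nSNV": [t.nSNV for t in targets],
            "nIndel": [t.nIndel for t in targets],
            "count_A": countA,
            "count_B": countB,
        }
    ).set_index("target_id")
    df["sum"] = df["count_A"] + df["count_B"]
    df["log2_ratio"] = log2_ratio(df["count_A"], df["count_B"], pseudocount)
    df.attrs["off_target"] = offA + offB
    return df


# ---------------------------------------------------------------- outlier filters

def _ratio_quantile_flags(counts: pd.DataFrame, q_low: float, q_high: float) -> pd.Series:
    """Flag targets with log2_ratio outside the empirical [q_low, q_high] quantiles.

    Targets with no assigned reads (sum == 0) carry no ratio information and
    are never flagged (nor do they enter the quantile estimate).
    """
    informative = counts["sum"] > 0
    lo, hi = np.quantile(counts.loc[informative, "log2_ratio"], [q_low, q_high])
    return ((counts["log2_ratio"] < lo) | (counts["log2_ratio"] > hi)) & informative


def filter_outlier_targets_simulation(
    replicate_counts: list[pd.DataFrame], q_low: float = 0.005, q_high: float = 0.995
) -> tuple[pd.Index, pd.DataFrame]:
    """Discard targets flagged as ratio outliers in >= 2 of 3 unbiased replicates."""
    if len(replicate_counts) < 2:
        raise ValueError("need at least two replicate count tables")
    index = replicate_counts[0].index
    for c in replicate_counts[1:]:
        if not c.index.equals(index):
            raise ValueError("replicate count tables cover different target sets")
    flags = pd.DataFrame(
        {i: _ratio_quantile_flags(c, q_low, q_high) for i, c in enumerate(replicate_counts)}
    )
    n_flagged = flags.sum(axis=1)
    retained = index[n_flagged < 2]
    return retained, flags


def filter_outlier_targets_wgs(
    counts: pd.DataFrame,
    q_low: float = 0.005,
    q_high: float = 0.995,
    sum_cap: int | None = None,
) -> tuple[pd.Index, pd.Series]:
    """Discard ratio-quantile outliers or targets with total count above sum_cap.

    sum_cap=None uses the 99.5% quantile of per-target sums (scale-invariant
    analogue of the absolute cap used at full sequencing depth).
    """
    flags = _ratio_quantile_flags(counts, q_low, q_high)
    if sum_cap is None:
        informative = counts["sum"] > 0
        sum_cap = float(np.quantile(counts.loc[informative, "sum"], 0.995))
    flags = flags | (counts["sum"] > sum_cap)
    return counts.index[~flags], flags


# ---------------------------------------------------------------- group analyses

@dataclass
class BiasGroupSummary:
    nSNV: int
    has_indel: bool
    n_targets: int
    median: float
    q1: float
    q3: float
    p_value: float | None  # vs the (0 SNV, no indel) reference group


def test_group_difference(x, y) -> float:
    """Two-sided test that group x is shifted relative to group y.

    Mann-Whitney U in the regular case.  When one group is a point mass (the
    identical-sequence reference group of the simulation channel, where every
    read ties between the alleles and the pseudocount ratio is exactly 0),
    the MW asymptotic null is invalid — any spread in the other group rejects
    regardless of shift — so the comparison reduces to what U actually
    measures there: the exact sign test of the spread group against the
    reference constant.  Degenerate all-tied input gives p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both groups need >= 2 targets")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all observations tied; returning p = 1")
        return 1.0
    x_const = np.all(x == x[0])
    y_const = np.all(y == y[0])
    if x_const or y_const:
        spread, c = (y, x[0]) if x_const else (x, y[0])
        n_above = int((spread > c).sum())
        n_informative = int((spread != c).sum())
        if n_informative == 0:
            return 1.0
        return float(stats.binomtest(n_above, n_informative, 0.5).pvalue)
    return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def group_bias_by_divergence(
    counts: pd.DataFrame, max_snv: int | None = None
) -> list[BiasGroupSummary]:
    """Summaries of log2 ratios per (nSNV, has_indel) group with p vs (0, False).

    Expects a count table carrying nSNV/nIndel columns (count_reads_per_target
    restricted to retained targets).  Empty groups are omitted.
    """
    df = counts.copy()
    df["has_indel"] = df["nIndel"] > 0
    if max_snv is not None:
        df = df[df["nSNV"] <= max_snv]
    ref = df[(df["nSNV"] == 0) & (~df["has_indel"])]["log2_ratio"].to_numpy()
    out: list[BiasGroupSummary] = []
    for (nsnv, has_indel), sub in df.groupby(["nSNV", "has_indel"], sort=True):
        r = sub["log2_ratio"].to_numpy()
        if (nsnv, has_indel) == REFERENCE_GROUP or len(ref) < 2 or len(r) < 2:
            p = None
        else:
            p = test_group_difference(r, ref)
        q1, med, q3 = np.percentile(r, [25, 50, 75])
        out.append(BiasGroupSummary(int(nsnv), bool(has_indel), len(r), med, q1, q3, p))
    return out


def group_summary_frame(summaries: list[BiasGroupSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "nSNV": s.nSNV,
                "has_indel": s.has_indel,
                "n_targets": s.n_targets,
                "median": s.median,
                "q1": s.q1,
                "q3": s.q3,
                "p_value": s.p_value,
            }
            for s in summaries
        ]
    )


def snv_spacing_analysis(
    counts: pd.DataFrame,
    targets: list[Target],
    truth,
    bins: tuple = ((1, 1), (2, 10), (11, 30), (31, 60), (61, 10**9)),
) -> pd.DataFrame:
    """Median bias by SNV spacing among targets with exactly 2 SNVs and no indels.

    Spacing is the base distance between the two truth SNVs inside the
    extended target; each bin is compared to the largest populated spacing
    bin (Mann-Whitney, two-sided).
    """
    snv_pos: dict[str, list[int]] = {}
    for v in truth:
        if v.kind == "SNV":
            snv_pos.setdefault(v.chrom, []).append(v.pos)
    for ps in snv_pos.values():
        ps.sort()
    rows = []
    tmap = {t.id: t for t in targets}
    for tid, row in counts.iterrows():
        if row["nSNV"] != 2 or row["nIndel"] != 0 or tid not in tmap:
            continue
        t = tmap[tid]
        import bisect

        ps = snv_pos.get(t.chrom, [])
        i = bisect.bisect_left(ps, t.startA)
        j = bisect.bisect_left(ps, t.endA)
        inside = ps[i:j]
        if len(inside) != 2:
            continue
        rows.append((tid, inside[1] - inside[0], row["log2_ratio"]))
    if not rows:
        return pd.DataFrame(columns=["bin", "lo", "hi", "n_targets", "median", "p_value"])
    sp = pd.DataFrame(rows, columns=["target_id", "spacing", "log2_ratio"])
    per_bin = []
    for lo, hi in bins:
        sub = sp[(sp["spacing"] >= lo) & (sp["spacing"] <= hi)]
        if len(sub) == 0:
            continue
        per_bin.append(((lo, hi), sub["log2_ratio"].to_numpy()))
    out_rows = []
    ref = per_bin[-1][1] if per_bin else None
    for (lo, hi), vals in per_bin:
        if per_bin[-1][0] == (lo, hi) or len(vals) < 2 or ref is None or len(ref) < 2:
            p = None
        else:
            p = test_group_difference(vals, ref)
        out_rows.append(
            {
                "bin": f"{lo}-{hi if hi < 10**9 else ''}",
                "lo": lo,
                "hi": hi,
                "n_targets": len(vals),
                "median": float(np.median(vals)),
                "p_value": p,
            }
        )
    return pd.DataFrame(out_rows)


# ---------------------------------------------------------------- depth

def compute_depth(
    alignments: pd.DataFrame, chrom: str, start: int, end: int, suffix: str = ""
) -> tuple[np.ndarray, float]:
    """Per-position read-overlap counts on [start, end) and their mean."""
    depth = np.zeros(end - start, dtype=int)
    ccol, pcol, ecol = "chrom" + suffix, "pos" + suffix, "end" + suffix
    sub = alignments[alignments[ccol] == chrom]
    p = np.clip(sub[pcol].to_numpy(dtype=int) - start, 0, end - start)
    e = np.clip(sub[ecol].to_numpy(dtype=int) - start, 0, end - start)
    delta = np.zeros(end - start + 1, dtype=int)
    np.add.at(delta, p, 1)
    np.add.at(delta, e, -1)
    depth = delta[:-1].cumsum()
    return depth, float(depth.mean()) if len(depth) else 0.0


def mean_depth_over_targets(
    alignments: pd.DataFrame, targets: list[Target], *, core_pad: int = 0, suffix: str = ""
) -> float:
    """Mean depth pooled over all target positions (optionally shrunk by core_pad)."""
    total = 0
    n_pos = 0
    by_chrom: dict[str, list[Target]] = {}
    for t in targets:
        by_chrom.setdefault(t.chrom, []).append(t)
    for chrom, ts in by_chrom.items():
        sub = alignments[alignments["chrom" + suffix] == chrom]
        if sub.empty:
            n_pos += sum(t.endA - t.startA - 2 * core_pad for t in ts)
            continue
        L = max(int(sub["end" + suffix].max()), max(t.endA for t in ts)) + 1
        delta = np.zeros(L + 1, dtype=np.int64)
        np.add.at(delta, sub["pos" + suffix].to_numpy(dtype=int), 1)
        np.add.at(delta, sub["end" + suffix].to_numpy(dtype=int), -1)
        cov = delta[:-1].cumsum()
        for t in ts:
            lo, hi = t.startA + core_pad, t.endA - core_pad
            total += int(cov[lo:hi].sum())
            n_pos += hi - lo
    return total / n_pos if n_pos else 0.0
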