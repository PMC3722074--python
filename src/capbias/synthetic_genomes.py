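"""Synthetic divergent genome pair, truth variants, liftover, and capture targets.

Emulates the C57BL/6J (strain A) vs SPRET/EiJ (strain B) setting at desk
scale: strain B is derived from strain A by applying SNVs and short indels
at configurable rates, with the exact variant table and an A→B coordinate
liftover kept as ground truth.  Capture targets are 120-bp non-overlapping
intervals on strain A.

All coordinates are 0-based half-open; only VCF output is 1-based.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace

import numpy as np

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


@dataclass
class Genome:
    """A set of named chromosome sequences over {A,C,G,T,N} for one strain."""

    strain_label: str
    chromosomes: dict[str, str]

    def validate(self) -> None:
        if len(self.chromosomes) == 0:
            raise ConfigurationError("genome has no chromosomes")
        for name, seq in self.chromosomes.items():
            if len(seq) < 1:
                raise ConfigurationError(f"chromosome {name} is empty")
            if set(seq) - set("ACGTN"):
                raise ConfigurationError(f"chromosome {name} has bases outside ACGTN")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())


@dataclass(frozen=True)
class TruthVariant:
    """A strain-B variant in strain-A coordinates (anchored VCF-style alleles)."""

    chrom: str
    pos: int  # 0-based position of ref_allele[0] on strain A
    kind: str  # "SNV" | "insertion" | "deletion"
    ref_allele: str
    alt_allele: str

    @property
    def ref_span(self) -> int:
        return len(self.ref_allele)


@dataclass
class LiftoverMap:
    """Piecewise-constant offset map from strain-A to strain-B coordinates.

    Each chromosome holds parallel arrays (a_starts, a_ends, offsets): for a
    non-deleted A position p with a_starts[i] <= p < a_ends[i], the B position
    is p + offsets[i].  Positions deleted in B fall in no segment.
    """

    segments: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]

    def a_to_b(self, chrom: str, pos: int) -> int | None:
        starts, ends, offs = self.segments[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i < 0 or pos >= ends[i]:
            return None  # deleted in strain B
        return pos + int(offs[i])

    def b_to_a(self, chrom: str, pos_b: int) -> int | None:
        starts, ends, offs = self.segments[chrom]
        for i in range(len(starts)):
            if starts[i] + offs[i] <= pos_b < ends[i] + offs[i]:
                return pos_b - int(offs[i])
        return None

    def map_interval(self, chrom: str, start: int, end: int) -> tuple[int, int] | None:
        """Map a half-open A interval to B, clipping endpoints inward past deletions."""
        b_lo = None
        for p in range(start, end):
            b_lo = self.a_to_b(chrom, p)
            if b_lo is not None:
                break
        b_hi = None
        for p in range(end - 1, start - 1, -1):
            b_hi = self.a_to_b(chrom, p)
            if b_hi is not None:
                break
        if b_lo is None or b_hi is None:
            return None
        return b_lo, b_hi + 1


@dataclass
class Target:
    """A capture interval on strain A with its strain-B ortholog and divergence."""

    id: str
    chrom: str
    startA: int
    endA: int
    startB: int | None = None
    endB: int | None = None
    nSNV: int = -1  # -1 = not yet annotated
    nIndel: int = -1
    extended: bool = False

    @property
    def lengthA(self) -> int:
        return self.endA - self.startA

    @property
    def lengthB(self) -> int:
        if self.startB is None or self.endB is None:
            raise ValueError(f"target {self.id} has no strain-B interval")
        return self.endB - self.startB


@dataclass
class DivergenceConfig:
    """Rates of the strain-B mutation process.

    The "spretus-like" defaults aim at the genome-wide SNV:indel ratio of the
    SPRET/EiJ vs C57BL/6J comparison (roughly 1 SNV per 70 bp and 1 indel per
    550 bp genome-wide), with geometric indel lengths of mean 2.  A fraction
    of 2-kb blocks is fully conserved, reproducing the large identical-target
    class seen in real exomes (coding regions are not uniformly divergent).
    """

    snv_rate: float = 1.0 / 70.0
    indel_rate: float = 1.0 / 550.0
    indel_length_mean: float = 2.0
    conserved_fraction: float = 0.3
    conserved_block: int = 2000
    seed: int = 0

    def validate(self) -> None:
        for name in ("snv_rate", "indel_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 0.2:
                raise ConfigurationError(f"{name}={r} outside [0, 0.2]")
        if self.indel_length_mean < 1.0:
            raise ConfigurationError("indel_length_mean must be >= 1")
        if not 0.0 <= self.conserved_fraction < 1.0:
            raise ConfigurationError("conserved_fraction must be in [0, 1)")


def generate_base_genome(
    n_chrom: int, chrom_length: int, gc: float, seed: int, *, strain_label: str = "A"
) -> Genome:
    """Generate i.i.d. random chromosomes with the given GC fraction."""
    if n_chrom < 1:
        raise ConfigurationError("n_chrom must be >= 1")
    if chrom_length < 1000:
        raise ConfigurationError("chrom_length must be >= 1000")
    if not 0.0 < gc < 1.0:
        raise ConfigurationError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    chroms: dict[str, str] = {}
    base_arr = np.frombuffer(b"ACGT", dtype="S1")
    for c in range(n_chrom):
        codes = rng.choice(4, size=chrom_length, p=p)
        chroms[f"chr{c + 1}"] = base_arr[codes].tobytes().decode()
    g = Genome(strain_label=strain_label, chromosomes=chroms)
    g.validate()
    return g


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in BASES if b != base]
    return choices[rng.integers(3)]


def derive_divergent_genome(
    base: Genome, cfg: DivergenceConfig
) -> tuple[Genome, list[TruthVariant], LiftoverMap]:
    """Apply a random SNV/indel process to strain A, returning strain B plus truth.

    Events whose strain-A footprints would overlap are resolved by keeping the
    earlier event; the realized rates are then marginally below the nominal
    ones (negligibly so at the default densities).
    """
    base.validate()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    chroms_b: dict[str, str] = {}
    truth: list[TruthVariant] = []
    segments: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    for chrom, seq in base.chromosomes.items():
        L = len(seq)
        # conserved-block mask: 1 = mutable
        n_blocks = (L + cfg.conserved_block - 1) // cfg.conserved_block
        block_mut = rng.random(n_blocks) >= cfg.conserved_fraction
        mask = np.repeat(block_mut, cfg.conserved_block)[:L]

        u = rng.random(L)
        snv_pos = np.nonzero((u < cfg.snv_rate) & mask)[0]
        u2 = rng.random(L)
        indel_pos = np.nonzero((u2 < cfg.indel_rate) & mask)[0]
        indel_is_ins = rng.random(indel_pos.size) < 0.5
        p_geom = min(1.0, 1.0 / cfg.indel_length_mean)
        indel_len = rng.geometric(p_geom, size=indel_pos.size)

        events: list[tuple[int, str, int]] = [(int(p), "SNV", 1) for p in snv_pos]
        for p, is_ins, ln in zip(indel_pos, indel_is_ins, indel_len):
            if is_ins:
                events.append((int(p), "insertion", int(ln)))
            else:
                events.append((int(p), "deletion", int(ln)))
        events.sort()

        variants: list[TruthVariant] = []
        prev_end = 1  # keep position 0 clean so anchored indels always have an anchor
        for pos, kind, ln in events:
            footprint = 1 if kind in ("SNV", "insertion") else 1 + ln
            if pos < prev_end or pos + footprint > L - 1:
                continue  # overlap with previous event or too close to chromosome end
            if kind == "SNV":
                ref = seq[pos]
                if ref == "N":
                    continue
                variants.append(TruthVariant(chrom, pos, "SNV", ref, _other_base(rng, ref)))
            elif kind == "insertion":
                ref = seq[pos]
                if ref == "N":
                    continue
                ins = "".join(BASES[rng.integers(4)] for _ in range(ln))
                variants.append(TruthVariant(chrom, pos, "insertion", ref, ref + ins))
            else:
                ref = seq[pos : pos + 1 + ln]
                if "N" in ref:
                    continue
                variants.append(TruthVariant(chrom, pos, "deletion", ref, seq[pos]))
            prev_end = pos + footprint
        truth.extend(variants)

        chroms_b[chrom] = _apply_variants(seq, variants)
        segments[chrom] = _build_liftover_segments(L, variants)

    genome_b = Genome(strain_label="B", chromosomes=chroms_b)
    genome_b.validate()
    truth.sort(key=lambda v: (v.chrom, v.pos))
    return genome_b, truth, LiftoverMap(segments)


def _apply_variants(seq: str, variants: list[TruthVariant]) -> str:
    parts: list[str] = []
    cursor = 0
    for v in variants:
        parts.append(seq[cursor : v.pos])
        parts.append(v.alt_allele)
        cursor = v.pos + v.ref_span
    parts.append(seq[cursor:])
    return "".join(parts)


def _build_liftover_segments(
    L: int, variants: list[TruthVariant]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    starts: list[int] = []
    ends: list[int] = []
    offs: list[int] = []
    seg_start = 0
    offset = 0
    for v in variants:
        if v.kind == "SNV":
            continue
        if v.kind == "insertion":
            # positions <= v.pos keep current offset; positions > v.pos shift
            cut = v.pos + 1
            delta = len(v.alt_allele) - 1
        else:  # deletion: positions v.pos+1 .. v.pos+dlen have no image
            cut = v.pos + 1
            delta = -(len(v.ref_allele) - 1)
        starts.append(seg_start)
        ends.append(cut)
        offs.append(offset)
        offset += delta
        seg_start = cut if v.kind == "insertion" else v.pos + v.ref_span
    starts.append(seg_start)
    ends.append(L)
    offs.append(offset)
    return np.asarray(starts), np.asarray(ends), np.asarray(offs)


def define_targets(
    genome: Genome,
    n_targets: int,
    target_length: int = 120,
    min_gap: int = 250,
    seed: int = 0,
    *,
    margin: int = 150,
) -> list[Target]:
    """Place non-overlapping capture targets uniformly at random on strain A.

    A `margin` is kept free at both chromosome ends so the later 100-nt
    extension never crosses a boundary.  Raises ConfigurationError when the
    requested packing does not fit.
    """
    genome.validate()
    if n_targets == 0:
        return []
    if n_targets < 0 or target_length < 1:
        raise ConfigurationError("n_targets and target_length must be positive")
    rng = np.random.default_rng(seed)
    names = list(genome.chromosomes)
    lengths = np.array([len(genome.chromosomes[c]) for c in names], dtype=float)
    # allocate per chromosome proportionally to length (largest remainder)
    quota = lengths / lengths.sum() * n_targets
    alloc = np.floor(quota).astype(int)
    rem = n_targets - alloc.sum()
    for i in np.argsort(-(quota - alloc))[:rem]:
        alloc[i] += 1

    targets: list[Target] = []
    for c, k in zip(names, alloc):
        if k == 0:
            continue
        L = len(genome.chromosomes[c])
        usable = L - 2 * margin
        need = k * target_length + (k - 1) * min_gap
        if need > usable:
            raise ConfigurationError(
                f"cannot place {k} targets of {target_length} bp with gap {min_gap} on {c} ({L} bp)"
            )
        slack = usable - need
        extra = np.sort(rng.integers(0, slack + 1, size=k))
        starts = margin + extra + np.arange(k) * (target_length + min_gap)
        for s in starts:
            targets.append(Target(id="", chrom=c, startA=int(s), endA=int(s) + target_length))
    targets.sort(key=lambda t: (t.chrom, t.startA))
    for i, t in enumerate(targets):
        t.id = f"t{i:05d}"
    return targets


def count_variants_in_intervals(
    truth: list[TruthVariant], targets: list[Target], *, use_core: bool = False, core_pad: int = 100
) -> list[tuple[int, int]]:
    """Per-target (nSNV, nIndel) counts of truth variants with pos in [startA, endA).

    With use_core=True, counts are taken on the interval shrunk by `core_pad`
    on each side (undoing the capture-context extension).
    """
    by_chrom: dict[str, list[TruthVariant]] = {}
    for v in truth:
        by_chrom.setdefault(v.chrom, []).append(v)
    for vs in by_chrom.values():
        vs.sort(key=lambda v: v.pos)
    pos_by_chrom = {c: [v.pos for v in vs] for c, vs in by_chrom.items()}
    out: list[tuple[int, int]] = []
    for t in targets:
        lo, hi = t.startA, t.endA
        if use_core:
            lo, hi = lo + core_pad, hi - core_pad
        vs = by_chrom.get(t.chrom, [])
        positions = pos_by_chrom.get(t.chrom, [])
        i = bisect.bisect_left(positions, lo)
        j = bisect.bisect_left(positions, hi)
        n_snv = sum(1 for v in vs[i:j] if v.kind == "SNV")
        n_indel = (j - i) - n_snv
        out.append((n_snv, n_indel))
    return out


def annotate_target_divergence(targets: list[Target], truth: list[TruthVariant]) -> list[Target]:
    """Set nSNV/nIndel on each (extended) target from the truth table."""
    for t in targets:
        if not t.extended:
            raise ValueError(f"target {t.id} not extended; annotate after extension")
    counts = count_variants_in_intervals(truth, targets)
    out = []
    for t, (ns, ni) in zip(targets, counts):
        out.append(replace(t, nSNV=ns, nIndel=ni))
    return out
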