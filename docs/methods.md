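# Methods

## Study design

The package evaluates allele-specific hybridization-capture bias the way one
would in an F1 hybrid resequencing experiment, but on synthetic parental
genomes so that every read, variant and interval has a known truth. The
stages, in pipeline order:

1. **Genome pair.** Strain A is an i.i.d. random genome at a configurable GC
   fraction. Strain B is derived from A by a stochastic mutation process;
   the variant table (VCF-style anchored alleles, strain-A coordinates) and
   a piecewise-offset A→B liftover are retained as ground truth.
2. **Targets and orthology.** 120-bp capture intervals are placed without
   overlap on strain A, then located on strain B by aligning each target's
   sequence (seed-and-extend, full-chromosome scan fallback). Retention
   filters: unique placement on the same-named chromosome; collinear
   5'→3' order (longest strictly increasing subsequence of B starts per
   chromosome — the global-consistent formalization of local synteny);
   100-nt extension on both sides in each genome's own coordinates, dropping
   targets whose extension crosses a chromosome end or touches an N.
3. **Read simulation.** Single-end, error-free, Q40 reads of 101 nt. A
   source (target, allele) is chosen with probability proportional to its
   extended interval length times `exp(−β_snv·nSNV − β_indel·nIndel)` for
   the B allele; the start is uniform over the positions where the read fits
   inside the extended interval; the strand is a fair coin. β = (0, 0)
   reproduces plain length-proportional sampling and serves as the control
   channel; a uniform whole-genome channel provides an orthogonal control.
4. **Mapping and origin assignment.** Reads map to both genomes with a
   seed-and-extend aligner (4 non-overlapping 20-mers per strand; banded
   edit-distance extension with cap 5). Reads that multi-map on either
   genome are discarded; per genome, unique records sharing (chromosome,
   leftmost position, strand) collapse to one (PCR-duplicate rule); the
   allelic origin is the genome with the smaller edit distance, with ties
   unassignable.
5. **Bias statistics and filters.** Per-target counts of A- vs B-origin
   reads give `log2((n_A+0.5)/(n_B+0.5))`. Targets with ratios outside the
   [0.5%, 99.5%] quantiles in ≥2 of 3 unbiased replicates, or outside the
   quantiles / above the total-count cap in the WGS channel, are excluded.
   Ratios are then summarized per (nSNV, has_indel) group and per SNV-spacing
   bin among 2-SNV targets.
6. **Mapping-bias filter and sensitivity.** Each target's read count under
   dual-genome mapping is compared with strain-A-only mapping in the three
   unbiased replicates; only targets with identical counts in all three are
   kept for variant analysis. A pileup caller on strain-A alignments calls
   heterozygous SNVs; reads are Bernoulli-subsampled to a grid of mean
   depths (default 10…80) and sensitivity is the fraction of truth SNVs
   recovered, per target-divergence group.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `snv_rate` | 1/70 per bp | strain-B SNV density inside mutable blocks |
| `indel_rate` | 1/550 per bp | indel density; geometric lengths, mean 2 |
| `conserved_fraction` | 0.3 | fraction of 2-kb blocks with no variants |
| `n_targets`, `target_length` | 600, 120 bp | capture design, desk scale |
| `n_reads` | 300,000 / replicate | exome channel depth (~140x core) |
| `read_length` | 101 nt | single-end read length |
| `beta_snv`, `beta_indel` | 0 (control) | capture penalty per variant on the B allele |
| `max_edit` | 5 | aligner edit cap; creates the >5-edit mappability cliff |
| `seed_k` | 20 | aligner seed length (4 seeds per strand) |
| `q_low`, `q_high` | 0.005, 0.995 | outlier-filter ratio quantiles |
| `min_depth/min_alt_count/min_alt_fraction` | 5 / 3 / 0.2 | het caller thresholds |
| `depth_grid` | 10…80 | subsampling grid for the sensitivity analysis |

The divergence preset targets the genome-wide SNV:indel ratio of a highly
divergent wild-derived strain against the reference strain (about one SNV
per 70 bp and one indel per 550 bp). The conserved-block mixture reproduces
the large identical-target class seen in real capture designs (exons are not
uniformly divergent); without it, essentially no target would be
variant-free and the identical-sequence reference group of the bias analysis
would be empty. With these defaults the per-target nSNV histogram has its
mode at 0 and support up to ~15–20 over 320-bp extended targets.

The caller thresholds put a balanced heterozygote at mean depth 10 in the
~80–95% detection regime, so the depth-10 end of the grid is informative
about capture bias rather than saturated.

## Numerical and procedural choices

- **Coordinates** are 0-based half-open everywhere; only VCF output is
  1-based. A variant "belongs" to an interval when its anchor position lies
  inside it.
- **Edit distances** are unit-cost Levenshtein, computed by banded
  semiglobal alignment (edlib) during mapping. Equal-score placements whose
  starts differ by at most half a read length on the same strand are one
  locus (optimal alignments are ambiguous by a few bases around indels; a
  conventional aligner reports one locus, and without merging essentially
  every indel-spanning read would be discarded as multi-mapping).
- **Degenerate reference group.** In the simulation channel every read from
  an identical-sequence target ties between the genomes, so that group's
  ratios are a point mass at 0 (its read counts are 0 on both sides and
  excluded from MA/quantile analyses, but the group itself is the natural
  bias-free reference). Mann–Whitney's asymptotic null is invalid against a
  point mass — any spread in the other group rejects regardless of shift —
  so group comparisons fall back to the exact sign test against the
  reference constant in that case.
- **Indel-adjacent SNVs.** The unit-cost optimal alignment of an
  indel-carrying read is not unique, and a raw alignment path can absorb an
  adjacent SNV into the gap, hiding its alt evidence from the pileup. Reads
  whose window length differs from the read length are therefore realigned
  with a leftmost single-gap placement (all gap positions enumerated via
  prefix/suffix mismatch sums; fewest substitutions wins, leftmost on ties)
  — the desk-scale stand-in for indel realignment. Reads spanning two
  separate indels keep the raw path.
- **Core vs extended intervals.** Capture-bias analyses annotate divergence
  on the extended (320-bp) interval, which is what the capture weight acts
  on. Variant-detection truth sets and mean-depth normalization use the
  120-bp core probe interval: simulated reads never start outside the
  extension window, so flank coverage decays linearly to ~1 read at the
  edges and flank SNVs are uncallable at any depth, whereas core positions
  are uniformly covered.
- **Sensitivity trend test.** The capture-bias effect on depth-10
  sensitivity is assessed on per-SNV detection rates (averaged over 10
  subsample seeds) with a one-sided Spearman trend against the target's SNV
  count. Individual (1-SNV vs 4-SNV) group contrasts are reported but not
  tested: at desk scale the smallest groups hold a handful of SNVs, and
  repeated subsample seeds are not independent evidence about a fixed truth
  set.
- **Ties and determinism.** Duplicate removal keeps the smallest read
  index; target ids are assigned in (chromosome, start) order; all
  randomness flows from explicit seeds, and rerunning a configuration
  reproduces every output byte for byte.
- **Event collisions** in the mutation process (overlapping footprints on
  strain A) are resolved by keeping the earlier event; at the default
  densities this perturbs realized rates by well under 2%.
- **Reads running off a chromosome** cannot arise in synthetic mode
  (targets keep a margin ≥ the extension from chromosome ends); in real
  mode the simulator resamples the start within the same source.

## What the generator emulates — and what it does not

The generator reproduces the features the analysis actually exercises:
divergence-dependent allelic composition per target, indel-induced
coordinate offsets between the genomes, an identical-target class, a
length-proportional unbiased capture null, and a tunable capture-bias
ground truth. It does **not** model sequencing errors or quality decay
(reads are error-free Q40 by design, matching the evaluated simulation
protocol), GC- or fragment-length-dependent coverage, repeat structure or
segmental duplication, PCR duplicates (injected only as test fixtures), or
paired-end structure. Passing tests therefore demonstrate correctness of
the pipeline's accounting and inference under the stated read model — not
robustness to base-call noise or repeat-driven mismapping in real data.

## Problem sizes

The default configuration — 2 chromosomes x 400 kb, 600 targets, three
300k-read replicates per channel, one 300k-read WGS control — was chosen so
that a full study runs in minutes on a single CPU while every divergence
group up to 6 SNVs retains tens of targets. The acceptance script runs this
configuration; the test suite reuses the same scale for end-to-end checks
and smaller worlds (60 kb–100 kb, tens of targets) for unit fixtures.

## Known limitations

- The aligner guarantees detection of placements with ≤3 edits (pigeonhole
  over four 20-mer seeds) and finds 4–5-edit placements with near-certainty;
  a conventional aligner's exact multi-mapping and clipping behavior is not
  reproduced.
- The caller is a fixed-threshold pileup genotyper; its absolute
  sensitivities are comparable in shape, not in value, to a production
  caller with realignment and recalibration.
- Orthology placement uses full-length alignment with an edit budget of 25%
  of the target length, not BLAST statistics; targets whose true ortholog
  diverges beyond that budget are reported unmapped.
- With indels near interval edges, the aligner-derived strain-B interval
  can differ from the liftover image by a few bases (optimal alignment ends
  are ambiguous there); bias counting is overlap-based and insensitive to
  this.
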