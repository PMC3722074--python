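# capbias

Allele-specific hybridization-capture bias evaluation for F1 hybrid exome
sequencing, on fully synthetic diploid genomes.

## The problem

Exome capture kits are designed against one reference genome. When such a kit
is applied to an F1 hybrid of two divergent inbred strains (the motivating
setting: a C57BL/6J x SPRET/EiJ mouse, whose parental genomes differ by tens
of millions of SNVs and indels), two distinct artifacts skew allele-specific
measurements:

- **capture bias** — probes designed on strain A hybridize less efficiently
  to strain-B fragments, so divergent targets are depleted of B-allele reads;
- **mapping bias** — aligning reads against the strain-A reference silently
  loses B-allele reads that carry too many mismatches, which confounds any
  attempt to measure capture bias and depresses variant-calling sensitivity.

`capbias` reimplements the evaluation pipeline for this setting end to end at
desk scale, with every input simulated and therefore a complete ground truth:
a strain-A genome, a derived strain-B genome with a truth variant table and
coordinate liftover, 120-nt capture targets with one-to-one orthologous
strain-B intervals, single-end 101-nt capture reads with an optional
parametric capture-bias model, dual-genome read mapping with edit-distance
allelic-origin assignment, per-target bias statistics, and a pileup-based
heterozygous SNV caller with depth subsampling.

## The statistics at the core

Per retained target, reads are assigned an allelic origin by comparing edit
distances against both parental genomes (ties are unassignable), and the
capture-bias statistic is

```
M = log2((n_A + c) / (n_B + c)),   c = 0.5
```

plotted/filtered against the per-target total `n_A + n_B` (MA layout).
The read simulator draws each read from source (target *t*, allele *s*) with
probability

```
P(t, s)  ∝  L(t, s) · exp(−β_snv·nSNV(t) − β_indel·nIndel(t))·[s = B]
```

where `L(t, s)` is the extended interval length; `β = 0` is the unbiased
control in which `P` is exactly length over cumulative length. The injected
model predicts a per-SNV log2 ratio shift of `β_snv / ln 2`, which the
pipeline recovers from the counts alone. Divergence groups `(nSNV,
has_indel)` are compared by two-sided Mann–Whitney U (exact sign test when
the reference group is degenerate); variant-detection sensitivity is the
fraction of truth SNVs recovered per mean-depth level after Bernoulli read
subsampling.

## Worked example

```python
from capbias.pipeline import ExperimentConfig, run_full_experiment

cfg = ExperimentConfig(beta_snv=0.15, beta_indel=0.3)   # inject capture bias
result = run_full_experiment(cfg, "report")
print(result["manifest"])
```

The default configuration (2 chromosomes x 400 kb, 600 targets, three
300k-read replicates per channel) finishes in a few minutes on one CPU and
writes every table as TSV plus FASTA/VCF/BED/SAM artifacts under `report/`.
Running the same study through `scripts/acceptance.py` (below) prints, among
others:

```
null_grand_median_log2_ratio            0.0     # unbiased control is centred
bias_recovered_log2_shift_per_snv       0.2167  # vs 0.2164 injected (0.15/ln2)
bias_median_log2_ratio_4snv_no_indel    0.8822  # 4-SNV targets, biased channel
pct_targets_free_of_mapping_bias        45.67   # two-strategy filter survivors
sensitivity_full_depth_pct              100.0   # saturating depth, unbiased
sensitivity_depth10_bias_1snv_pct       81.25   # capture bias at depth 10:
sensitivity_depth10_bias_4snv_pct       49.52   #   divergent targets suffer
```

The unbiased control shows no such depth-10 gap (90.0% vs 87.6%) — the
sensitivity loss is attributable to capture bias, not mapping.

A CLI mirrors the library (`capbias generate | simulate | map | orthology |
bias | mapfilter | call | sensitivity | run`); intermediate artifacts use
standard formats so external tools (BWA, samtools, bedtools) can be swapped
into any stage.

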