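"""End-to-end experiment orchestration from a single seeded configuration.

Stage order mirrors the study design: generate the divergent genome pair and
capture targets, establish target orthology, simulate exome replicates (a
capture-biased channel and an unbiased control channel) plus a WGS control,
dual-map every replicate, apply the simulation/WGS outlier filters, run the
capture-bias analyses, apply the two-strategy mapping-bias filter, and
finish with strain-A-only variant calling and the sensitivity-vs-depth grid.

Every stage logs its conservation counts (inputs = retained + dropped); the
run manifest records the config, seeds and package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from capbias import io as cbio
from capbias.aligner import GenomeIndex, map_readset
from capbias.allelic_bias import (
    count_reads_per_target,
    filter_outlier_targets_simulation,
    filter_outlier_targets_wgs,
    group_bias_by_divergence,
    group_summary_frame,
    mean_depth_over_targets,
    assign_origins,
    snv_spacing_analysis,
)
from capbias.mapping_bias_filter import count_mapped_two_strategies, retain_unbiased_targets
from capbias.read_simulator import BiasModel, simulate_exome_reads, simulate_wgs_reads
from capbias.synthetic_genomes import (
    DivergenceConfig,
    annotate_target_divergence,
    define_targets,
    generate_base_genome,
    derive_divergent_genome,
)
from capbias.target_orthology import establish_orthology
from capbias.variant_analysis import (
    CallerParams,
    PileupEngine,
    call_het_snvs,
    compare_callsets,
    sensitivity_by_depth,
    truth_snvs_in_targets,
    write_vcf,
)

log = logging.getLogger("capbias")


@dataclass
class ExperimentConfig:
    # genomes
    n_chrom: int = 2
    chrom_length: int = 400_000
    gc: float = 0.42
    genome_seed: int = 11
    # divergence ("spretus-like" preset)
    snv_rate: float = 1.0 / 70.0
    indel_rate: float = 1.0 / 550.0
    indel_length_mean: float = 2.0
    conserved_fraction: float = 0.3
    divergence_seed: int = 13
    # targets
    n_targets: int = 600
    target_length: int = 120
    min_gap: int = 250
    target_seed: int = 7
    # simulation
    n_reads: int = 300_000
    read_length: int = 101
    replicates: int = 3
    sim_seeds: list[int] = field(default_factory=lambda: [101, 102, 103])
    beta_snv: float = 0.0
    beta_indel: float = 0.0
    wgs_reads: int = 300_000
    wgs_seed: int = 201
    # aligner
    seed_k: int = 20
    max_edit: int = 5
    # filters
    q_low: float = 0.005
    q_high: float = 0.995
    sum_cap: int | None = None
    # caller
    min_depth: int = 5
    min_alt_count: int = 3
    min_alt_fraction: float = 0.2
    # sensitivity
    depth_grid: list[float] = field(default_factory=lambda: [10, 20, 30, 40, 50, 60, 70, 80])
    subsample_seed: int = 301

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def validate_config(cfg: ExperimentConfig) -> list[str]:
    """Check config invariants; returns a list of violations (empty = ok)."""
    v: list[str] = []
    if not 0 < cfg.gc < 1:
        v.append("gc: must be in (0, 1)")
    if cfg.chrom_length < 1000:
        v.append("chrom_length: must be >= 1000")
    if not 0 <= cfg.snv_rate <= 0.2:
        v.append("snv_rate: must be in [0, 0.2]")
    if not 0 <= cfg.indel_rate <= 0.2:
        v.append("indel_rate: must be in [0, 0.2]")
    if cfg.q_low >= cfg.q_high:
        v.append("q_low/q_high: low quantile must be below high quantile")
    if not 0 <= cfg.q_low <= 1 and 0 <= cfg.q_high <= 1:
        v.append("q_low/q_high: quantiles must be in [0, 1]")
    if cfg.read_length < cfg.seed_k:
        v.append("read_length: must be >= aligner seed length k")
    if len(cfg.sim_seeds) < cfg.replicates:
        v.append("sim_seeds: need one seed per replicate")
    if cfg.beta_snv < 0 or cfg.beta_indel < 0:
        v.append("beta_snv/beta_indel: must be >= 0")
    if any(d <= 0 for d in cfg.depth_grid):
        v.append("depth_grid: depths must be positive")
    if cfg.max_edit < 0:
        v.append("max_edit: must be >= 0")
    return v


@dataclass
class ExperimentData:
    """Genomes, truth, targets and read/alignment tables shared across stages."""

    cfg: ExperimentConfig
    genomeA: object = None
    genomeB: object = None
    truth: list = None
    liftover: object = None
    orthology: object = None
    targets: list = None  # retained, extended, annotated
    indexA: object = None
    indexB: object = None


def prepare_genomes_and_targets(cfg: ExperimentConfig) -> ExperimentData:
    """Stages 1-2: genome pair, truth table, targets, orthology, annotation."""
    data = ExperimentData(cfg=cfg)
    data.genomeA = generate_base_genome(cfg.n_chrom, cfg.chrom_length, cfg.gc, cfg.genome_seed)
    dcfg = DivergenceConfig(
        snv_rate=cfg.snv_rate,
        indel_rate=cfg.indel_rate,
        indel_length_mean=cfg.indel_length_mean,
        conserved_fraction=cfg.conserved_fraction,
        seed=cfg.divergence_seed,
    )
    data.genomeB, data.truth, data.liftover = derive_divergent_genome(data.genomeA, dcfg)
    raw_targets = define_targets(
        data.genomeA, cfg.n_targets, cfg.target_length, cfg.min_gap, cfg.target_seed
    )
    data.orthology = establish_orthology(raw_targets, data.genomeA, data.genomeB)
    data.targets = annotate_target_divergence(data.orthology.retained, data.truth)
    log.info(
        "orthology: %d targets in, %d retained, %d dropped",
        len(raw_targets), len(data.targets), len(data.orthology.dropped),
    )
    data.indexA = GenomeIndex(data.genomeA, cfg.seed_k)
    data.indexB = GenomeIndex(data.genomeB, cfg.seed_k)
    return data


def simulate_and_map(
    data: ExperimentData, bias: BiasModel, seed: int
) -> tuple[object, pd.DataFrame, pd.DataFrame]:
    """One replicate: simulate exome reads and dual-map them."""
    cfg = data.cfg
    reads = simulate_exome_reads(
        data.targets, data.genomeA, data.genomeB, cfg.n_reads, cfg.read_length, bias, seed
    )
    alnA = map_readset(reads, data.indexA, cfg.max_edit)
    alnB = map_readset(reads, data.indexB, cfg.max_edit)
    log.info(
        "replicate seed=%d: %d reads, %d mapped A, %d mapped B", seed, len(reads), len(alnA), len(alnB)
    )
    return reads, alnA, alnB


def run_full_experiment(cfg: ExperimentConfig, outdir: str | Path) -> dict:
    """Run every stage and write the report directory; returns summary dict."""
    violations = validate_config(cfg)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    data = prepare_genomes_and_targets(cfg)
    cbio.write_fasta(data.genomeA, outdir / "strainA.fasta")
    cbio.write_fasta(data.genomeB, outdir / "strainB.fasta")
    cbio.write_truth_vcf(data.truth, data.genomeA, outdir / "truth.vcf")
    cbio.write_liftover_tsv(data.liftover, outdir / "liftover.tsv")
    cbio.write_targets_bed(data.targets, outdir / "targets_retained.bed")
    pd.DataFrame(
        [(tid, reason) for tid, reason in sorted(data.orthology.dropped.items())],
        columns=["target_id", "reason"],
    ).to_csv(outdir / "targets_dropped.tsv", sep="\t", index=False)

    # --- simulation channels -------------------------------------------------
    biased = BiasModel(cfg.beta_snv, cfg.beta_indel)
    has_bias = cfg.beta_snv > 0 or cfg.beta_indel > 0
    unbiased_reps = []  # (reads, alnA, alnB) for control channel
    for r in range(cfg.replicates):
        unbiased_reps.append(simulate_and_map(data, BiasModel(), cfg.sim_seeds[r]))
    if has_bias:
        exome_reps = [
            simulate_and_map(data, biased, cfg.sim_seeds[r] + 7919)
            for r in range(cfg.replicates)
        ]
    else:
        exome_reps = unbiased_reps

    wgs_reads = simulate_wgs_reads(
        data.genomeA, data.genomeB, cfg.wgs_reads, cfg.read_length, cfg.wgs_seed
    )
    wgs_alnA = map_readset(wgs_reads, data.indexA, cfg.max_edit)
    wgs_alnB = map_readset(wgs_reads, data.indexB, cfg.max_edit)

    # --- per-target allele-specific counts ----------------------------------
    unbiased_counts = [
        count_reads_per_target(assign_origins(a, b), data.targets) for _, a, b in unbiased_reps
    ]
    exome_counts = (
        [count_reads_per_target(assign_origins(a, b), data.targets) for _, a, b in exome_reps]
        if has_bias
        else unbiased_counts
    )
    wgs_counts = count_reads_per_target(assign_origins(wgs_alnA, wgs_alnB), data.targets)

    for i, c in enumerate(unbiased_counts, 1):
        c.to_csv(outdir / f"counts_simulation{i}.tsv", sep="\t", float_format="%.6g")
    for i, c in enumerate(exome_counts, 1):
        c.to_csv(outdir / f"counts_exome{i}.tsv", sep="\t", float_format="%.6g")
    wgs_counts.to_csv(outdir / "counts_wgs.tsv", sep="\t", float_format="%.6g")

    # --- outlier filters (simulation replicates + WGS control) --------------
    sim_retained, sim_flags = filter_outlier_targets_simulation(
        unbiased_counts, cfg.q_low, cfg.q_high
    )
    wgs_retained, wgs_flags = filter_outlier_targets_wgs(
        wgs_counts, cfg.q_low, cfg.q_high, cfg.sum_cap
    )
    analysis_ids = sim_retained.intersection(wgs_retained)
    flags = pd.DataFrame(
        {
            "sim_outlier": (~pd.Index(wgs_counts.index).isin(sim_retained)),
            "wgs_outlier": (~pd.Index(wgs_counts.index).isin(wgs_retained)),
        },
        index=wgs_counts.index,
    )
    flags.to_csv(outdir / "filter_flags.tsv", sep="\t")
    log.info(
        "outlier filters: %d targets in, %d retained (%d sim-dropped, %d wgs-dropped)",
        len(data.targets), len(analysis_ids),
        int(flags["sim_outlier"].sum()), int(flags["wgs_outlier"].sum()),
    )

    # --- capture-bias analyses (first exome replicate) ------------------------
    bias_counts = exome_counts[0].loc[analysis_ids]
    ma = bias_counts[["sum", "log2_ratio"]].copy()
    ma.to_csv(outdir / "ma_exome1.tsv", sep="\t", float_format="%.6g")
    summaries = group_bias_by_divergence(bias_counts)
    group_df = group_summary_frame(summaries)
    group_df.to_csv(outdir / "bias_groups_exome1.tsv", sep="\t", index=False, float_format="%.6g")
    retained_targets = [t for t in data.targets if t.id in set(analysis_ids)]
    spacing = snv_spacing_analysis(bias_counts, retained_targets, data.truth)
    spacing.to_csv(outdir / "snv_spacing_exome1.tsv", sep="\t", index=False, float_format="%.6g")

    # --- mapping-bias filter (unbiased replicates) ---------------------------
    strategy_counts = [
        count_mapped_two_strategies(a, b, data.targets) for _, a, b in unbiased_reps
    ]
    for i, c in enumerate(strategy_counts, 1):
        c.to_csv(outdir / f"strategy_counts_sim{i}.tsv", sep="\t")
    mapfree_ids = retain_unbiased_targets(strategy_counts)
    log.info(
        "mapping-bias filter: %d targets in, %d retained", len(data.targets), len(mapfree_ids)
    )
    call_targets = [t for t in data.targets if t.id in set(mapfree_ids)]
    cbio.write_targets_bed(call_targets, outdir / "targets_mapfree.bed")

    # --- variant calling + sensitivity ---------------------------------------
    params = CallerParams(cfg.min_depth, cfg.min_alt_count, cfg.min_alt_fraction)
    core_pad = 100
    core_intervals = [
        (t.chrom, t.startA + core_pad, t.endA - core_pad) for t in call_targets
    ]
    truth_df = truth_snvs_in_targets(data.truth, call_targets, core_pad)

    from capbias.aligner import remove_duplicates, unique_only

    callsets = []
    sens_df = None
    for r, (reads, alnA, _) in enumerate(exome_reps, 1):
        dedupA = remove_duplicates(unique_only(alnA))
        engine = PileupEngine(dedupA, reads, data.genomeA)
        counts_full = engine.counts()
        calls = call_het_snvs(counts_full, data.genomeA, core_intervals, params)
        callsets.append(calls)
        write_vcf(calls, data.genomeA, outdir / f"calls_exome{r}.vcf")
        if r == 1:
            current = mean_depth_over_targets(dedupA, call_targets, core_pad=core_pad)
            grid = [d for d in cfg.depth_grid if d <= current]
            sens_df = sensitivity_by_depth(
                engine, data.genomeA, truth_df, core_intervals, current,
                grid, params, cfg.subsample_seed,
            )
            sens_df.to_csv(outdir / "sensitivity.tsv", sep="\t", index=False, float_format="%.6g")
            log.info("sensitivity grid at mean depth %.1f: %d levels", current, len(grid))

    concordance = compare_callsets(callsets, truth_df)
    pd.Series(concordance).to_csv(outdir / "concordance.tsv", sep="\t", header=False)

    manifest = {
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(cfg.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "package_version": __import__("capbias").__version__,
        "n_targets_generated": cfg.n_targets,
        "n_targets_orthologous": len(data.targets),
        "n_targets_analysis": len(analysis_ids),
        "n_targets_mapfree": len(mapfree_ids),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return {
        "data": data,
        "unbiased_counts": unbiased_counts,
        "exome_counts": exome_counts,
        "wgs_counts": wgs_counts,
        "analysis_ids": analysis_ids,
        "group_summaries": summaries,
        "spacing": spacing,
        "strategy_counts": strategy_counts,
        "mapfree_ids": mapfree_ids,
        "sensitivity": sens_df,
        "concordance": concordance,
        "manifest": manifest,
    }
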