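"""Origin assignment, per-target counting, outlier filters and group statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from capbias.aligner import AlignmentRecord, DualMapping
from capbias.allelic_bias import (
    assign_allelic_origin,
    assign_origins,
    compute_depth,
    count_reads_per_target,
    filter_outlier_targets_simulation,
    filter_outlier_targets_wgs,
    group_bias_by_divergence,
    log2_ratio,
    snv_spacing_analysis,
    test_group_difference as group_difference,
)
from capbias.synthetic_genomes import Target


def _rec(genome, edit, pos=100):
    return AlignmentRecord("r", genome, "chr1", pos, pos + 101, "+", edit, True)


class TestOriginAssignment:
    def test_smaller_edit_distance_wins(self):
        dm = DualMapping("r", _rec("A", 0), _rec("B", 2))
        assert assign_allelic_origin(dm) == "A"
        dm = DualMapping("r", _rec("A", 3), _rec("B", 1))
        assert assign_allelic_origin(dm) == "B"

    def test_equal_edit_distance_ambiguous(self):
        assert assign_allelic_origin(DualMapping("r", _rec("A", 1), _rec("B", 1))) == "ambiguous"

    def test_single_genome_obvious(self):
        assert assign_allelic_origin(DualMapping("r", None, _rec("B", 1))) == "B"
        assert assign_allelic_origin(DualMapping("r", _rec("A", 4), None)) == "A"

    def test_multimapper_discarded(self):
        dm = DualMapping("r", None, _rec("B", 0), multi_A=True)
        assert assign_allelic_origin(dm) == "discarded"
        assert assign_allelic_origin(DualMapping("r", None, None)) == "discarded"

    def test_batch_assignment_matches_single(self):
        cols = ["read_idx", "chrom", "pos", "end", "strand", "edit", "n_best"]
        alnA = pd.DataFrame(
            [
                (0, "chr1", 100, 201, "+", 0, 1),  # A origin (0 vs 2)
                (1, "chr1", 300, 401, "+", 1, 1),  # tie -> ambiguous
                (3, "chr1", 500, 601, "+", 2, 2),  # multi on A -> discarded
            ],
            columns=cols,
        )
        alnB = pd.DataFrame(
            [
                (0, "chr1", 100, 201, "+", 2, 1),
                (1, "chr1", 300, 401, "+", 1, 1),
                (2, "chr1", 700, 801, "-", 0, 1),  # B only
                (3, "chr1", 500, 601, "+", 0, 1),
            ],
            columns=cols,
        )
        out = assign_origins(alnA, alnB).set_index("read_idx")
        assert out.loc[0, "origin"] == "A"
        assert out.loc[1, "origin"] == "ambiguous"
        assert out.loc[2, "origin"] == "B"
        assert 3 not in out.index  # discarded entirely


def _targets():
    return [
        Target("t0", "chr1", 1000, 1320, startB=1000, endB=1320, nSNV=2, nIndel=0, extended=True),
        Target("t1", "chr1", 2000, 2320, startB=1990, endB=2310, nSNV=0, nIndel=1, extended=True),
    ]


def _origins(rows):
    cols = [
        "read_idx", "origin",
        "chrom_A", "pos_A", "end_A", "strand_A",
        "chrom_B", "pos_B", "end_B", "strand_B",
    ]
    recs = []
    for i, (origin, chrom, pos) in enumerate(rows):
        if origin == "A":
            recs.append((i, "A", chrom, pos, pos + 101, "+", None, np.nan, np.nan, None))
        else:
            recs.append((i, origin, None, np.nan, np.nan, None, chrom, pos, pos + 101, "+"))
    return pd.DataFrame(recs, columns=cols)


class TestCounting:
    def test_counts_and_ratio_arithmetic(self):
        rows = [("A", "chr1", 1000 + 10 * k) for k in range(5)]
        rows += [("B", "chr1", 1010 + 10 * k) for k in range(3)]
        counts = count_reads_per_target(_origins(rows), _targets(), pseudocount=0)
        assert counts.loc["t0", "count_A"] == 5 and counts.loc["t0", "count_B"] == 3
        assert counts.loc["t0", "log2_ratio"] == pytest.approx(np.log2(5 / 3), abs=1e-9)
        assert counts.loc["t0", "log2_ratio"] == pytest.approx(0.737, abs=1e-3)

    def test_abutting_read_not_counted(self):
        # read ends exactly at target start / begins at target end: overlap 0
        rows = [("A", "chr1", 1320), ("A", "chr1", 899)]
        counts = count_reads_per_target(_origins(rows), _targets())
        assert counts.loc["t0", "sum"] == 0
        assert counts.attrs["off_target"] == 2

    def test_one_base_overlap_counted(self):
        rows = [("A", "chr1", 1319), ("A", "chr1", 900)]
        counts = count_reads_per_target(_origins(rows), _targets())
        assert counts.loc["t0", "count_A"] == 2

    def test_read_conservation(self, small_world, small_null_rep):
        # every origin-assigned read lands in exactly one target or off-target
        _, alnA, alnB = small_null_rep
        origins = assign_origins(alnA, alnB)
        assigned = origins[origins["origin"].isin(["A", "B"])]
        counts = count_reads_per_target(origins, small_world.targets)
        assert counts["sum"].sum() + counts.attrs["off_target"] == len(assigned)

    def test_ambiguous_reads_excluded(self):
        rows = [("A", "chr1", 1000), ("ambiguous", "chr1", 1000)]
        counts = count_reads_per_target(_origins(rows), _targets())
        assert counts.loc["t0", "sum"] == 1


class TestOutlierFilters:
    def _table(self, ratios, sums=None):
        n = len(ratios)
        df = pd.DataFrame(
            {
                "nSNV": np.zeros(n, dtype=int),
                "nIndel": np.zeros(n, dtype=int),
                "count_A": np.full(n, 50),
                "count_B": np.full(n, 50),
                "sum": np.full(n, 100) if sums is None else np.asarray(sums),
                "log2_ratio": np.asarray(ratios, dtype=float),
            },
            index=[f"t{i:04d}" for i in range(n)],
        )
        return df

    def test_simulation_filter_brute_force_oracle(self):
        rng = np.random.default_rng(50)
        tables = [self._table(rng.normal(0, 0.3, size=1000)) for _ in range(3)]
        retained, flags = filter_outlier_targets_simulation(tables)
        # independent oracle: per-replicate quantile flags, >=2-of-3 drop
        expected_drop = set()
        flag_sets = []
        for tab in tables:
            lo, hi = np.quantile(tab["log2_ratio"], [0.005, 0.995])
            flag_sets.append(set(tab.index[(tab["log2_ratio"] < lo) | (tab["log2_ratio"] > hi)]))
        for tid in tables[0].index:
            if sum(tid in s for s in flag_sets) >= 2:
                expected_drop.add(tid)
        assert set(tables[0].index) - set(retained) == expected_drop

    def test_extreme_outlier_in_all_replicates_discarded(self):
        rng = np.random.default_rng(51)
        tables = []
        for _ in range(3):
            t = self._table(rng.normal(0, 0.1, size=500))
            t.loc["t0000", "log2_ratio"] = np.log2(100 / 1)
            tables.append(t)
        retained, _ = filter_outlier_targets_simulation(tables)
        assert "t0000" not in retained

    def test_flagged_once_retained(self):
        rng = np.random.default_rng(52)
        tables = [self._table(rng.normal(0, 0.1, size=500)) for _ in range(3)]
        tables[0].loc["t0000", "log2_ratio"] = 5.0  # outlier in one replicate only
        retained, flags = filter_outlier_targets_simulation(tables)
        assert "t0000" in retained
        assert flags.loc["t0000"].sum() == 1

    def test_mismatched_universes_rejected(self):
        t1 = self._table(np.zeros(10))
        t2 = self._table(np.zeros(9))
        with pytest.raises(ValueError):
            filter_outlier_targets_simulation([t1, t2, t1])

    def test_wgs_filter_sum_cap_and_quantiles(self):
        rng = np.random.default_rng(53)
        tab = self._table(rng.normal(0, 0.2, size=1000), sums=rng.integers(50, 100, size=1000))
        tab.loc["t0001", "sum"] = 200  # above any cap
        retained, flags = filter_outlier_targets_wgs(tab, sum_cap=110)
        assert "t0001" not in retained
        # direct-filter oracle
        lo, hi = np.quantile(tab["log2_ratio"], [0.005, 0.995])
        expected = tab.index[
            ~(((tab["log2_ratio"] < lo) | (tab["log2_ratio"] > hi)) | (tab["sum"] > 110))
        ]
        assert list(retained) == list(expected)

    def test_median_target_retained(self):
        tab = self._table(np.linspace(-1, 1, 201))
        retained, _ = filter_outlier_targets_wgs(tab, sum_cap=110)
        assert "t0100" in retained  # ratio 0, median sum


class TestGroupStatistics:
    def test_identical_groups_p_near_one(self):
        rng = np.random.default_rng(54)
        x = rng.normal(0, 1, 100)
        assert group_difference(x, x) > 0.5

    def test_shifted_groups_significant(self):
        rng = np.random.default_rng(55)
        x = rng.normal(0, 1, 200)
        y = rng.normal(3, 1, 200)  # 3 pooled SDs apart
        assert group_difference(x, y) < 0.01

    def test_matches_exact_permutation_oracle(self):
        rng = np.random.default_rng(56)
        x = rng.normal(0.0, 1, 8)
        y = rng.normal(1.0, 1, 8)
        p_mw = group_difference(x, y)
        # exact permutation of the rank-sum statistic
        from itertools import combinations

        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        obs = ranks[:8].sum()
        mid = len(pooled) * (len(pooled) + 1) / 2 / 2  # symmetric center for 8+8
        count = total = 0
        for comb in combinations(range(16), 8):
            s = ranks[list(comb)].sum()
            total += 1
            if abs(s - mid) >= abs(obs - mid) - 1e-9:
                count += 1
        p_exact = count / total
        assert p_mw == pytest.approx(p_exact, rel=0.10)

    def test_degenerate_all_tied(self):
        with pytest.warns(UserWarning):
            assert group_difference(np.zeros(5), np.zeros(7)) == 1.0

    def test_group_partition_and_zero_medians(self):
        n = 60
        df = pd.DataFrame(
            {
                "nSNV": np.repeat(np.arange(6), 10),
                "nIndel": np.tile([0, 1], 30),
                "count_A": 10,
                "count_B": 10,
                "sum": 20,
                "log2_ratio": 0.0,
            },
            index=[f"t{i}" for i in range(n)],
        )
        summaries = group_bias_by_divergence(df)
        assert all(s.median == 0 for s in summaries)
        assert sum(s.n_targets for s in summaries) == n

    def test_injected_bias_monotone_medians(self, small_world):
        # simulator ground truth: beta_snv=0.2 makes group medians rise with nSNV
        from capbias.pipeline import simulate_and_map
        from capbias.read_simulator import BiasModel

        _, alnA, alnB = simulate_and_map(
            small_world, BiasModel(beta_snv=0.2), seed=60
        )
        counts = count_reads_per_target(assign_origins(alnA, alnB), small_world.targets)
        sub = counts[counts["nIndel"] == 0]
        medians = sub.groupby("nSNV")["log2_ratio"].median()
        sizes = sub.groupby("nSNV").size()
        medians = medians[sizes >= 4]
        assert (np.diff(medians.values) >= -0.08).all()  # non-decreasing up to noise
        assert medians.iloc[-1] > medians.iloc[0]


class TestSpacing:
    def test_empty_input(self):
        df = pd.DataFrame(columns=["nSNV", "nIndel", "log2_ratio"])
        out = snv_spacing_analysis(df, [], [])
        assert out.empty

    def test_spacing_equals_truth_distance(self, small_world):
        from capbias.allelic_bias import count_reads_per_target

        # build a fake count table over the real targets, then check binning uses
        # the true |pos2 - pos1| from the truth table
        targets = [t for t in small_world.targets if t.nSNV == 2 and t.nIndel == 0]
        if not targets:
            pytest.skip("fixture has no 2-SNV/0-indel targets")
        counts = pd.DataFrame(
            {
                "nSNV": 2,
                "nIndel": 0,
                "count_A": 10,
                "count_B": 10,
                "sum": 20,
                "log2_ratio": 0.0,
            },
            index=[t.id for t in targets],
        )
        out = snv_spacing_analysis(counts, targets, small_world.truth)
        assert out["n_targets"].sum() == len(targets)
        # oracle: recompute spacings and match bin populations
        spacings = []
        for t in targets:
            snvs = sorted(
                v.pos
                for v in small_world.truth
                if v.kind == "SNV" and v.chrom == t.chrom and t.startA <= v.pos < t.endA
            )
            assert len(snvs) == 2
            spacings.append(snvs[1] - snvs[0])
        for row in out.itertuples():
            expected = sum(1 for s in spacings if row.lo <= s <= row.hi)
            assert row.n_targets == expected


class TestDepth:
    def _aln(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "end"])

    def test_full_and_half_coverage(self):
        aln = self._aln([("chr1", 1000, 1120)])
        depth, mean = compute_depth(aln, "chr1", 1000, 1120)
        assert mean == 1.0 and depth.min() == 1
        aln = self._aln([("chr1", 1000, 1060)])
        _, mean = compute_depth(aln, "chr1", 1000, 1120)
        assert mean == 0.5

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(57)
        rows = [
            ("chr1", int(p), int(p) + 101) for p in rng.integers(900, 1400, size=200)
        ]
        depth, mean = compute_depth(self._aln(rows), "chr1", 1000, 1320)
        brute = np.zeros(320, dtype=int)
        for _, p, e in rows:
            for x in range(max(p, 1000), min(e, 1320)):
                brute[x - 1000] += 1
        assert (depth == brute).all()
        assert mean == pytest.approx(brute.mean())
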