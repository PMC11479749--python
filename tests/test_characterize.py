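import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from eccv.caller import EccRecord
from eccv.characterize import (
    SampleEccSet,
    chrom_density,
    common_start_end,
    compare_gc_groups,
    epm,
    gc_with_flanks,
    ks_length_compare,
    length_bin_ratios,
    length_density_peaks,
    per_circle_differential,
    rank_sum_test,
)

# ---------------------------------------------------------------------------
# Independent oracles


def wilcoxon_enumeration_oracle(x, y):
    """Exact two-sided rank-sum p by full enumeration of group assignments.

    Pools the data, assigns midranks, and walks every C(n1+n2, n1) choice of
    which observations belong to the first group; the p-value doubles the
    smaller tail probability of the observed rank sum (capped at 1).
    """
    pooled = list(x) + list(y)
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    sums = [sum(c) for c in itertools.combinations(ranks, n1)]
    n_le = sum(s <= w_obs + 1e-9 for s in sums)
    n_ge = sum(s >= w_obs - 1e-9 for s in sums)
    return min(1.0, 2.0 * min(n_le, n_ge) / len(sums))


def ks_sup_oracle(a, b):
    """Brute-force sup of |ECDF_a - ECDF_b| over all pooled breakpoints."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    d = 0.0
    for v in np.concatenate([a, b]):
        d = max(d, abs((a <= v).mean() - (b <= v).mean()))
    return d


def _sample(sample_id, group, lengths_or_records, mapped=1_000_000):
    records = [
        r if isinstance(r, EccRecord)
        else EccRecord("chr1", 1000 * i, 1000 * i + int(r), 5, 0.4, sample_id)
        for i, r in enumerate(lengths_or_records)
    ]
    return SampleEccSet(sample_id, group, records, mapped)


# ---------------------------------------------------------------------------


class TestEpm:
    def test_definition(self):
        s = _sample("s", "A", [500] * 150, mapped=30_000_000)
        assert epm(s) == 5.0

    def test_empty_catalog(self):
        s = SampleEccSet("s", "A", [], 1_000_000)
        assert epm(s) == 0.0

    def test_scale_equivariance(self, rng):
        n = int(rng.integers(10, 200))
        mapped = int(rng.integers(10**5, 10**7))
        s1 = _sample("s", "A", [500] * n, mapped=mapped)
        s2 = _sample("s", "A", [500] * (2 * n), mapped=2 * mapped)
        assert epm(s1) == pytest.approx(epm(s2))

    def test_nonpositive_mapped_reads_rejected(self):
        with pytest.raises(ValueError):
            SampleEccSet("s", "A", [], 0)


class TestRankSum:
    def test_identical_groups_p_one(self):
        res = rank_sum_test([0.3, 0.4, 0.5], [0.3, 0.4, 0.5])
        assert res.method == "exact"
        assert res.pvalue == 1.0

    def test_disjoint_small_groups(self):
        """[0.3,0.4,0.5] vs [0.6,0.7,0.8]: the most extreme of the 20
        assignments, so two-sided p = 2/20."""
        res = rank_sum_test([0.3, 0.4, 0.5], [0.6, 0.7, 0.8])
        assert res.pvalue == pytest.approx(0.1)
        assert res.pvalue == pytest.approx(
            wilcoxon_enumeration_oracle([0.3, 0.4, 0.5], [0.6, 0.7, 0.8]))

    def test_exact_matches_enumeration_with_and_without_ties(self, rng):
        for _ in range(40):
            n1, n2 = rng.integers(2, 8, size=2)
            # integer values force ties often
            x = rng.integers(0, 6, size=n1).astype(float)
            y = rng.integers(0, 6, size=n2).astype(float)
            got = rank_sum_test(x, y)
            assert got.method == "exact"
            assert got.pvalue == pytest.approx(wilcoxon_enumeration_oracle(x, y))

    def test_exact_matches_scipy_when_no_ties(self, rng):
        for _ in range(20):
            x = rng.normal(size=8)
            y = rng.normal(size=6)
            got = rank_sum_test(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert got.pvalue == pytest.approx(ref.pvalue)
            assert got.statistic == pytest.approx(ref.statistic)

    def test_asymptotic_matches_scipy_tie_correction(self, rng):
        x = rng.integers(0, 20, size=40).astype(float)
        y = rng.integers(3, 23, size=35).astype(float)
        got = rank_sum_test(x, y)
        assert got.method == "asymptotic"
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
        assert got.pvalue == pytest.approx(ref.pvalue, rel=1e-9)

    def test_group_swap_symmetry(self, rng):
        x = list(rng.normal(size=6))
        y = list(rng.normal(loc=1, size=5))
        assert rank_sum_test(x, y).pvalue == pytest.approx(rank_sum_test(y, x).pvalue)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        x=st.lists(st.integers(0, 9), min_size=2, max_size=6),
        y=st.lists(st.integers(0, 9), min_size=2, max_size=6),
    )
    def test_exact_p_equals_enumeration_property(self, x, y):
        """Exact DP agrees with brute-force enumeration on arbitrary
        small integer samples, ties included."""
        got = rank_sum_test(x, y)
        assert got.method == "exact"
        assert got.pvalue == pytest.approx(wilcoxon_enumeration_oracle(x, y))
        assert 0.0 < got.pvalue <= 1.0


class TestGcFlanks:
    def test_flank_intervals_by_definition(self, small_genome):
        r = EccRecord("chr1", 1000, 2000, 5, 0.4, "s")
        fl = gc_with_flanks(r, small_genome)
        from eccv.caller import gc_of_interval

        assert fl.upstream_gc == pytest.approx(gc_of_interval(small_genome, "chr1", 0, 1000))
        assert fl.downstream_gc == pytest.approx(gc_of_interval(small_genome, "chr1", 2000, 3000))
        assert not fl.upstream_truncated and not fl.downstream_truncated

    def test_circle_at_chromosome_start_flags_upstream_absent(self, small_genome):
        r = EccRecord("chr1", 0, 1000, 5, 0.4, "s")
        fl = gc_with_flanks(r, small_genome)
        assert fl.upstream_gc is None and fl.upstream_truncated

    def test_partially_truncated_flank_flagged(self, small_genome):
        r = EccRecord("chr1", 500, 1500, 5, 0.4, "s")
        fl = gc_with_flanks(r, small_genome)
        assert fl.upstream_truncated and fl.upstream_gc is not None

    def test_unbiased_circles_match_flank_gc(self, small_cohort_genome, small_config, rng):
        """With no GC placement preference, circle GC equals flank GC on average."""
        from eccv.simulate import GroupProfile, SimCohortConfig, sample_truth_circles
        from eccv.caller import gc_of_interval

        cfg = SimCohortConfig(
            n_samples_per_group=1, chrom_lengths=small_config.chrom_lengths,
            groups={"G": GroupProfile(700, ((700.0, 100.0, 1.0),), gc_shift=0.0)},
            seed=31,
        )
        deltas = []
        for _ in range(3):
            for c in sample_truth_circles(small_cohort_genome, cfg, "G", "s", rng):
                rec = EccRecord(c.chrom, c.start, c.end, 5,
                                gc_of_interval(small_cohort_genome, c.chrom, c.start, c.end), "s")
                fl = gc_with_flanks(rec, small_cohort_genome)
                flanks = [g for g in (fl.upstream_gc, fl.downstream_gc) if g is not None]
                if flanks:
                    deltas.append(fl.ecc_gc - np.mean(flanks))
        assert len(deltas) >= 2000
        assert abs(np.mean(deltas)) < 0.01

    def test_group_gc_shift_detected(self, small_cohort_genome, rng):
        from eccv.simulate import GroupProfile, SimCohortConfig, sample_truth_circles
        from eccv.caller import gc_of_interval

        cohort = []
        for group, shift in (("HC-like", 0.0), ("LF-like", 0.05)):
            cfg = SimCohortConfig(
                n_samples_per_group=1,
                chrom_lengths={"chr1": 200_000, "chr2": 150_000},
                groups={group: GroupProfile(600, ((700.0, 100.0, 1.0),), gc_shift=shift)},
                seed=37,
            )
            recs = [
                EccRecord(c.chrom, c.start, c.end, 5,
                          gc_of_interval(small_cohort_genome, c.chrom, c.start, c.end), group)
                for c in sample_truth_circles(small_cohort_genome, cfg, group, group, rng)
            ]
            cohort.append(SampleEccSet(group, group, recs, 1_000_000))
        res = compare_gc_groups(cohort, ("LF-like", "HC-like"))
        assert res.pvalue < 0.05


class TestChromDensity:
    def test_single_chromosome_is_100pct(self):
        s = _sample("s", "A", [500] * 10)
        df = chrom_density([s], {"chr1": 1_000_000})
        assert df["pct"].iloc[0] == pytest.approx(100.0)

    def test_equal_per_mb_rates_split_evenly(self):
        recs = [EccRecord("chr1", i * 100, i * 100 + 50, 2, 0.4, "s") for i in range(10)]
        recs += [EccRecord("chr2", i * 100, i * 100 + 50, 2, 0.4, "s") for i in range(20)]
        s = SampleEccSet("s", "A", recs, 1_000_000)
        df = chrom_density([s], {"chr1": 1_000_000, "chr2": 2_000_000})
        assert df["pct"].tolist() == pytest.approx([50.0, 50.0])

    def test_percentages_sum_to_100(self, rng):
        recs = [EccRecord(f"chr{rng.integers(1, 4)}", 0, 500, 2, 0.4, "s")
                for _ in range(100)]
        s = SampleEccSet("s", "A", recs, 1_000_000)
        df = chrom_density([s], {"chr1": 10**6, "chr2": 2 * 10**6, "chr3": 5 * 10**5})
        assert df["pct"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_uniform_placement_near_mean_line(self, rng):
        """Uniform circle placement keeps each chromosome within 3 binomial SD."""
        lens = {"chr1": 10**6, "chr2": 10**6, "chr3": 10**6}
        n = 3000
        chroms = rng.choice(list(lens), size=n)
        recs = [EccRecord(c, 0, 500, 2, 0.4, "s") for c in chroms]
        df = chrom_density([SampleEccSet("s", "A", recs, 10**6)], lens)
        p = 1 / 3
        sd_pct = 100 * np.sqrt(p * (1 - p) / n)  # equal lengths: pct = 100 * count share
        assert (abs(df["pct"] - df["mean_pct"]) < 3 * sd_pct).all()


class TestLengthPeaks:
    def test_five_mode_mixture_recovered(self, rng):
        modes = [370, 566, 751, 946, 1124]
        draws = rng.normal(rng.choice(modes, size=5000), 20)
        peaks = length_density_peaks(draws)
        assert len(peaks) == 5
        for got, want in zip(peaks, modes):
            assert abs(got - want) <= 15

    def test_identical_lengths_single_peak(self):
        peaks = length_density_peaks([500.0] * 100)
        assert len(peaks) == 1 and peaks[0] == 500

    def test_unimodal_gaussian_one_peak(self, rng):
        draws = rng.normal(800, 100, size=5000)
        peaks = length_density_peaks(draws)
        assert len(peaks) == 1
        assert abs(peaks[0] - 800) < 30

    def test_too_few_lengths_warns_empty(self):
        with pytest.warns(UserWarning):
            peaks = length_density_peaks([500.0] * 5)
        assert len(peaks) == 0

    def test_window_restriction_drops_long_circles(self, rng):
        draws = np.concatenate([rng.normal(500, 20, 2000),
                                rng.normal(10_000, 100, 2000)])
        peaks = length_density_peaks(draws)
        assert all(p < 3000 for p in peaks)


class TestKs:
    def test_identical_samples_d_zero(self):
        res = ks_length_compare([100, 200, 300], [100, 200, 300])
        assert res.statistic == 0.0

    def test_disjoint_supports_d_one(self):
        res = ks_length_compare([1, 2, 3, 4], [5, 6, 7, 8])
        assert res.statistic == 1.0

    def test_d_matches_brute_force_sup(self, rng):
        for _ in range(100):
            a = rng.integers(0, 4000, size=rng.integers(5, 40))
            b = rng.integers(0, 4000, size=rng.integers(5, 40))
            res = ks_length_compare(a, b)
            assert res.statistic == pytest.approx(ks_sup_oracle(a, b))

    def test_p_monotone_in_shift(self, rng):
        a = rng.normal(1000, 100, 200)
        ps = [ks_length_compare(a, a + shift).pvalue for shift in (0, 30, 100, 300)]
        assert ps == sorted(ps, reverse=True)


class TestBinRatios:
    def test_single_sample_all_600bp(self):
        cohort = [_sample("a", "A", [600] * 10), _sample("b", "B", [600] * 10),
                  _sample("a2", "A", [600] * 9), _sample("b2", "B", [600] * 9)]
        df = length_bin_ratios(cohort, groups=("A", "B")).set_index("bin")
        assert df.loc["0.5-1kb", "mean_A"] == pytest.approx(1.0)
        assert df.loc["0-0.5kb", "mean_A"] == pytest.approx(0.0)
        assert df.loc[">2kb", "mean_B"] == pytest.approx(0.0)

    def test_per_sample_ratios_partition(self, rng):
        cohort = [
            _sample(f"s{i}", "A" if i < 3 else "B",
                    rng.integers(100, 4000, size=50)) for i in range(6)
        ]
        df = length_bin_ratios(cohort, groups=("A", "B"))
        assert df["mean_A"].sum() == pytest.approx(1.0)
        assert df["mean_B"].sum() == pytest.approx(1.0)

    def test_t_statistic_matches_scipy(self, rng):
        cohort = [
            _sample(f"s{i}", "A" if i < 4 else "B",
                    rng.integers(100, 3000, size=80)) for i in range(8)
        ]
        df = length_bin_ratios(cohort, groups=("A", "B"))
        # recompute the first bin by hand
        va, vb = [], []
        for s in cohort:
            frac = np.mean([r.length < 500 for r in s.records])
            (va if s.group == "A" else vb).append(frac)
        t, p = sps.ttest_ind(va, vb, equal_var=True)
        assert df["t"].iloc[0] == pytest.approx(t)
        assert df["p"].iloc[0] == pytest.approx(p)


def _keyed_sample(sid, group, keys, mapped=1_000_000):
    recs = [EccRecord(c, s, e, 3, 0.4, sid) for c, s, e in keys]
    return SampleEccSet(sid, group, recs, mapped)


class TestCommonStartEnd:
    def test_constructed_shared_keys(self):
        shared_keys = [("chr1", 100, 600), ("chr1", 1000, 1800), ("chr2", 50, 900)]
        a = _keyed_sample("a", "A", shared_keys + [("chr1", 5000, 6000)])
        b = _keyed_sample("b", "B", shared_keys + [("chr2", 7000, 8000)])
        res = common_start_end([a, b], ("A", "B"))
        assert res.counts == {"a_only": 1, "b_only": 1, "shared": 3}
        assert res.shared == sorted(shared_keys)

    def test_disjoint_catalogs(self):
        a = _keyed_sample("a", "A", [("chr1", 100, 600)])
        b = _keyed_sample("b", "B", [("chr1", 2000, 2600)])
        res = common_start_end([a, b], ("A", "B"))
        assert res.counts["shared"] == 0

    def test_tolerance_merges_nearby_keys(self):
        a = _keyed_sample("a", "A", [("chr1", 1000, 2000)])
        b = _keyed_sample("b", "B", [("chr1", 1003, 1998)])
        exact = common_start_end([a, b], ("A", "B"), tolerance=0)
        merged = common_start_end([a, b], ("A", "B"), tolerance=5)
        assert exact.counts["shared"] == 0
        assert merged.counts["shared"] == 1
        assert merged.shared == [("chr1", 1000, 1998)]


class TestPerCircleDifferential:
    def test_small_sample_exact_p(self):
        """Key in every A sample (EPM 5,6,7) and no B sample: the extreme
        arrangement of 20, so two-sided p = 0.1."""
        key = ("chr1", 100, 600)
        cohort = [
            _keyed_sample("a1", "A", [key] * 5, mapped=1_000_000),
            _keyed_sample("a2", "A", [key] * 6, mapped=1_000_000),
            _keyed_sample("a3", "A", [key] * 7, mapped=1_000_000),
            _keyed_sample("b1", "B", [("chr2", 1, 200)], mapped=1_000_000),
            _keyed_sample("b2", "B", [("chr2", 1, 200)], mapped=1_000_000),
            _keyed_sample("b3", "B", [key], mapped=1_000_000),
        ]
        shared = common_start_end(cohort, ("A", "B"))
        df = per_circle_differential(cohort, shared)
        row = df[(df.start == 100)].iloc[0]
        # signals: A = (5,6,7), B = (0,0,1) -> still most extreme split
        assert row["p"] == pytest.approx(
            wilcoxon_enumeration_oracle([5, 6, 7], [0, 0, 1]))
        assert row["direction"] == "A"

    def test_identical_occurrence_p_one(self):
        key = ("chr1", 100, 600)
        cohort = [_keyed_sample(f"{g}{i}", g, [key] * 3)
                  for g in "AB" for i in range(3)]
        shared = common_start_end(cohort, ("A", "B"))
        df = per_circle_differential(cohort, shared)
        assert df["p"].iloc[0] == 1.0
        assert not df["significant"].iloc[0]

    def test_presence_mode_binary_signal(self):
        key = ("chr1", 100, 600)
        cohort = [
            _keyed_sample("a1", "A", [key] * 9, mapped=1_000_000),
            _keyed_sample("a2", "A", [key] * 1, mapped=1_000_000),
            _keyed_sample("b1", "B", [key] * 1, mapped=1_000_000),
            _keyed_sample("b2", "B", [key] * 1, mapped=1_000_000),
        ]
        shared = common_start_end(cohort, ("A", "B"))
        df = per_circle_differential(cohort, shared, signal_mode="presence")
        assert df["p"].iloc[0] == 1.0  # all present -> identical binary signal

    def test_group_swap_flips_direction(self):
        key = ("chr1", 100, 600)
        cohort = [
            _keyed_sample("a1", "A", [key] * 5),
            _keyed_sample("a2", "A", [key] * 6),
            _keyed_sample("b1", "B", [("chr2", 1, 200)]),
            _keyed_sample("b2", "B", [key]),
        ]
        fwd = per_circle_differential(cohort, common_start_end(cohort, ("A", "B")))
        rev = per_circle_differential(cohort, common_start_end(cohort, ("B", "A")))
        assert fwd["p"].iloc[0] == pytest.approx(rev["p"].iloc[0])
        assert fwd["direction"].iloc[0] == "A" and rev["direction"].iloc[0] == "A"

    def test_planted_enrichment_flagged(self, rng):
        """A key 10x more frequent in one group is flagged with that direction."""
        key = ("chr1", 100, 600)
        hits = 0
        for trial in range(10):
            cohort = []
            for i in range(10):
                n = int(rng.poisson(10))
                cohort.append(_keyed_sample(f"a{i}", "A", [key] * max(n, 0)))
            for i in range(10):
                n = int(rng.poisson(1))
                keys = [key] * n if n else [("chr2", 1, 200)]
                cohort.append(_keyed_sample(f"b{i}", "B", keys))
            shared = common_start_end(cohort, ("A", "B"))
            if key not in shared.shared:
                continue
            df = per_circle_differential(cohort, shared)
            row = df[df.start == 100].iloc[0]
            if row["significant"] and row["direction"] == "A":
                hits += 1
        assert hits >= 9
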