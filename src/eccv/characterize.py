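"""Cohort-level characterization of circle catalogs.

Implements the statistics used to compare circular-DNA catalogs between two
sample groups: eccDNA-per-million-mapped-reads (EPM) abundance, GC content
of circles versus equal-length flanking regions, per-chromosome density,
kernel-density length peaks, cumulative-length Kolmogorov-Smirnov
comparison, per-length-bin ratio t-tests, circles with common start-end
coordinates across groups, and a per-circle differential-occurrence test.

The two-sample Wilcoxon rank-sum test is implemented in-package with an
exact, tie-aware null distribution (dynamic programming over midranks) for
small samples and a tie-corrected normal approximation otherwise; ties
share midranks in both regimes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

from eccv.caller import EccRecord

DEFAULT_LENGTH_BINS = (0, 500, 1000, 2000, float("inf"))
#: length windows (bp) restricting the density-peak and KS analyses
PEAK_MAX_LEN = 3000
KS_MAX_LEN = 5000


@dataclass
class SampleEccSet:
    """One sample's called circles plus the EPM denominator."""

    sample_id: str
    group: str
    records: list[EccRecord]
    mapped_reads: int

    def __post_init__(self):
        if self.mapped_reads <= 0:
            raise ValueError(
                f"{self.sample_id}: mapped_reads must be positive, got {self.mapped_reads}"
            )

    @property
    def lengths(self) -> np.ndarray:
        return np.array([r.length for r in self.records], dtype=float)


class TestResult(NamedTuple):
    statistic: float
    pvalue: float
    method: str


def epm(sample: SampleEccSet) -> float:
    """Circles per million mapped reads: ``n_circles * 1e6 / mapped_reads``."""
    return len(sample.records) * 1e6 / sample.mapped_reads


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def _exact_rank_sum_distribution(doubled_ranks: np.ndarray, n1: int) -> np.ndarray:
    """Counts of subsets of size n1 by doubled-rank sum, via subset-sum DP.

    Midranks are half-integers, so doubling makes them integers; the DP
    enumerates, exactly, how many of the C(N, n1) equally likely group
    assignments achieve each rank sum. Identical to brute-force enumeration
    of all assignments, at polynomial cost.
    """
    total = int(doubled_ranks.sum())
    f = np.zeros((n1 + 1, total + 1), dtype=np.int64)
    f[0, 0] = 1
    for d in doubled_ranks:
        d = int(d)
        for j in range(n1, 0, -1):
            f[j, d:] += f[j - 1, : total + 1 - d]
    return f[n1]


def rank_sum_test(x: Sequence[float], y: Sequence[float],
                  exact_limit: int = 25) -> TestResult:
    """Two-sided two-sample Wilcoxon rank-sum (Mann-Whitney) test.

    Exact tie-aware null distribution when both sides have at most
    ``exact_limit`` observations; tie-corrected normal approximation (no
    continuity correction) otherwise. Returns the Mann-Whitney U of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = ranks[:n1].sum()
    u = w - n1 * (n1 + 1) / 2.0
    if n1 <= exact_limit and n2 <= exact_limit:
        doubled = np.rint(2 * ranks).astype(np.int64)
        dist = _exact_rank_sum_distribution(doubled, n1)
        total = dist.sum()
        w2 = int(round(2 * w))
        p_le = dist[: w2 + 1].sum() / total
        p_ge = dist[w2:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return TestResult(float(u), float(p), "exact")
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return TestResult(float(u), 1.0, "asymptotic")
    z = (w - n1 * (n + 1) / 2.0) / np.sqrt(var)
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return TestResult(float(u), float(p), "asymptotic")


# ---------------------------------------------------------------------------
# GC of circles vs flanks


@dataclass(frozen=True)
class GcFlanks:
    ecc_gc: float
    upstream_gc: float | None
    downstream_gc: float | None
    upstream_truncated: bool = False
    downstream_truncated: bool = False


def gc_with_flanks(record: EccRecord, genome) -> GcFlanks:
    """GC of a circle and of its equal-length upstream/downstream flanks.

    Flanks are the intervals of ``record.length`` bp immediately before the
    start and after the end. A flank truncated by a chromosome edge is
    computed on the remaining piece and flagged; a flank that falls entirely
    off-chromosome is reported absent (None) and flagged.
    """
    from eccv.caller import gc_of_interval

    L = record.length
    clen = genome.lengths[record.chrom]
    ecc_gc = gc_of_interval(genome, record.chrom, record.start, record.end)

    up_lo, up_hi = record.start - L, record.start
    up_trunc = up_lo < 0
    up_lo = max(0, up_lo)
    up_gc = (
        gc_of_interval(genome, record.chrom, up_lo, up_hi) if up_hi > up_lo else None
    )

    dn_lo, dn_hi = record.end, record.end + L
    dn_trunc = dn_hi > clen
    dn_hi = min(clen, dn_hi)
    dn_gc = (
        gc_of_interval(genome, record.chrom, dn_lo, dn_hi) if dn_hi > dn_lo else None
    )
    return GcFlanks(ecc_gc, up_gc, dn_gc, up_trunc, dn_trunc)


def gc_flank_table(cohort: Sequence[SampleEccSet], genome) -> pd.DataFrame:
    rows = []
    for s in cohort:
        for r in s.records:
            fl = gc_with_flanks(r, genome)
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "group": s.group,
                    "chrom": r.chrom,
                    "start": r.start,
                    "end": r.end,
                    "ecc_gc": fl.ecc_gc,
                    "upstream_gc": fl.upstream_gc,
                    "downstream_gc": fl.downstream_gc,
                    "upstream_truncated": fl.upstream_truncated,
                    "downstream_truncated": fl.downstream_truncated,
                }
            )
    return pd.DataFrame(rows)


def compare_gc_groups(cohort: Sequence[SampleEccSet],
                      groups: tuple[str, str] | None = None) -> TestResult:
    """Wilcoxon rank-sum on per-record GC pooled by group (two-sided)."""
    ga, gb = groups or _infer_groups(cohort)
    gc_a = [r.gc for s in cohort if s.group == ga for r in s.records]
    gc_b = [r.gc for s in cohort if s.group == gb for r in s.records]
    return rank_sum_test(gc_a, gc_b)


# ---------------------------------------------------------------------------
# Chromosomal distribution


def chrom_density(cohort: Sequence[SampleEccSet],
                  chrom_lengths: dict[str, int]) -> pd.DataFrame:
    """Percent of circles per Mb for each chromosome.

    Each chromosome's count is divided by its length in Mb, and the per-Mb
    rates are expressed as percentages of their sum; the ``mean_pct``
    column repeats the across-chromosome average (the cohort's dashed
    reference line).
    """
    counts = {c: 0 for c in chrom_lengths}
    for s in cohort:
        for r in s.records:
            if r.chrom in counts:
                counts[r.chrom] += 1
    df = pd.DataFrame(
        {
            "chrom": list(chrom_lengths),
            "count": [counts[c] for c in chrom_lengths],
            "length_mb": [chrom_lengths[c] / 1e6 for c in chrom_lengths],
        }
    )
    df["per_mb"] = df["count"] / df["length_mb"]
    tot = df["per_mb"].sum()
    df["pct"] = 100.0 * df["per_mb"] / tot if tot > 0 else 0.0
    df["mean_pct"] = df["pct"].mean()
    return df


# ---------------------------------------------------------------------------
# Length distribution


def length_density_peaks(
    lengths: Sequence[float],
    max_len: int = PEAK_MAX_LEN,
    bandwidth: float | str | None = None,
    min_prominence_frac: float = 0.05,
    grid_step: float = 1.0,
) -> np.ndarray:
    """Positions (bp) of local maxima of the smoothed length density.

    A Gaussian KDE (Silverman bandwidth by default) is fitted to lengths
    below ``max_len`` and evaluated on a 1-bp grid; local maxima with
    prominence of at least ``min_prominence_frac`` of the highest density
    are reported, sorted ascending. Fewer than 10 usable lengths yields an
    empty result with a warning.
    """
    arr = np.asarray(lengths, dtype=float)
    arr = arr[arr < max_len]
    if len(arr) < 10:
        warnings.warn("fewer than 10 lengths below the window; no peaks reported")
        return np.array([])
    if np.ptp(arr) == 0:  # degenerate: all identical, density is one spike
        return np.array([arr[0]])
    kde = stats.gaussian_kde(arr, bw_method=bandwidth or "silverman")
    grid = np.arange(0.0, max_len + grid_step, grid_step)
    dens = kde(grid)
    peaks, _ = signal.find_peaks(dens, prominence=min_prominence_frac * dens.max())
    return grid[peaks]


def ks_length_compare(lengths_a: Sequence[float], lengths_b: Sequence[float],
                      max_len: int = KS_MAX_LEN) -> TestResult:
    """Two-sample two-sided Kolmogorov-Smirnov test on lengths below 5 kb."""
    a = np.asarray(lengths_a, dtype=float)
    b = np.asarray(lengths_b, dtype=float)
    a, b = a[a < max_len], b[b < max_len]
    res = stats.ks_2samp(a, b, method="asymp")
    return TestResult(float(res.statistic), float(res.pvalue), "ks_asymp")


def _bin_labels(bins: Sequence[float]) -> list[str]:
    labels = []
    for lo, hi in zip(bins[:-1], bins[1:]):
        if np.isinf(hi):
            labels.append(f">{lo / 1000:g}kb")
        else:
            labels.append(f"{lo / 1000:g}-{hi / 1000:g}kb")
    return labels


def length_bin_ratios(cohort: Sequence[SampleEccSet],
                      bins: Sequence[float] = DEFAULT_LENGTH_BINS,
                      groups: tuple[str, str] | None = None) -> pd.DataFrame:
    """Per-sample fraction of circles in each length bin, compared by group.

    For every bin, each sample contributes the fraction of its circles
    falling in that bin (the per-sample ratios partition to 1); group means
    are compared with an equal-variance two-sample t-test.
    """
    ga, gb = groups or _infer_groups(cohort)
    edges = np.asarray(bins, dtype=float)
    per_sample = {}
    for s in cohort:
        if not s.records:
            continue
        h, _ = np.histogram(s.lengths, bins=edges)
        per_sample[s.sample_id] = (s.group, h / h.sum())
    rows = []
    for i, label in enumerate(_bin_labels(edges)):
        va = [v[i] for g, v in per_sample.values() if g == ga]
        vb = [v[i] for g, v in per_sample.values() if g == gb]
        t, p = stats.ttest_ind(va, vb, equal_var=True)
        rows.append(
            {
                "bin": label,
                f"mean_{ga}": np.mean(va),
                f"sd_{ga}": np.std(va, ddof=1),
                f"mean_{gb}": np.mean(vb),
                f"sd_{gb}": np.std(vb, ddof=1),
                "t": float(t),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Common start-end circles and differential occurrence


@dataclass
class SharedCircles:
    """Circles whose (chrom, start, end) key occurs in both groups."""

    shared: list[tuple[str, int, int]]
    counts: dict  # {"a_only": int, "b_only": int, "shared": int}
    key_counts: dict  # key -> {sample_id: occurrence count}
    groups: tuple[str, str]


def _merge_keys_with_tolerance(keys: list[tuple[str, int, int]],
                               tolerance: int) -> dict[tuple[str, int, int], tuple[str, int, int]]:
    """Map each key to a consensus key, merging keys whose endpoints both
    agree within ``tolerance`` (same clustering rule as the caller)."""
    from eccv.caller import JunctionEvidence, cluster_and_call, CallerParams  # noqa: F401
    from eccv.caller import _lower_median

    mapping: dict[tuple[str, int, int], tuple[str, int, int]] = {}
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in keys:
        by_chrom.setdefault(chrom, []).append((s, e))
    for chrom, pairs in by_chrom.items():
        pairs = sorted(set(pairs))
        clusters: list[dict] = []
        for s, e in pairs:
            placed = False
            for cl in clusters:
                if abs(s - cl["ms"]) <= tolerance and abs(e - cl["me"]) <= tolerance:
                    cl["members"].append((s, e))
                    cl["ms"] = _lower_median([m[0] for m in cl["members"]])
                    cl["me"] = _lower_median([m[1] for m in cl["members"]])
                    placed = True
                    break
            if not placed:
                clusters.append({"members": [(s, e)], "ms": s, "me": e})
        for cl in clusters:
            consensus = (chrom, cl["ms"], cl["me"])
            for s, e in cl["members"]:
                mapping[(chrom, s, e)] = consensus
    return mapping


def common_start_end(cohort: Sequence[SampleEccSet],
                     groups: tuple[str, str] | None = None,
                     tolerance: int = 0) -> SharedCircles:
    """Circle keys present in at least one sample of each group.

    By default keys match on exact (chrom, start, end) identity; with a
    positive ``tolerance``, keys whose endpoints both agree within that
    many bp are merged to a consensus key first.
    """
    ga, gb = groups or _infer_groups(cohort)
    all_keys = [r.key for s in cohort for r in s.records]
    if tolerance > 0:
        mapping = _merge_keys_with_tolerance(all_keys, tolerance)
    else:
        mapping = {k: k for k in all_keys}
    key_counts: dict = {}
    group_of_key: dict = {}
    for s in cohort:
        for r in s.records:
            k = mapping[r.key]
            key_counts.setdefault(k, {}).setdefault(s.sample_id, 0)
            key_counts[k][s.sample_id] += 1
            group_of_key.setdefault(k, set()).add(s.group)
    shared = sorted(k for k, gs in group_of_key.items() if ga in gs and gb in gs)
    a_only = sum(1 for gs in group_of_key.values() if gs == {ga})
    b_only = sum(1 for gs in group_of_key.values() if gs == {gb})
    return SharedCircles(
        shared,
        {"a_only": a_only, "b_only": b_only, "shared": len(shared)},
        key_counts,
        (ga, gb),
    )


def per_circle_differential(
    cohort: Sequence[SampleEccSet],
    shared: SharedCircles,
    signal_mode: str = "epm",
    alpha: float = 0.05,
    correct: str | None = None,
) -> pd.DataFrame:
    """Wilcoxon rank-sum on each shared circle's per-sample occurrence.

    The per-sample signal is the sample's EPM-scaled count of the key
    (``signal_mode="epm"``, 0 when absent) or binary presence
    (``signal_mode="presence"``). p-values are two-sided; keys with
    p < ``alpha`` are flagged and given the direction of the higher group
    median (group-mean difference breaks median ties). No multiplicity
    correction is applied by default, matching the convention of reporting
    raw per-circle significance; ``correct="bh"`` applies
    Benjamini-Hochberg.
    """
    if signal_mode not in ("epm", "presence"):
        raise ValueError(f"unknown signal_mode {signal_mode!r}")
    ga, gb = shared.groups
    samples_a = [s for s in cohort if s.group == ga]
    samples_b = [s for s in cohort if s.group == gb]
    rows = []
    for key in shared.shared:
        counts = shared.key_counts.get(key, {})

        def sig(s: SampleEccSet) -> float:
            c = counts.get(s.sample_id, 0)
            if signal_mode == "presence":
                return float(c > 0)
            return c * 1e6 / s.mapped_reads

        va = [sig(s) for s in samples_a]
        vb = [sig(s) for s in samples_b]
        res = rank_sum_test(va, vb)
        da = np.median(va) - np.median(vb)
        if da == 0:
            da = np.mean(va) - np.mean(vb)
        direction = ga if da > 0 else (gb if da < 0 else "equal")
        rows.append(
            {
                "chrom": key[0],
                "start": key[1],
                "end": key[2],
                "statistic": res.statistic,
                "p": res.pvalue,
                "direction": direction,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        if correct == "bh":
            df["p_adj"] = stats.false_discovery_control(df["p"], method="bh")
            df["significant"] = df["p_adj"] < alpha
        else:
            df["significant"] = df["p"] < alpha
    return df


# ---------------------------------------------------------------------------
# Bundle


@dataclass
class CohortStats:
    """All cohort-level characterization outputs, bundled."""

    groups: tuple[str, str]
    epm_per_sample: dict[str, float]
    group_epm_test: TestResult
    gc_flank_table: pd.DataFrame
    gc_group_test: TestResult
    chrom_density: pd.DataFrame
    length_peaks: dict[str, np.ndarray]
    ks_result: TestResult
    bin_ratio_tests: pd.DataFrame
    common_circles: SharedCircles
    differential: pd.DataFrame
    headline: dict = field(default_factory=dict)


def _infer_groups(cohort: Sequence[SampleEccSet]) -> tuple[str, str]:
    gs = sorted({s.group for s in cohort})
    if len(gs) != 2:
        raise ValueError(f"expected exactly two groups, found {gs}")
    return (gs[0], gs[1])


def compute_cohort_stats(
    cohort: Sequence[SampleEccSet],
    genome,
    groups: tuple[str, str] | None = None,
    tolerance: int = 0,
    signal_mode: str = "epm",
) -> CohortStats:
    """Run the full characterization battery on a two-group cohort.

    ``groups`` orders the comparison (a, b); the headline summary reports
    the direction of the EPM, length and GC contrasts between them.
    """
    ga, gb = groups or _infer_groups(cohort)
    epms = {s.sample_id: epm(s) for s in cohort}
    epm_a = [epms[s.sample_id] for s in cohort if s.group == ga]
    epm_b = [epms[s.sample_id] for s in cohort if s.group == gb]
    t, p = stats.ttest_ind(epm_a, epm_b, equal_var=True)
    epm_test = TestResult(float(t), float(p), "student_t")

    gc_table = gc_flank_table(cohort, genome)
    gc_test = compare_gc_groups(cohort, (ga, gb))
    dens = chrom_density(cohort, genome.lengths)

    lengths_a = np.concatenate([s.lengths for s in cohort if s.group == ga] or [[]])
    lengths_b = np.concatenate([s.lengths for s in cohort if s.group == gb] or [[]])
    peaks = {
        ga: length_density_peaks(lengths_a),
        gb: length_density_peaks(lengths_b),
    }
    ks = ks_length_compare(lengths_a, lengths_b)
    bins_df = length_bin_ratios(cohort, groups=(ga, gb))
    shared = common_start_end(cohort, (ga, gb), tolerance=tolerance)
    diff = per_circle_differential(cohort, shared, signal_mode=signal_mode)

    headline = {
        "epm_mean": {ga: float(np.mean(epm_a)), gb: float(np.mean(epm_b))},
        "epm_higher_group": ga if np.mean(epm_a) > np.mean(epm_b) else gb,
        "median_length": {
            ga: float(np.median(lengths_a)) if len(lengths_a) else float("nan"),
            gb: float(np.median(lengths_b)) if len(lengths_b) else float("nan"),
        },
        "shorter_length_group": (
            ga if np.median(lengths_a) < np.median(lengths_b) else gb
        ),
        "ks_p": ks.pvalue,
        "mean_gc": {
            ga: float(np.mean([r.gc for s in cohort if s.group == ga for r in s.records])),
            gb: float(np.mean([r.gc for s in cohort if s.group == gb for r in s.records])),
        },
        "gc_p": gc_test.pvalue,
    }
    headline["higher_gc_group"] = (
        ga if headline["mean_gc"][ga] > headline["mean_gc"][gb] else gb
    )
    return CohortStats(
        (ga, gb), epms, epm_test, gc_table, gc_test, dens, peaks, ks, bins_df,
        shared, diff, headline,
    )
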