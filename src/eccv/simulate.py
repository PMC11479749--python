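"""Synthetic two-group Circle-seq cohort generator.

Emulates the generative process behind a circle-enrichment sequencing
experiment: each sample carries a catalog of circular DNA molecules
(ground truth), every circle is amplified by rolling-circle amplification
into a long concatemer, and sequencing reads are uniform substrings of
that concatemer. A read that crosses the circle's start-end joint is a
*junction read*: in the ideal alignment it appears as a matched segment
ending (or starting) at one circle boundary with the remainder soft-clipped,
and the clipped bases map back at the other boundary. Only circular
templates yield reads — exonuclease removal of linear DNA is represented by
their absence — but a separate linear-template generator exists so the
caller's specificity can be probed.

Two sample groups are built in, defaulting to the contrasts observed
between healthy-control ("HC-like") and liver-failure ("LF-like") plasma-EV
cohorts: the LF-like group carries more circles per mapped read, shorter
circles whose length density shows five periodic peaks (370, 566, 751, 946
and 1124 bp), and GC-richer circle loci.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from eccv.caller import AlignedSegment
from eccv.genome import SyntheticGenome, generate_genome

#: Length-density peak positions (bp) used as the LF-like mixture modes.
LF_LENGTH_PEAKS = (370, 566, 751, 946, 1124)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class CircleTruth:
    """A ground-truth circle: 0-based half-open genomic interval plus
    the rolling-circle amplification factor (``copies``)."""

    chrom: str
    start: int
    end: int
    sample_id: str
    copies: int = 1

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GroupProfile:
    """Per-group generative parameters.

    circles_per_sample
        Poisson mean of the number of circles per sample.
    length_mixture
        Gaussian mixture components (mode_bp, sd_bp, weight) for circle
        lengths; weights must sum to 1. Lengths are truncated at >= 100 bp.
    gc_shift
        Additive GC preference when placing circles: the sampler tilts the
        locus choice so the mean GC of circle intervals moves by roughly
        this amount relative to the genome background. 0 means uniform
        (exactly unbiased) placement.
    """

    circles_per_sample: float
    length_mixture: tuple[tuple[float, float, float], ...]
    gc_shift: float = 0.0

    def validate(self) -> None:
        w = sum(c[2] for c in self.length_mixture)
        if abs(w - 1.0) > 1e-9:
            raise ConfigError(f"length_mixture weights sum to {w}, expected 1")
        if self.circles_per_sample < 0:
            raise ConfigError("circles_per_sample must be >= 0")


def _default_groups() -> dict[str, GroupProfile]:
    lf_mix = tuple((float(m), 20.0, 1.0 / len(LF_LENGTH_PEAKS)) for m in LF_LENGTH_PEAKS)
    hc_mix = ((800.0, 200.0, 0.5), (1500.0, 300.0, 0.3), (2500.0, 400.0, 0.2))
    return {
        "HC-like": GroupProfile(120.0, hc_mix, gc_shift=0.0),
        "LF-like": GroupProfile(200.0, lf_mix, gc_shift=0.05),
    }


@dataclass
class SimCohortConfig:
    """Full configuration of a simulated two-group cohort.

    Defaults encode the study conditions the generator emulates: the
    LF-like group has more circles per sample (hence higher EPM at equal
    library size), shorter circles with the five periodic length peaks,
    and a +0.05 GC placement preference; sequencing is 150 bp single-end
    with a 1e-3 substitution error rate and ~30 junction reads per circle.
    """

    n_samples_per_group: int = 8
    groups: dict[str, GroupProfile] = field(default_factory=_default_groups)
    depth: float = 30.0
    read_len: int = 150
    seq_error_rate: float = 1e-3
    mapped_reads_total: int = 2_000_000
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000, "chr3": 1_000_000}
    )
    base_gc: float = 0.41
    min_circle_len: int = 100
    # recurrent circles: fixed loci shared across samples (the substrate of
    # the common start-end and differential-occurrence analyses). "Shared"
    # circles appear in samples of both groups at equal probability;
    # "enriched" circles appear 10x more frequently in the enriched group.
    n_shared_circles: int = 8
    shared_presence: float = 0.7
    n_enriched_circles: int = 2
    enriched_presence: float = 0.9
    enriched_background_presence: float = 0.09
    enriched_group: str = "LF-like"
    seed: int = 0

    def validate(self) -> None:
        if self.read_len <= 0:
            raise ConfigError(f"read_len must be positive, got {self.read_len}")
        if not 0.0 <= self.seq_error_rate <= 1.0:
            raise ConfigError("seq_error_rate must be in [0,1]")
        if self.mapped_reads_total <= 0:
            raise ConfigError("mapped_reads_total must be positive")
        if self.n_samples_per_group <= 0:
            raise ConfigError("n_samples_per_group must be positive")
        for rate in (self.shared_presence, self.enriched_presence,
                     self.enriched_background_presence):
            if not 0.0 <= rate <= 1.0:
                raise ConfigError("presence probabilities must be in [0,1]")
        for chrom, length in self.chrom_lengths.items():
            if length < 10_000:
                raise ConfigError(f"chromosome {chrom!r} shorter than 10 kb")
        max_chrom = max(self.chrom_lengths.values())
        for name, prof in self.groups.items():
            prof.validate()
            for mode, _sd, _w in prof.length_mixture:
                if mode > max_chrom:
                    raise ConfigError(
                        f"group {name!r}: mixture mode {mode} exceeds longest chromosome"
                    )

    def with_seed(self, seed: int) -> "SimCohortConfig":
        return replace(self, seed=seed)


def build_genome(config: SimCohortConfig, rng: np.random.Generator | None = None) -> SyntheticGenome:
    """Generate the cohort's reference genome from the config."""
    config.validate()
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed))
    return generate_genome(config.chrom_lengths, config.base_gc, rng)


def _sample_lengths(profile: GroupProfile, n: int, min_len: int, max_len: int,
                    rng: np.random.Generator) -> np.ndarray:
    modes = np.array([c[0] for c in profile.length_mixture])
    sds = np.array([c[1] for c in profile.length_mixture])
    weights = np.array([c[2] for c in profile.length_mixture])
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        k = n - filled
        comp = rng.choice(len(modes), size=k, p=weights)
        draw = np.rint(rng.normal(modes[comp], sds[comp])).astype(np.int64)
        ok = draw[(draw >= min_len) & (draw <= max_len)]
        out[filled : filled + len(ok)] = ok
        filled += len(ok)
    return out


def sample_truth_circles(
    genome: SyntheticGenome,
    config: SimCohortConfig,
    group: str,
    sample_id: str,
    rng: np.random.Generator | None = None,
) -> list[CircleTruth]:
    """Draw one sample's ground-truth circle catalog.

    Circle lengths come from the group's Gaussian mixture, truncated at
    ``config.min_circle_len`` and the longest chromosome. Loci are placed
    uniformly when ``gc_shift`` is 0; otherwise the start position is chosen
    among 64 uniform candidates with exponential-tilt weights so the mean GC
    of chosen intervals shifts by approximately ``gc_shift``.
    """
    if group not in config.groups:
        raise ConfigError(f"unknown group {group!r}; known: {sorted(config.groups)}")
    config.validate()
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed))
    profile = config.groups[group]
    chroms = list(genome.chrom_names)
    clens = np.array([genome.lengths[c] for c in chroms], dtype=np.float64)
    n = int(rng.poisson(profile.circles_per_sample))
    lengths = _sample_lengths(profile, n, config.min_circle_len, int(clens.max()), rng)

    p = genome.base_gc
    pq = max(p * (1 - p), 1e-6)
    circles: list[CircleTruth] = []
    for length in lengths:
        # restrict to chromosomes that can hold this circle
        ok = clens >= length
        probs = np.where(ok, clens, 0.0)
        probs /= probs.sum()
        ci = rng.choice(len(chroms), p=probs)
        chrom = chroms[ci]
        hi = int(clens[ci]) - int(length)
        if profile.gc_shift == 0.0 or hi == 0:
            start = int(rng.integers(0, hi + 1))
        else:
            cand = rng.integers(0, hi + 1, size=64)
            cs = genome.gc_cumsum(chrom)
            gcs = (cs[cand + length] - cs[cand]) / length
            lam = profile.gc_shift * length / pq
            logw = lam * (gcs - gcs.mean())
            w = np.exp(logw - logw.max())
            w /= w.sum()
            start = int(cand[rng.choice(64, p=w)])
        copies = 1 + int(rng.poisson(0.3))
        circles.append(CircleTruth(chrom, start, start + int(length), sample_id, copies))
    circles.sort(key=lambda c: (c.chrom, c.start, c.end))
    return circles


_COMP = str.maketrans("ACGT", "TGCA")
_ALT = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    if len(hits) == 0:
        return seq
    chars = list(seq)
    for i in hits:
        chars[i] = _ALT.get(chars[i], "A")[rng.integers(0, 3)]
    return "".join(chars)


def simulate_circleseq_reads(
    genome: SyntheticGenome,
    truth: list[CircleTruth],
    config: SimCohortConfig,
    rng: np.random.Generator | None = None,
) -> list[AlignedSegment]:
    """Simulate reads from rolling-circle concatemers of the truth circles.

    Every read is a substring of the infinite concatemer of its circle,
    starting at a uniform offset. The number of reads per circle is chosen
    so the expected count of junction-crossing reads is ``depth * copies``.
    Each read's ideal alignment is returned as an :class:`AlignedSegment`:
    non-crossing reads are a full match; junction reads are emitted in one
    of the two equivalent split representations (right soft-clip anchored
    at the circle end, or left soft-clip anchored at the circle start),
    chosen at random. Reads longer than the circle wrap and carry clips on
    both ends. Substitution errors are applied at ``seq_error_rate``; the
    alignment coordinates describe the error-free template.
    """
    config.validate()
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed))
    R = config.read_len
    segments: list[AlignedSegment] = []
    for idx, circ in enumerate(truth):
        L = circ.length
        circle_seq = genome.fetch(circ.chrom, circ.start, circ.end)
        reps = math.ceil((L + R) / L)
        concat = circle_seq * (reps + 1)
        # expected junction-crossers among n uniform-offset reads = n*min(1,R/L)
        n_reads = math.ceil(config.depth * circ.copies * max(L / R, 1.0))
        offsets = rng.integers(0, L, size=n_reads)
        sides = rng.integers(0, 2, size=n_reads)
        for j, o in enumerate(offsets):
            o = int(o)
            seq = _apply_errors(concat[o : o + R], config.seq_error_rate, rng)
            rid = f"{circ.sample_id}:c{idx}:r{j}"
            if o + R <= L:
                cigar = [("M", R)]
                pos = circ.start + o
            else:
                head = L - o  # bases up to the circle end
                rest = R - head
                if sides[j] == 0:
                    # right-clip form: match ends at the circle end
                    pos = circ.start + o
                    cigar = [("M", head), ("S", rest)]
                else:
                    # left-clip form: match starts at the circle start
                    pos = circ.start
                    m = min(rest, L)
                    cigar = [("S", head), ("M", m)]
                    if rest > L:
                        cigar.append(("S", rest - L))
            segments.append(AlignedSegment(rid, circ.chrom, pos, cigar, 60, seq))
    return segments


def simulate_linear_reads(
    genome: SyntheticGenome,
    n_reads: int,
    config: SimCohortConfig,
    rng: np.random.Generator | None = None,
    adapter_clip_frac: float = 0.1,
) -> list[AlignedSegment]:
    """Reads from linear (non-circular) templates: a specificity null.

    Linear fragments align as full-length matches; a fraction carries a
    terminal soft-clip of random bases (adapter read-through), which cannot
    map back to any circle boundary. A circle caller should produce zero
    calls from this input.
    """
    config.validate()
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed))
    R = config.read_len
    chroms = list(genome.chrom_names)
    clens = np.array([genome.lengths[c] for c in chroms], dtype=np.float64)
    probs = clens / clens.sum()
    segments = []
    for j in range(n_reads):
        ci = rng.choice(len(chroms), p=probs)
        chrom = chroms[ci]
        pos = int(rng.integers(0, int(clens[ci]) - R))
        seq = _apply_errors(genome.fetch(chrom, pos, pos + R), config.seq_error_rate, rng)
        if rng.random() < adapter_clip_frac:
            clip = 30
            junk = "".join("ACGT"[k] for k in rng.integers(0, 4, size=clip))
            seq = seq[: R - clip] + junk
            cigar = [("M", R - clip), ("S", clip)]
        else:
            cigar = [("M", R)]
        segments.append(AlignedSegment(f"lin:r{j}", chrom, pos, cigar, 60, seq))
    return segments


# ---------------------------------------------------------------------------
# Cohort driver and file output


@dataclass
class SimulatedSample:
    sample_id: str
    group: str
    truth: list[CircleTruth]
    segments: list[AlignedSegment]
    mapped_reads: int


@dataclass
class SimulatedCohort:
    genome: SyntheticGenome
    samples: list[SimulatedSample]
    config: SimCohortConfig
    recurrent: list[tuple[str, int, int, str]] = field(default_factory=list)


def draw_recurrent_loci(
    genome: SyntheticGenome,
    config: SimCohortConfig,
    rng: np.random.Generator,
) -> list[tuple[str, int, int, str]]:
    """Fixed cohort-level circle loci: (chrom, start, end, kind).

    kind is "shared" (equal presence in both groups) or "enriched"
    (presence boosted in ``config.enriched_group``). Lengths are uniform in
    300-1500 bp, loci uniform on the genome.
    """
    chroms = list(genome.chrom_names)
    clens = np.array([genome.lengths[c] for c in chroms], dtype=float)
    probs = clens / clens.sum()
    loci = []
    kinds = ["shared"] * config.n_shared_circles + ["enriched"] * config.n_enriched_circles
    for kind in kinds:
        length = int(rng.integers(300, 1501))
        ci = rng.choice(len(chroms), p=probs)
        start = int(rng.integers(0, int(clens[ci]) - length))
        loci.append((chroms[ci], start, start + length, kind))
    return loci


def _presence_prob(config: SimCohortConfig, kind: str, group: str) -> float:
    if kind == "shared":
        return config.shared_presence
    if group == config.enriched_group:
        return config.enriched_presence
    return config.enriched_background_presence


def simulate_cohort(
    config: SimCohortConfig,
    outdir: str | Path | None = None,
    with_reads: bool = True,
) -> SimulatedCohort:
    """Simulate the full two-group cohort; optionally write all artifacts.

    Each sample's catalog is the union of its private mixture-drawn circles
    and the cohort's recurrent circles (each included with its per-group
    presence probability). When ``outdir`` is given, writes: ``genome.fa``,
    per-sample ``<sample>.fastq`` / ``<sample>.sam`` / ``<sample>.truth.bed``
    and a cohort ``manifest.tsv`` (sample_id, group, sam_path, truth_bed,
    mapped_reads). All randomness descends from ``config.seed`` through a
    spawned seed tree, so outputs are byte-identical across runs.
    ``with_reads=False`` skips read simulation (truth catalogs only).
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    genome_ss, recurrent_ss, *sample_ss = root.spawn(
        2 + len(config.groups) * config.n_samples_per_group)
    genome = build_genome(config, np.random.default_rng(genome_ss))
    recurrent = draw_recurrent_loci(genome, config,
                                    np.random.default_rng(recurrent_ss))

    samples: list[SimulatedSample] = []
    k = 0
    for group in config.groups:
        tag = group.split("-")[0]
        for i in range(config.n_samples_per_group):
            rng = np.random.default_rng(sample_ss[k])
            k += 1
            sid = f"{tag}_{i + 1}"
            truth = sample_truth_circles(genome, config, group, sid, rng)
            for chrom, start, end, kind in recurrent:
                if rng.random() < _presence_prob(config, kind, group):
                    truth.append(CircleTruth(chrom, start, end, sid,
                                             1 + int(rng.poisson(0.3))))
            truth.sort(key=lambda c: (c.chrom, c.start, c.end))
            segs = (simulate_circleseq_reads(genome, truth, config, rng)
                    if with_reads else [])
            mapped = int(rng.poisson(config.mapped_reads_total))
            samples.append(SimulatedSample(sid, group, truth, segs, mapped))

    cohort = SimulatedCohort(genome, samples, config, recurrent)
    if outdir is not None:
        write_cohort(cohort, outdir)
    return cohort


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> Path:
    from eccv import io as eio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.genome.write_fasta(outdir / "genome.fa")
    rows = []
    for s in cohort.samples:
        fastq = outdir / f"{s.sample_id}.fastq"
        sam = outdir / f"{s.sample_id}.sam"
        bed = outdir / f"{s.sample_id}.truth.bed"
        eio.write_fastq(s.segments, fastq)
        eio.write_sam(s.segments, cohort.genome, sam)
        eio.write_truth_bed(s.truth, bed)
        rows.append((s.sample_id, s.group, sam.name, bed.name, s.mapped_reads))
    manifest = outdir / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("sample_id\tgroup\tsam_path\ttruth_bed\tmapped_reads\n")
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")
    return manifest
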