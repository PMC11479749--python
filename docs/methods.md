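# Methods

## Generative model of the synthetic cohort

The simulator produces everything downstream of wet-lab work in a
Circle-seq experiment on two sample groups, at desk scale.

**Genome.** Bases are i.i.d. with P(G)+P(C) = `base_gc` (default 0.41,
human-like). Default genome: 3 chromosomes × 1 Mb. This is deliberately a
composition-only null: it has no repeats, isochores or mappability
structure, so clip re-mapping is nearly always unique — one reason caller
precision on simulated data is higher than one should expect on a real
genome.

**Circle catalogs.** Per sample, the circle count is Poisson with a
per-group mean (defaults: 120 HC-like, 200 LF-like; with equal library
sizes this programs the higher-EPM contrast). Lengths are drawn from a
per-group Gaussian mixture truncated at ≥ 100 bp: the LF-like default is
five equal-weight modes at 370, 566, 751, 946 and 1124 bp with sd 20 bp
(the periodic short-length peaks the pipeline must recover); the HC-like
default is a broader, longer mixture (800/1500/2500 bp), giving the
shorter-LF contrast and the bin-ratio direction (more 0.5–1 kb, fewer
> 2 kb circles in LF-like).

**GC preference.** With `gc_shift = 0` a circle's start is uniform on the
chromosome (exactly unbiased, verified against genome-wide GC). With a
nonzero shift the start is chosen among K = 64 uniform candidate windows
with weights exp(λ·g), λ = shift·L/(p(1−p)) — the Gaussian exponential
tilt whose asymptotic mean GC shift equals `gc_shift`. At finite K the
realized shift is slightly smaller than nominal (softmax over 64
candidates cannot reach the full tilt); the default LF-like shift of +0.05
realizes ≈ +0.035–0.045, which is the programmed direction and is highly
detectable at cohort scale. We chose candidate-tilting over rejection
sampling because exact exponential-tilt rejection has vanishing acceptance
probability for windows of hundreds of bp.

**Recurrent circles.** Real cohorts contain circles with identical
start–end coordinates in many samples. The generator plants a small set of
fixed loci (default 8 "shared" + 2 "enriched", lengths uniform 300–1500 bp):
shared loci enter any sample with probability 0.7 regardless of group;
enriched loci enter the LF-like group with probability 0.9 and the other
group with 0.09 (a 10× presence contrast). These are the substrate of the
common start–end and differential-occurrence analyses.

**Reads.** Rolling-circle amplification is modeled only as "reads are
uniform substrings of the infinite concatemer"; chimeras, branching and
coverage waves are not modeled. Read count per circle is chosen so the
expected number of junction-crossing reads is `depth × copies`
(default depth 30, copies = 1 + Poisson(0.3)). Errors are substitutions
only (default 10⁻³/base) — no indels, which keeps the simulator's ideal
CIGARs exact. Layout is 150 bp single-end. A junction read is emitted in
one of its two equivalent split representations (right-clip anchored at
the circle end, or left-clip anchored at the start), chosen at random, so
the caller is exercised on both. Linear-template reads (the exonuclease
null) are full-length matches, a fraction carrying an unmappable random
terminal clip to exercise the caller's skip path.

**EPM denominator.** `mapped_reads` is a per-sample library-size figure
(Poisson around 2 × 10⁶ by default), not the count of emitted reads: a real
library is dominated by non-junction reads, and only the ratio matters for
EPM. Per-sample variation in the denominator also breaks ties in the
EPM-scaled differential signal.

**Determinism.** All randomness descends from one seed through a
`SeedSequence` spawn tree (genome / recurrent loci / one stream per
sample); outputs are byte-identical across runs, including FASTA, FASTQ,
SAM and BED files.

## Circle calling

Junction detection uses terminal soft-clips: for a right clip the matched
segment's end is a candidate circle end and the clip is searched upstream
(it belongs at the circle start); symmetrically for left clips. The search
window is `max_circle_len + 2 kb` (default 12 kb) — bounded work per clip.
Matching is exact substring search first, then single-mismatch placements
recovered by the pigeonhole split (one half of the clip must match
exactly), verified by direct comparison. Among valid placements the one
with fewest mismatches wins, ties broken toward the boundary closest to
the anchor (the shortest circle) — a deterministic, conservative rule.
Clips shorter than `min_clip_len` (20 bp) or on reads below `min_mapq`
(20) are ignored; unmappable clips are counted and logged, not fatal.

Evidence is clustered per chromosome: a junction joins a cluster when both
endpoints lie within `boundary_tolerance` (5 bp) of the cluster's running
consensus, the per-endpoint lower median (even counts resolve toward the
smaller coordinate — deterministic, and stable under duplicating the
input, which doubles every support count without moving boundaries).
Clusters need `min_split_reads` (2) members and a consensus length of at
least `min_circle_len` (100 bp). Duplicate reads are not collapsed.
Circles shorter than the read length are callable in principle but a clip
longer than the circle wraps and cannot re-map in full; with the default
length mixtures such circles are vanishingly rare.

## Statistics

- **EPM** = circle count × 10⁶ / mapped reads; group comparison by
  equal-variance two-sample t-test.
- **GC vs flanks**: flanks are the equal-length intervals immediately
  up/downstream; edge-truncated flanks are computed on the remaining piece
  and flagged, fully-off-chromosome flanks reported absent. Group GC is
  compared with the Wilcoxon rank-sum test on per-record GC.
- **Wilcoxon rank-sum**: exact when both sides have ≤ 25 observations,
  via a subset-sum dynamic program over doubled midranks — identical to
  enumerating all C(n₁+n₂, n₁) assignments, including ties, at polynomial
  cost; otherwise a tie-corrected normal approximation without continuity
  correction. Two-sided p = min(1, 2·min(lower tail, upper tail)).
- **Chromosomal density**: per-chromosome circles/Mb, normalized to
  percentages; the reference line is the across-chromosome mean.
- **Length peaks**: Gaussian KDE (Silverman bandwidth) on lengths < 3 kb,
  evaluated on a 1-bp grid; maxima with prominence ≥ 5 % of the peak
  density. Degenerate input (all lengths equal) returns that single value;
  < 10 lengths returns empty with a warning. The prominence cut means a
  weakly populated mode can be missed in small cohorts.
- **KS comparison**: two-sided two-sample KS on lengths < 5 kb, asymptotic
  p (scipy).
- **Length-bin ratios**: default bins < 0.5 / 0.5–1 / 1–2 / > 2 kb; each
  sample contributes its fraction per bin (fractions partition to 1);
  groups compared per bin by Student's t-test.
- **Common start–end circles**: exact (chrom, start, end) identity by
  default; an optional ± tolerance merges nearby keys with the caller's
  clustering rule first.
- **Per-circle differential occurrence**: per sample, the signal is the
  EPM-scaled count of the key (0 when absent); binary presence is
  available behind `signal_mode="presence"`. EPM scaling is the default
  because it carries abundance information and matches the pipeline's
  normalization elsewhere. Two-sided rank-sum per shared key; keys with
  p < 0.05 are flagged with the direction of the higher group median. No
  multiplicity correction by default — the analysis reports raw per-circle
  significance — with Benjamini–Hochberg available via `correct="bh"`.

## Annotation

Overlaps are computed with an interval tree per (track, chromosome);
half-open intervals, strand ignored (circles are unstranded). The eccGene
rule is strict: a circle is an eccGene iff some single gene overlaps it by
**more than** 75 bp (75 exactly does not qualify); the per-gene maximum is
used, not total genic overlap. Gene models are whole gene bodies (GFF3
gene features collapsed to intervals); TE/cCRE subclasses are carried
through verbatim from BED column 5.

## Pipeline

Stages run in order simulate → call → stats → annotate (annotate only when
track paths are configured). Each stage records a signature (config
subset + input digests) and output SHA-256 digests in
`run_manifest.json`; a re-run skips stages whose signature and outputs are
unchanged. Coordinates are 0-based half-open internally and in BED on
disk; browser-style region strings are parsed as 1-based inclusive.

## Problem sizes and what the tests show

The test suite and the acceptance script run at desk scale: genomes of a
few Mb, cohorts of 8–20 samples, ~50–200 circles per sample, junction
depth 20–30 — sizes chosen so every stage runs against exact ground truth
in seconds while all statistical contrasts remain strongly detectable.
Passing tests demonstrate correctness of the algorithms and the programmed
direction of the group contrasts on data from this generator; they do not
demonstrate performance on real Circle-seq data, where repetitive DNA,
chimeric RCA artifacts, indels and uneven coverage would reduce caller
precision and blur boundaries. The caller's clip re-mapping is exactly
solvable here by construction; on a real genome one would add mappability
filtering and two-sided support requirements before trusting precision
estimates.

## Known limitations

- Substitution-only error model; no indels or structural noise.
- No multi-fragment (chimeric multi-locus) circle reconstruction; no
  coverage-based quantification beyond split support.
- Paired-end discordant evidence is not used; only split reads set
  boundaries.
- The per-sample occurrence of a given key after consensus calling is
  effectively 0/1, so the EPM-scaled differential signal mainly encodes
  presence weighted by library size.
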