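# eccv

Simulation, calling, characterization and functional annotation of
extrachromosomal circular DNA (eccDNA) from Circle-seq-style sequencing,
built around the comparison of two plasma-EV cohorts (healthy-control-like
vs liver-failure-like).

## The problem

Cells shed circular DNA molecules — eccDNA — that can end up inside plasma
extracellular vesicles (EVs). Circle-seq enriches them by digesting linear
DNA with exonuclease and amplifying the surviving circles with
rolling-circle amplification (RCA) before sequencing. Because RCA produces
concatemers of the circular template, some reads cross the circle's
start–end joint: aligned to the linear reference they split into a matched
segment abutting one circle boundary plus a soft-clipped tail whose
sequence belongs at the other boundary. Those junction (split) reads are
the evidence this package uses to call circles, and the resulting per-sample
circle catalogs are then compared between groups.

`eccv` provides, as a library with a thin CLI:

- **`eccv.simulate`** — a synthetic two-group cohort generator: random
  reference genome, ground-truth circle catalogs with group-programmed
  contrasts (circle abundance, a five-mode short-length mixture at
  370/566/751/946/1124 bp, GC placement preference, recurrent circles
  shared across samples with a subset enriched in one group), and
  RCA-style reads with ideal soft-clipped alignments (FASTQ + SAM), so the
  whole downstream stack is testable against known truth.
- **`eccv.caller`** — split-read junction calling: terminal soft-clips are
  re-mapped near the candidate partner boundary (exact or one mismatch),
  junction evidence is clustered at ±5 bp, and circles with ≥2 junction
  reads become BED records with length, split support and GC.
- **`eccv.characterize`** — cohort statistics: EPM
  (`circles × 10⁶ / mapped reads`), GC of circles vs equal-length flanks,
  per-chromosome density (% of circles per Mb), KDE length-density peaks,
  two-sample Kolmogorov–Smirnov comparison of lengths (< 5 kb),
  per-length-bin ratio t-tests, common start–end circles across groups,
  and a per-circle differential-occurrence Wilcoxon rank-sum test. The
  rank-sum test uses an exact, tie-aware null distribution (subset-sum
  dynamic programming over midranks) for small samples and a tie-corrected
  normal approximation otherwise.
- **`eccv.annotate`** — interval-tree overlap of circles with gene,
  transposable-element and cCRE tracks; circles overlapping a gene by
  strictly more than 75 bp are flagged as **eccGenes**.
- **`eccv.pipeline` / `eccv` CLI** — one-config orchestration
  (`eccv simulate|call|stats|annotate|run`) with digest-based resumability
  and a machine-readable run manifest.

## Worked example

`examples/` contains one short script per capability. Running
`python examples/03_cohort_statistics.py` (simulate 2 × 4 samples, call
circles, characterize) prints:

```
mean EPM: HC-like = 58.6, LF-like = 101.9 (t-test p = 1.26e-04)
median length: HC-like = 1242 bp, LF-like = 755 bp (KS D = 0.499, p = 2.93e-69)
mean GC: HC-like = 0.410, LF-like = 0.446 (rank-sum p = 8.92e-156)
LF-like length peaks (bp): [379, 574, 745, 953]
common start-end circles: {'a_only': 446, 'b_only': 791, 'shared': 9}
```

Reading the numbers: the LF-like group carries more circles per million
mapped reads (higher EPM), its circles are shorter (the KS test compares
the two cumulative length distributions below 5 kb) and GC-richer, and the
detected length-density peaks fall near the generator's programmed modes.
"Shared" counts circles whose exact (chromosome, start, end) key occurs in
samples of both groups; those keys then enter the per-circle differential
test.

The same analysis from the shell:

```bash
eccv run --config examples/demo_config.yaml --outdir demo_out
cat demo_out/stats/summary.json
```

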