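# Demo cohort: 2 groups x 4 samples on a 3 x 400 kb genome.
seed: 42
n_samples_per_group: 4
chrom_lengths: {chr1: 400000, chr2: 400000, chr3: 400000}
base_gc: 0.41
depth: 20
read_len: 150
seq_error_rate: 0.001
mapped_reads_total: 1000000
groups:
  HC-like:
    circles_per_sample: 60
    gc_shift: 0.0
    length_mixture: [[800, 200, 0.5], [1500, 300, 0.3], [2500, 400, 0.2]]
  LF-like:
    circles_per_sample: 110
    gc_shift: 0.05
    length_mixture: [[370, 20, 0.2], [566, 20, 0.2], [751, 20, 0.2], [946, 20, 0.2], [1124, 20, 0.2]]
caller:
  min_clip_len: 20
  min_mapq: 20
  min_split_reads: 2
stats:
  tolerance: 0
  signal_mode: epm
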