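"""Run the cohort characterization battery on called circle catalogs.

Computes EPM (circles per million mapped reads), GC of circles vs
equal-length flanks, per-chromosome density, length-density peaks, the
cumulative-length KS comparison, length-bin ratio t-tests, common
start-end circles, and the per-circle differential-occurrence test.
"""

import numpy as np

from eccv import (SampleEccSet, SimCohortConfig, call_sample,
                  compute_cohort_stats, simulate_cohort)

cfg = SimCohortConfig(n_samples_per_group=4, seed=3)
cohort = simulate_cohort(cfg)

sets = [
    SampleEccSet(s.sample_id, s.group,
                 call_sample(s.segments, cohort.genome, sample_id=s.sample_id),
                 s.mapped_reads)
    for s in cohort.samples
]
cs = compute_cohort_stats(sets, cohort.genome, groups=("HC-like", "LF-like"))

h = cs.headline
print(f"mean EPM: HC-like = {h['epm_mean']['HC-like']:.1f}, "
      f"LF-like = {h['epm_mean']['LF-like']:.1f} "
      f"(t-test p = {cs.group_epm_test.pvalue:.2e})")
print(f"median length: HC-like = {h['median_length']['HC-like']:.0f} bp, "
      f"LF-like = {h['median_length']['LF-like']:.0f} bp "
      f"(KS D = {cs.ks_result.statistic:.3f}, p = {cs.ks_result.pvalue:.2e})")
print(f"mean GC: HC-like = {h['mean_gc']['HC-like']:.3f}, "
      f"LF-like = {h['mean_gc']['LF-like']:.3f} "
      f"(rank-sum p = {cs.gc_group_test.pvalue:.2e})")
print(f"LF-like length peaks (bp): "
      f"{np.round(cs.length_peaks['LF-like']).astype(int).tolist()}")
print(f"common start-end circles: {cs.common_circles.counts}")
print("-> all three headline contrasts (more, shorter, GC-richer circles in the")
print("   LF-like group) come out in the programmed direction; the detected LF-like")
print("   length peaks sit near the generator modes (370/566/751/946/1124 bp) —")
print("   at this cohort size a low-density mode can fall below the prominence cut.")
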