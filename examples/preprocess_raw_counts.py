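"""Run the preprocessing chain on raw-count-like data.

Simulates a Poisson count matrix, then applies the standard chain:
drop undetected genes -> counts-per-million -> log2(x+1) -> quantile
normalization. The output is the normalized log matrix the correction
consumes.
"""

import numpy as np

from npmatch import SimConfig, preprocess_counts, simulate_counts

counts, annotation, _ = simulate_counts(SimConfig(p=500, n=12, seed=3, baseline_mean=6))
normalized = preprocess_counts(counts)

print(f"raw counts:  {counts.n_features} genes x {counts.n_samples} samples, "
      f"library sizes {counts.values.sum(axis=0).min():.0f}-{counts.values.sum(axis=0).max():.0f}")
print(f"normalized:  {normalized.n_features} genes kept (all-zero genes dropped)")
# tie-averaging (the many zero counts) reshuffles values within tie groups
# but preserves each sample's total exactly, so all column sums coincide
col_sums = normalized.values.sum(axis=0)
print("after quantile normalization all samples share one total:",
      bool(np.allclose(col_sums, col_sums[0])))
print(f"value range on the log2 scale: [{normalized.values.min():.2f}, "
      f"{normalized.values.max():.2f}]")
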