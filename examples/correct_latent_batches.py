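"""Correct latent batch effects in a simulated dataset and measure the gain.

Simulates a 2000-gene, 60-sample, two-class dataset spread over 3 hidden
batches, runs the nearest-pair matching correction using only the
phenotype labels, and compares metrics before and after. Higher phenotype
silhouette / lower batch silhouette / integrated score above 1 all mean
the correction recovered biological structure the batches were masking.
"""

from npmatch import NpmConfig, SimConfig, evaluate, integrated_score, npm_correct, simulate

matrix, annotation, truth = simulate(SimConfig(seed=7))
corrected = npm_correct(matrix, annotation, NpmConfig(k=1, n_top_features=2000))

before = evaluate(matrix, annotation, method_name="none")
after = evaluate(corrected, annotation, method_name="npm")
score = integrated_score(after, before)

print(f"dataset: {matrix.n_features} genes x {matrix.n_samples} samples, "
      f"{len(set(annotation.batch))} hidden batches")
print(f"phenotype silhouette: {before.silhouette:+.3f} -> {after.silhouette:+.3f}")
print(f"batch silhouette:     {before.batch_silhouette:+.3f} -> {after.batch_silhouette:+.3f}")
print(f"DEGs:                 {before.n_degs} -> {after.n_degs}")
print(f"SNR:                  {before.snr:.3f} -> {after.snr:.3f}")
print(f"PC1 ratio:            {before.pc1_ratio:.3f} -> {after.pc1_ratio:.3f}")
print(f"integrated score:     {score:.3f}  (uncorrected reference = 1)")
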