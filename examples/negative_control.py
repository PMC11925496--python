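"""Permuted-phenotype negative control.

The correction stratifies on phenotype labels, so handing it shuffled
labels should destroy — not fake — its benefit. We correct once with the
true labels and once with permuted labels, then score both against the
TRUE labels. The permuted run's score should fall well below the true
run's.
"""

import warnings

from npmatch import SimConfig, evaluate, integrated_score, npm_correct, permutation_control, simulate

matrix, annotation, _ = simulate(SimConfig(seed=11))
reference = evaluate(matrix, annotation)

true_run = evaluate(npm_correct(matrix, annotation), annotation)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # the broken run floors its ratios, loudly
    permuted = permutation_control(matrix, annotation, seed=11)
    s_true = integrated_score(true_run, reference)
    s_perm = integrated_score(permuted, reference)

print(f"score with true labels:     {s_true:.3f}")
print(f"score with permuted labels: {s_perm:.3f}")
print("control behaves correctly" if s_perm < s_true else "WARNING: control failed")
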