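"""Compare correction methods across simulated scenarios by mean rank.

Runs the blind nearest-pair correction against two known-batch
comparators (linear removal with a protected phenotype design, and plain
per-batch mean centering) plus the uncorrected baseline, over three named
scenarios. Each method gets an integrated score per dataset (uncorrected
= 1) and a mean rank across datasets (1 = best).
"""

from npmatch import run_benchmark, scenario_suite, simulate

wanted = {"balanced", "confounded", "tiny"}
datasets = {}
for cfg in scenario_suite():
    if cfg.name in wanted:
        matrix, annotation, _ = simulate(cfg)
        datasets[cfg.name] = (matrix, annotation)

report = run_benchmark(datasets)

print("integrated scores (uncorrected = 1):")
for ds, methods in report["datasets"].items():
    row = ", ".join(f"{m}={r['score']:.2f}" for m, r in methods.items())
    print(f"  {ds}: {row}")
print("mean rank across datasets (1 = best):")
for method, rank in report["mean_rank"].items():
    print(f"  {method}: {rank:.2f}")
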