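"""The end-to-end pipeline in one call.

Simulates a cohort, preprocesses it, tests all pairwise comparisons,
scores top markers, classifies each pair, tests marker-set overlaps and
clusters the samples, writing every table plus a summary.json.  The same
config (and seed) always produces a byte-identical summary.
"""

import json

from mirdiag import CohortConfig, CVConfig, PipelineConfig, run_pipeline

config = PipelineConfig(
    out_dir="scratch/pipeline_demo",
    seed=42,
    cohort=CohortConfig(n_mirnas=300,
                        class_sizes={"PDAC": 20, "CP": 15, "healthy": 15},
                        n_differential=30, effect_size=1.5, seed=0),
    cv=CVConfig(k_folds=5, n_repetitions=5, subset_sizes=(5, 10),
                n_permutation_reps=5, seed=0),
    n_overlap_permutations=10_000,
    log_level="WARNING",
)
summary = run_pipeline(config)

for name, comp in summary["comparisons"].items():
    line = f"{name:18s} significant={comp['n_significant']:3d}"
    if "cv" in comp:
        line += f"  AUC={comp['cv']['auc']['mean']:.3f}"
    print(line)
print("venn regions:", summary["venn_region_sizes"])
if "overlap_test" in summary:
    ot = summary["overlap_test"]
    print(f"overlap test: observed={ot['observed_overlap']} "
          f"expected={ot['closed_form_expectation']:.1f} "
          f"p={ot['empirical_p']:.2e}")
print("full summary:", json.dumps(summary, sort_keys=True)[:100], "...")
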