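"""Train the final classifier and benchmark it on an independent cohort.

Runs the full image-based chain at the study's reference cohort sizes:
a 68-patient development cohort (54 lower / 14 high risk) trains the
quadratic-kernel SVM with its averaged-F_max decision threshold; a
53-patient validation cohort (39 lower / 14 high) is then scored and the
classifier is compared against the ordinal reader-score benchmark and a
100-fold label-permutation null.
"""

from radstrat import CohortSpec, CVPlan, build_report, extract_table, generate_cohort
from radstrat.pipeline import train_final_for_algorithm

seed = 1
dev = extract_table(generate_cohort(CohortSpec(14, 54, image_size=64, seed=seed)))
val = extract_table(generate_cohort(CohortSpec(14, 39, image_size=64, seed=seed + 500_009)))

final = train_final_for_algorithm("QSVM", dev, CVPlan(folds=5, runs=10, base_seed=seed))
print(f"final QSVM decision threshold (mean of 10 per-run F_max thresholds): "
      f"{final.threshold:.4f}")

report = build_report(final, val, replicates=100, seed=seed)
print("\nbenchmark table (columns: AUC, then F/P/R for the high-risk and "
      "lower-risk classes):")
print(report.to_frame().to_string())
print("\nclassifier row shows the bootstrap-Friedman comparison p-value vs the "
      "reader score in parentheses; the permutation row shows the standard "
      "error over the 100 label-permuted copies. A permutation-null AUC near "
      "0.5 confirms the classifier's validation performance reflects a real "
      "feature-label relationship rather than chance.")
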