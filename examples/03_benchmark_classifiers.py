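"""Benchmark the seven candidate classifiers with oversampled repeated CV.

Runs stratified 5-fold cross-validation (3 repeats here for speed; the
study default is 10) of all seven algorithms on a synthetic development
table, ranks them per run on each of the seven evaluation measures, and
applies the Friedman omnibus test with the Nemenyi critical difference to
find the statistically best performer.
"""

import radstrat as rs
from radstrat import CohortSpec, CVPlan

dev = rs.generate_feature_table(
    CohortSpec(n_high=14, n_lower=54, seed=7, effect_size=0.6), n_informative=20
)
plan = CVPlan(folds=5, runs=3, base_seed=7)
results = rs.run_cv(rs.default_specs(seed=7), dev, plan)

auc = results.measure_matrix("auc").mean()
print("mean cross-validated AUC per algorithm:")
for alg, value in auc.sort_values(ascending=False).items():
    print(f"  {alg:7s} {value:.3f}")

analysis = rs.rank_analysis(results, "auc")
print(f"\nFriedman chi-square {analysis.friedman_statistic:.2f}"
      f" (p = {analysis.friedman_p:.3g}); Nemenyi CD = {analysis.nemenyi_cd:.3f}")
print("algorithms within one CD of the best mean rank:", ", ".join(analysis.top_group))

best, provenance = rs.select_best(rs.analyze_all_measures(results))
print(f"\nselected algorithm (top group of every measure, lowest grand mean rank): {best}")
print("with only 3 repeats the CD is wide, so several algorithms are "
      "statistically indistinguishable from the best; the study default of "
      "10 repeats narrows the CD to about 2.85 rank units for 7 algorithms.")
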