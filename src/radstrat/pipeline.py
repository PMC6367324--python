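"""End-to-end orchestration: simulate -> extract -> select -> validate.

Convenience wrappers that chain the package stages with one master seed,
mirroring how the framework is meant to be used: candidate benchmarking
and model selection on a development cohort, then the final classifier
with its averaged-F_max threshold evaluated on an independent cohort
against the reader-score and permutation benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import model_selection as ms
from .config import StudyConfig
from .features import extract_table
from .learners import LearnerSpec
from .model_selection import CVPlan, FinalClassifier, RunResults
from .synthetic import CohortSpec, generate_cohort
from .validation import BenchmarkReport, build_report


@dataclass
class StudyResult:
    """Everything the framework produces for one development/validation pair."""

    cv_results: RunResults
    analyses: dict
    best_algorithm: str
    selection_provenance: dict
    final: FinalClassifier
    report: BenchmarkReport


def simulate_feature_tables(
    n_dev: tuple[int, int] = (14, 54),
    n_val: tuple[int, int] = (14, 39),
    image_size: int = 64,
    effect_size: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic development and validation feature tables via the image stage.

    ``n_dev``/``n_val`` are (n_high, n_lower) cohort sizes.  The two
    cohorts use independent sub-seeds of ``seed``.
    """
    dev_spec = CohortSpec(*n_dev, image_size=image_size, effect_size=effect_size, seed=seed)
    val_spec = CohortSpec(
        *n_val, image_size=image_size, effect_size=effect_size, seed=seed + 500_009
    )
    return (
        extract_table(generate_cohort(dev_spec)),
        extract_table(generate_cohort(val_spec)),
    )


def run_study(
    dev_table: pd.DataFrame,
    val_table: pd.DataFrame,
    config: StudyConfig | None = None,
    seed: int = 0,
    replicates: int = 100,
) -> StudyResult:
    """Run the complete selection + validation framework on feature tables."""
    config = config or StudyConfig()
    plan = CVPlan(
        folds=config.cv.folds,
        runs=config.cv.runs,
        stratified=config.cv.stratified,
        base_seed=seed,
        oversample=config.cv.oversample,
    )
    specs = config.learner_specs(seed=seed)
    results = ms.run_cv(specs, dev_table, plan)
    analyses = ms.analyze_all_measures(results)
    best, provenance = ms.select_best(analyses)
    best_spec = next(s for s in specs if s.algorithm == best)
    final = ms.train_final(
        best_spec, dev_table, results, oversample=config.final_oversample
    )
    report = build_report(final, val_table, replicates=replicates, seed=seed)
    return StudyResult(
        cv_results=results,
        analyses=analyses,
        best_algorithm=best,
        selection_provenance=provenance,
        final=final,
        report=report,
    )


def train_final_for_algorithm(
    algorithm: str,
    dev_table: pd.DataFrame,
    plan: CVPlan,
    oversample_final: bool = True,
) -> FinalClassifier:
    """Final classifier for one named algorithm: CV for the per-run
    F_max thresholds, then a full-set fit with the averaged threshold."""
    spec = LearnerSpec(algorithm, seed=plan.base_seed)
    results = ms.run_cv([spec], dev_table, plan)
    return ms.train_final(spec, dev_table, results, oversample=oversample_final)
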