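"""Independent-cohort validation and the benchmark report.

The final classifier (model + fixed averaged-F_max threshold) is applied
to an independent cohort and compared against two benchmarks:

* the ordinal reader score (PI-RADS-like, 1–5), binarized at > 3 and used
  raw as a ranking score for AUC;
* a permutation null — the fixed classifier evaluated on 100 copies of
  the validation set whose labels were randomly permuted with class
  counts preserved (expected AUC 0.5).

Statistical comparison of classifier vs reader score uses 100 paired
bootstrap resamples of the validation cohort and, per measure, a Friedman
test over the 100 paired blocks with k = 2 methods (equivalent to a sign
test; retained in the Friedman form used for the candidate ranking).
The results are assembled into a three-row benchmark table (classifier /
reader score / permutation null) over the seven validation measures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError, UndefinedMetricError
from .metrics import PredictionSet, binarize, confusion_prf, evaluate_at, roc_auc
from .model_selection import FinalClassifier, friedman_test

#: Measure keys of the validation report, in table column order.
REPORT_MEASURES = ("auc", "high_f", "high_p", "high_r", "lower_f", "lower_p", "lower_r")

PIRADS_THRESHOLD = 3  # score > 3 => high risk


def apply_classifier(
    final: FinalClassifier, table: pd.DataFrame
) -> tuple[PredictionSet, np.ndarray]:
    """Score a cohort and binarize at the final threshold.

    Returns the prediction set (scores + true labels) and the hard
    predicted classes (high iff score >= threshold).
    """
    scores = final.model.score(table)
    preds = PredictionSet(
        scores,
        table["label"].to_numpy(dtype=object),
        sample_ids=np.asarray(table.index, dtype=object),
    )
    return preds, binarize(scores, final.threshold)


def pirads_binarize(score: int) -> str:
    """Risk class from an ordinal 1–5 reader score: > 3 is high risk."""
    if score not in (1, 2, 3, 4, 5):
        raise InvalidInputError(f"ordinal score must be in 1..5, got {score!r}")
    return "high" if score > PIRADS_THRESHOLD else "lower"


def pirads_evaluate(scores: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    """The seven validation measures for the ordinal-score benchmark.

    AUC treats the raw ordinal score as the ranking score (ties credited
    0.5); precision/recall/F per class come from the > 3 binarization.
    """
    scores = np.asarray(scores)
    labels = np.asarray(labels, dtype=object)
    hard = np.array([pirads_binarize(int(s)) for s in scores], dtype=object)
    # ordinal scores are not probabilities; rescale into [0,1] for PredictionSet
    preds = PredictionSet((scores - 1) / 4.0, labels)
    out = {"auc": roc_auc(preds)}
    for cls in ("high", "lower"):
        p, r, f = confusion_prf(hard, labels, cls)
        out[f"{cls}_f"] = f
        out[f"{cls}_p"] = p
        out[f"{cls}_r"] = r
    return out


def permutation_benchmark(
    final: FinalClassifier,
    table: pd.DataFrame,
    replicates: int = 100,
    seed: int = 0,
) -> dict[str, dict[str, float]]:
    """Fixed-classifier performance on label-permuted validation copies.

    Labels are permuted within the cohort (class counts preserved) for
    each replicate; scores and threshold stay fixed.  Returns per-measure
    mean, sd and standard error sd/sqrt(replicates).
    """
    if replicates < 2:
        raise InvalidInputError("need at least 2 replicates")
    preds, _ = apply_classifier(final, table)
    rng = np.random.default_rng(seed)
    records = []
    for _ in range(replicates):
        permuted = preds.labels[rng.permutation(len(preds))]
        shuffled = PredictionSet(preds.scores, permuted)
        records.append(evaluate_at(shuffled, final.threshold))
    frame = pd.DataFrame(records)
    return {
        m: {
            "mean": float(frame[m].mean()),
            "sd": float(frame[m].std(ddof=1)),
            "se": float(frame[m].std(ddof=1) / np.sqrt(replicates)),
        }
        for m in REPORT_MEASURES
    }


def _bootstrap_indices(
    rng: np.random.Generator, labels: np.ndarray, n: int
) -> np.ndarray:
    """Resample indices with replacement, redrawing until both classes appear."""
    for _ in range(1000):
        idx = rng.integers(0, n, size=n)
        if len(set(labels[idx])) == 2:
            return idx
    raise UndefinedMetricError("could not draw a two-class bootstrap replicate")


def bootstrap_compare(
    classifier_preds: PredictionSet,
    classifier_threshold: float,
    comparator_scores: np.ndarray,
    replicates: int = 100,
    seed: int = 0,
) -> dict[str, float]:
    """Paired-bootstrap Friedman comparison of classifier vs ordinal score.

    Each replicate draws one resample of the cohort (shared between the
    two methods) and computes the seven measures for both.  Per measure a
    Friedman test over the ``replicates`` paired blocks (k = 2 methods)
    yields the reported p-value.
    """
    labels = classifier_preds.labels
    comparator_scores = np.asarray(comparator_scores)
    if comparator_scores.shape != labels.shape:
        raise InvalidInputError("comparator scores must align with classifier samples")
    n = len(labels)
    rng = np.random.default_rng(seed)
    rows_clf, rows_cmp = [], []
    for _ in range(replicates):
        idx = _bootstrap_indices(rng, labels, n)
        sub = PredictionSet(classifier_preds.scores[idx], labels[idx])
        rows_clf.append(evaluate_at(sub, classifier_threshold))
        rows_cmp.append(pirads_evaluate(comparator_scores[idx], labels[idx]))
    clf = pd.DataFrame(rows_clf)
    cmp_ = pd.DataFrame(rows_cmp)
    p_values = {}
    for m in REPORT_MEASURES:
        diff = clf[m].to_numpy() - cmp_[m].to_numpy()
        # within-block ranks of the two methods: 1 for the better, ties 1.5
        r_clf = np.where(diff > 0, 1.0, np.where(diff < 0, 2.0, 1.5))
        ranks = np.column_stack([r_clf, 3.0 - r_clf])
        _, p = friedman_test(ranks)
        p_values[m] = float(p)
    return p_values


@dataclass
class BenchmarkReport:
    """Three-row benchmark comparison over the seven validation measures."""

    classifier: dict[str, float]
    comparison_p: dict[str, float]
    comparator: dict[str, float]
    permutation: dict[str, dict[str, float]]
    n_patients: int
    replicates: int

    def to_frame(self) -> pd.DataFrame:
        """Table-shaped report: one row per method, one column per measure.

        The classifier row carries the bootstrap comparison p-value in
        parentheses, the permutation row its standard error.
        """
        rows = {
            "Reader score benchmark": {
                m: f"{self.comparator[m]:.2f}" for m in REPORT_MEASURES
            },
            "Radiomics classifier": {
                m: f"{self.classifier[m]:.2f} ({self.comparison_p[m]:.3g})"
                for m in REPORT_MEASURES
            },
            "Randomized validation sets": {
                m: f"{self.permutation[m]['mean']:.2f} ({self.permutation[m]['se']:.2f})"
                for m in REPORT_MEASURES
            },
        }
        return pd.DataFrame(rows).T[list(REPORT_MEASURES)]

    def to_markdown(self) -> str:
        frame = self.to_frame()
        header = "| Method | " + " | ".join(frame.columns) + " |"
        sep = "|" + " --- |" * (len(frame.columns) + 1)
        lines = [header, sep]
        for name, row in frame.iterrows():
            lines.append("| " + name + " | " + " | ".join(row) + " |")
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(
            {
                "classifier": self.classifier,
                "comparison_p": self.comparison_p,
                "comparator": self.comparator,
                "permutation": self.permutation,
                "n_patients": self.n_patients,
                "replicates": self.replicates,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "BenchmarkReport":
        return cls(**json.loads(text))

    def save(self, directory) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "benchmark.json").write_text(self.to_json())
        self.to_frame().to_csv(directory / "benchmark.csv")
        (directory / "benchmark.md").write_text(self.to_markdown())
        return directory


def build_report(
    final: FinalClassifier,
    table: pd.DataFrame,
    replicates: int = 100,
    seed: int = 0,
) -> BenchmarkReport:
    """Full validation benchmark on one independent cohort table.

    The table must carry the feature columns, a ``label`` column and a
    ``pirads`` column with the ordinal reader scores.
    """
    if "pirads" not in table.columns:
        raise InvalidInputError("validation table must include a 'pirads' column")
    preds, _ = apply_classifier(final, table)
    classifier_eval = evaluate_at(preds, final.threshold)
    pirads = table["pirads"].to_numpy()
    comparator_eval = pirads_evaluate(pirads, preds.labels)
    permutation = permutation_benchmark(final, table, replicates, seed=seed)
    comparison = bootstrap_compare(
        preds, final.threshold, pirads, replicates, seed=seed + 1
    )
    return BenchmarkReport(
        classifier={m: float(classifier_eval[m]) for m in REPORT_MEASURES},
        comparison_p=comparison,
        comparator={m: float(comparator_eval[m]) for m in REPORT_MEASURES},
        permutation=permutation,
        n_patients=len(table),
        replicates=replicates,
    )
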