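"""Oversampled repeated cross-validation, Friedman–Nemenyi rank analysis
and final-classifier training.

The framework evaluates the seven candidate algorithms with stratified
5-fold cross-validation repeated 10 times.  Inside every round the
training folds (only) are rebalanced by random oversampling of the
minority class; the held-out fold is scored untouched, so out-of-fold
predictions cover each development patient exactly once per run.  Per
run and algorithm the seven evaluation measures (AUC and F_max/P_max/
R_max for each class) are computed, algorithms are ranked within runs,
and the Friedman omnibus test plus the Nemenyi critical difference decide
which algorithms are statistically indistinguishable per measure.  The
algorithm in the top statistical group of every measure (lowest grand
mean rank on ties) becomes the final classifier, trained on the whole
(oversampled) development set with its decision threshold set to the mean
of the ten per-run F_max-maximizing thresholds for the high-risk class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata, wilcoxon
from sklearn.model_selection import StratifiedKFold

from . import metrics
from .errors import (
    DegenerateTrainingError,
    InvalidInputError,
    UndefinedMetricError,
    UnsupportedParameterError,
)
from .learners import LearnerSpec, TrainedModel, fit
from .metrics import MEASURES, EvaluationResult, PredictionSet, evaluate


@dataclass(frozen=True)
class CVPlan:
    """Cross-validation layout: stratified k folds repeated ``runs`` times."""

    folds: int = 5
    runs: int = 10
    stratified: bool = True
    base_seed: int = 0
    oversample: bool = True

    def __post_init__(self) -> None:
        if self.folds < 2 or self.runs < 1:
            raise InvalidInputError("need folds >= 2 and runs >= 1")


def random_oversample(table: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Duplicate minority-class rows (with replacement) to balance classes.

    Majority rows are untouched; the output row order is shuffled
    deterministically by ``seed``.  Every added row is an exact copy of an
    input minority row — no synthesis.
    """
    labels = table["label"]
    counts = labels.value_counts()
    if len(counts) < 2:
        raise DegenerateTrainingError("oversampling requires two classes")
    minority = counts.idxmin()
    deficit = int(counts.max() - counts.min())
    rng = np.random.default_rng(seed)
    if deficit > 0:
        pool = table[labels == minority]
        extra = pool.iloc[rng.integers(0, len(pool), size=deficit)]
        table = pd.concat([table, extra])
    perm = rng.permutation(len(table))
    return table.iloc[perm]


def make_folds(labels: np.ndarray, folds: int, seed: int) -> np.ndarray:
    """Stratified fold assignment (0..folds-1 per sample), deterministic by seed.

    Per-class fold sizes differ by at most one.  Raises when the minority
    class cannot populate every fold.
    """
    labels = np.asarray(labels, dtype=object)
    _, counts = np.unique(labels, return_counts=True)
    if folds > counts.min():
        raise InvalidInputError(
            f"{folds} folds exceed the minority class count {counts.min()}"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=int)
    for k, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignment[test_idx] = k
    return assignment


@dataclass
class RunResults:
    """Out-of-fold predictions and evaluations per (algorithm, run)."""

    algorithms: list[str]
    plan: CVPlan
    predictions: dict[tuple[str, int], PredictionSet] = field(default_factory=dict)
    evaluations: dict[tuple[str, int], EvaluationResult] = field(default_factory=dict)
    fold_seeds: list[int] = field(default_factory=list)
    failures: dict[tuple[str, int], str] = field(default_factory=dict)

    def measure_matrix(self, measure: str) -> pd.DataFrame:
        """runs x algorithms matrix of one evaluation measure."""
        if measure not in MEASURES:
            raise InvalidInputError(f"unknown measure {measure!r}")
        data = {
            alg: [self.evaluations[(alg, r)].measure(measure) for r in range(self.plan.runs)]
            for alg in self.algorithms
        }
        return pd.DataFrame(data, index=range(self.plan.runs))

    def high_risk_thresholds(self, algorithm: str) -> list[float]:
        """Per-run thresholds that maximized the high-risk F-measure."""
        return [
            self.evaluations[(algorithm, r)].high.threshold_star
            for r in range(self.plan.runs)
        ]


def run_cv(
    specs: list[LearnerSpec], table: pd.DataFrame, plan: CVPlan
) -> RunResults:
    """Repeated stratified CV of all candidate algorithms.

    Training folds are oversampled (when ``plan.oversample``) *after* the
    split, so held-out samples never leak into training as copies.  Fold
    seeds derive from ``plan.base_seed + run`` and are recorded.
    """
    labels = table["label"].to_numpy(dtype=object)
    if len(set(labels)) < 2:
        raise DegenerateTrainingError("cross-validation requires two classes")
    results = RunResults(algorithms=[s.algorithm for s in specs], plan=plan)
    for r in range(plan.runs):
        run_seed = plan.base_seed + r
        results.fold_seeds.append(run_seed)
        assignment = make_folds(labels, plan.folds, run_seed)
        oof_scores = {alg: np.full(len(table), np.nan) for alg in results.algorithms}
        for k in range(plan.folds):
            test_mask = assignment == k
            train = table.iloc[~test_mask]
            test = table.iloc[test_mask]
            if plan.oversample:
                train = random_oversample(train, seed=run_seed * 131 + k)
            for spec in specs:
                spec_r = LearnerSpec(spec.algorithm, spec.hyperparameters, seed=run_seed)
                try:
                    model = fit(spec_r, train)
                    oof_scores[spec.algorithm][test_mask] = model.score(test)
                except Exception as exc:  # recorded per-cell, not fatal
                    results.failures[(spec.algorithm, r)] = f"fold {k}: {exc}"
        for alg in results.algorithms:
            if (alg, r) in results.failures:
                continue
            preds = PredictionSet(
                oof_scores[alg], labels, sample_ids=np.asarray(table.index, dtype=object)
            )
            results.predictions[(alg, r)] = preds
            results.evaluations[(alg, r)] = evaluate(preds)
    return results


# ---------------------------------------------------------------------------
# Friedman / Nemenyi
# ---------------------------------------------------------------------------

def friedman_test(rank_matrix: np.ndarray) -> tuple[float, float]:
    """Tie-corrected Friedman chi-square test from a runs x algorithms
    rank matrix (rank 1 = best, ties as average ranks).

    Uses the general tie-corrected statistic
    ``(k-1) * (sum_j R_j^2 - n^2 k (k+1)^2 / 4) /
    (sum_ij r_ij^2 - n k (k+1)^2 / 4)`` with a chi-square reference on
    k-1 degrees of freedom.  A fully tied matrix yields statistic 0 and
    p = 1 by convention.
    """
    R = np.asarray(rank_matrix, dtype=float)
    if R.ndim != 2 or R.shape[0] < 2 or R.shape[1] < 2:
        raise InvalidInputError("rank matrix must be at least 2 x 2")
    n, k = R.shape
    col_sums = R.sum(axis=0)
    num = (k - 1) * float((col_sums**2).sum() - n * n * k * (k + 1) ** 2 / 4.0)
    den = float((R**2).sum() - n * k * (k + 1) ** 2 / 4.0)
    if den <= 1e-12:  # all algorithms tied in every run
        return 0.0, 1.0
    statistic = num / den
    return statistic, float(chi2.sf(statistic, k - 1))


#: Critical values of the studentized range statistic at infinite degrees
#: of freedom, divided by sqrt(2), for k = 2..20 compared methods — the
#: constants of the Nemenyi critical difference.
_NEMENYI_Q = {
    0.05: [
        1.960, 2.343, 2.569, 2.728, 2.850, 2.949, 3.031, 3.102, 3.164,
        3.219, 3.268, 3.313, 3.354, 3.391, 3.426, 3.458, 3.489, 3.517, 3.544,
    ],
    0.10: [
        1.645, 2.052, 2.291, 2.459, 2.589, 2.693, 2.780, 2.855, 2.920,
        2.978, 3.030, 3.077, 3.120, 3.159, 3.196, 3.230, 3.261, 3.291, 3.319,
    ],
}


def nemenyi_q(k: int, alpha: float = 0.05) -> float:
    """Tabulated Nemenyi constant q_alpha(k) for k = 2..20."""
    if alpha not in _NEMENYI_Q:
        raise UnsupportedParameterError(f"alpha must be 0.05 or 0.10, got {alpha}")
    if not 2 <= k <= 20:
        raise UnsupportedParameterError(f"k must be in 2..20, got {k}")
    return _NEMENYI_Q[alpha][k - 2]


def nemenyi_cd(k: int, n: int, alpha: float = 0.05) -> float:
    """Nemenyi critical difference CD = q_alpha(k) * sqrt(k(k+1)/(6n))."""
    if n < 2:
        raise UnsupportedParameterError(f"n must be >= 2, got {n}")
    return nemenyi_q(k, alpha) * math.sqrt(k * (k + 1) / (6.0 * n))


@dataclass
class RankAnalysis:
    """Friedman–Nemenyi analysis of one evaluation measure."""

    measure: str
    algorithms: list[str]
    rank_matrix: np.ndarray  # runs x algorithms, rank 1 = best
    mean_ranks: np.ndarray
    friedman_statistic: float
    friedman_p: float
    nemenyi_cd: float
    groups: list[tuple[str, ...]]  # maximal indistinguishable groups
    top_group: tuple[str, ...]  # algorithms within CD of the best mean rank

    def cd_plot_data(self) -> dict:
        """Data needed to draw a critical-difference plot."""
        order = np.argsort(self.mean_ranks)
        return {
            "measure": self.measure,
            "algorithms": [self.algorithms[i] for i in order],
            "mean_ranks": [float(self.mean_ranks[i]) for i in order],
            "cd": self.nemenyi_cd,
            "groups": [list(g) for g in self.groups],
        }


def _grouping(algorithms: list[str], mean_ranks: np.ndarray, cd: float) -> list[tuple[str, ...]]:
    """Maximal sets of algorithms whose mean ranks all lie within CD."""
    order = np.argsort(mean_ranks)
    sorted_ranks = mean_ranks[order]
    groups: list[tuple[str, ...]] = []
    for i in range(len(order)):
        members = [j for j in range(len(order)) if sorted_ranks[j] - sorted_ranks[i] < cd and j >= i]
        group = tuple(algorithms[order[j]] for j in members)
        if not any(set(group) <= set(g) for g in groups):
            groups.append(group)
    return groups


def rank_analysis(results: RunResults, measure: str, alpha: float = 0.05) -> RankAnalysis:
    """Within-run ranks (higher metric = rank 1, ties averaged) plus the
    Friedman test and Nemenyi grouping for one measure."""
    values = results.measure_matrix(measure).to_numpy()
    ranks = np.vstack([rankdata(-row) for row in values])
    mean_ranks = ranks.mean(axis=0)
    statistic, p = friedman_test(ranks)
    cd = nemenyi_cd(len(results.algorithms), results.plan.runs, alpha)
    groups = _grouping(results.algorithms, mean_ranks, cd)
    top = tuple(
        a for a, mr in zip(results.algorithms, mean_ranks) if mr - mean_ranks.min() < cd
    )
    return RankAnalysis(
        measure=measure,
        algorithms=list(results.algorithms),
        rank_matrix=ranks,
        mean_ranks=mean_ranks,
        friedman_statistic=statistic,
        friedman_p=p,
        nemenyi_cd=cd,
        groups=groups,
        top_group=top,
    )


def analyze_all_measures(results: RunResults, alpha: float = 0.05) -> dict[str, RankAnalysis]:
    """Rank analyses for all seven evaluation measures."""
    return {m: rank_analysis(results, m, alpha) for m in MEASURES}


def select_best(analyses: dict[str, RankAnalysis]) -> tuple[str, dict]:
    """The algorithm to train the final classifier with.

    Preferred: a member of the top statistical group of *every* measure;
    among those, the lowest grand mean rank.  If no algorithm is in every
    top group, falls back to the lowest grand mean rank overall (recorded
    in the provenance dict).
    """
    algorithms = next(iter(analyses.values())).algorithms
    grand = np.mean([a.mean_ranks for a in analyses.values()], axis=0)
    in_all = [
        alg
        for alg in algorithms
        if all(alg in a.top_group for a in analyses.values())
    ]
    fallback = not in_all
    candidates = in_all or list(algorithms)
    best = min(candidates, key=lambda alg: (grand[algorithms.index(alg)], algorithms.index(alg)))
    provenance = {
        "grand_mean_ranks": dict(zip(algorithms, map(float, grand))),
        "in_every_top_group": in_all,
        "fallback_used": fallback,
    }
    return best, provenance


@dataclass
class FinalClassifier:
    """Final trained model plus its averaged-F_max decision threshold."""

    model: TrainedModel
    threshold: float
    per_run_thresholds: list[float]


def train_final(
    spec: LearnerSpec,
    table: pd.DataFrame,
    results: RunResults,
    oversample: bool = True,
) -> FinalClassifier:
    """Fit the chosen algorithm on the whole (oversampled) development set.

    The operating threshold is the arithmetic mean of the per-run
    thresholds that maximized the high-risk F-measure in cross-validation.
    """
    thresholds = results.high_risk_thresholds(spec.algorithm)
    train = random_oversample(table, seed=spec.seed) if oversample else table
    model = fit(spec, train)
    return FinalClassifier(
        model=model,
        threshold=float(np.mean(thresholds)),
        per_run_thresholds=[float(t) for t in thresholds],
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank and the oversampling comparison
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped.  For n <= 25 the p-value is exact,
    computed by enumerating the 2^n sign assignments through a polynomial
    convolution over the (tie-averaged, doubled) ranks; larger n uses the
    normal approximation with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InvalidInputError("paired vectors must have equal length")
    d = b - a
    d = d[d != 0]
    if d.size == 0:
        raise UndefinedMetricError("all paired differences are zero")
    if d.size < 5:
        raise InvalidInputError("need >= 5 nonzero differences")
    if d.size <= 25:
        ranks2 = np.rint(2 * rankdata(np.abs(d))).astype(int)  # doubled avg ranks
        w_plus2 = int(ranks2[d > 0].sum())
        dist = np.array([1.0])
        for r in ranks2:
            new = np.zeros(dist.size + r)
            new[: dist.size] += dist
            new[r:] += dist
            dist = new
        dist /= dist.sum()
        lower = dist[: w_plus2 + 1].sum()
        upper = dist[w_plus2:].sum()
        return float(min(1.0, 2.0 * min(lower, upper)))
    stat = wilcoxon(d, correction=True, method="approx")
    return float(stat.pvalue)


def compare_oversampling(
    specs: list[LearnerSpec], table: pd.DataFrame, plan: CVPlan
) -> pd.DataFrame:
    """Paired with/without-oversampling comparison of every algorithm.

    Runs the identical CV (shared fold seeds) twice, toggling only the
    training-fold resampling, pairs the per-run measures, and reports a
    two-sided Wilcoxon signed-rank p plus the mean paired difference
    (oversampled minus raw) for every (algorithm, measure).
    """
    with_os = run_cv(specs, table, CVPlan(plan.folds, plan.runs, plan.stratified, plan.base_seed, True))
    without = run_cv(specs, table, CVPlan(plan.folds, plan.runs, plan.stratified, plan.base_seed, False))
    rows = []
    for spec in specs:
        for measure in MEASURES:
            x = with_os.measure_matrix(measure)[spec.algorithm].to_numpy()
            y = without.measure_matrix(measure)[spec.algorithm].to_numpy()
            try:
                p = wilcoxon_signed_rank(y, x)
            except (UndefinedMetricError, InvalidInputError):
                p = np.nan
            rows.append(
                {
                    "algorithm": spec.algorithm,
                    "measure": measure,
                    "mean_with": float(x.mean()),
                    "mean_without": float(y.mean()),
                    "mean_difference": float((x - y).mean()),
                    "n_runs_improved": int((x > y).sum()),
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)
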