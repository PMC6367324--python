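"""CV framework, Friedman–Nemenyi analysis, final classifier, Wilcoxon."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from radstrat import (
    CohortSpec,
    CVPlan,
    LearnerSpec,
    analyze_all_measures,
    compare_oversampling,
    friedman_test,
    generate_feature_table,
    make_folds,
    nemenyi_cd,
    random_oversample,
    rank_analysis,
    run_cv,
    select_best,
    train_final,
    wilcoxon_signed_rank,
)
from radstrat.errors import (
    DegenerateTrainingError,
    InvalidInputError,
    UndefinedMetricError,
    UnsupportedParameterError,
)
from radstrat.model_selection import RunResults, _grouping


# ------------------------------------------------------------- oversampling

def test_oversample_balances_development_counts():
    t = generate_feature_table(CohortSpec(14, 54, seed=0), n_informative=0)
    out = random_oversample(t, seed=1)
    assert len(out) == 108
    assert out["label"].value_counts().to_dict() == {"high": 54, "lower": 54}


def test_oversample_leaves_balanced_input_unchanged():
    t = generate_feature_table(CohortSpec(10, 10, seed=0), n_informative=0)
    out = random_oversample(t, seed=1)
    assert sorted(out.index) == sorted(t.index)


def test_oversample_copies_only_existing_minority_rows():
    t = generate_feature_table(CohortSpec(4, 12, seed=2), n_informative=0)
    out = random_oversample(t, seed=3)
    minority_ids = set(t.index[t["label"] == "high"])
    extra = out[out["label"] == "high"]
    assert set(extra.index) <= minority_ids
    for pid, row in extra.iterrows():  # exact copies, no synthesis
        assert np.array_equal(row.drop("label").to_numpy(), t.loc[pid].drop("label").to_numpy())


def test_oversample_single_class_rejected():
    t = generate_feature_table(CohortSpec(5, 0, seed=0), n_informative=0)
    with pytest.raises(DegenerateTrainingError):
        random_oversample(t, seed=0)


# -------------------------------------------------------------------- folds

def test_make_folds_exact_divisibility():
    labels = np.array(["lower"] * 40 + ["high"] * 10, dtype=object)
    assignment = make_folds(labels, 5, seed=0)
    for k in range(5):
        fold = labels[assignment == k]
        assert (fold == "lower").sum() == 8 and (fold == "high").sum() == 2


def test_make_folds_balanced_remainders_on_imbalanced_counts():
    labels = np.array(["lower"] * 54 + ["high"] * 14, dtype=object)
    assignment = make_folds(labels, 5, seed=3)
    high_counts = [int((labels[assignment == k] == "high").sum()) for k in range(5)]
    assert set(high_counts) <= {2, 3} and sum(high_counts) == 14


def test_make_folds_partition_and_minority_guard():
    labels = np.array(["lower"] * 20 + ["high"] * 4, dtype=object)
    assignment = make_folds(labels, 4, seed=1)
    assert sorted(np.unique(assignment)) == [0, 1, 2, 3]
    assert len(assignment) == 24
    with pytest.raises(InvalidInputError):
        make_folds(labels, 5, seed=1)


# ------------------------------------------------------------------- run_cv

@pytest.fixture(scope="module")
def small_cv():
    table = generate_feature_table(CohortSpec(8, 24, seed=5, effect_size=1.0), n_informative=15)
    specs = [LearnerSpec("LogReg"), LearnerSpec("QSVM")]
    plan = CVPlan(folds=4, runs=3, base_seed=9)
    return table, specs, plan, run_cv(specs, table, plan)


def test_out_of_fold_predictions_cover_each_sample_once(small_cv):
    table, specs, plan, results = small_cv
    assert not results.failures
    for alg in ("LogReg", "QSVM"):
        for r in range(plan.runs):
            preds = results.predictions[(alg, r)]
            assert sorted(preds.sample_ids) == sorted(table.index)
            assert np.all(np.isfinite(preds.scores))


def test_no_leakage_of_held_out_ids_into_training():
    """Oversampling happens after the split: copies of held-out patients
    never reach the training folds."""
    table = generate_feature_table(CohortSpec(6, 18, seed=1), n_informative=0)
    labels = table["label"].to_numpy(dtype=object)
    assignment = make_folds(labels, 3, seed=0)
    for k in range(3):
        train = random_oversample(table.iloc[assignment != k], seed=k)
        held = set(table.index[assignment == k])
        assert not (set(train.index) & held)


def test_measure_matrix_shape(small_cv):
    _, _, plan, results = small_cv
    m = results.measure_matrix("auc")
    assert m.shape == (plan.runs, 2)
    assert np.all((m.to_numpy() >= 0) & (m.to_numpy() <= 1))


# ----------------------------------------------------------------- Friedman

def test_friedman_identical_columns_statistic_zero():
    ranks = np.full((10, 7), 4.0)  # all algorithms tied in every run
    statistic, p = friedman_test(ranks)
    assert statistic == 0.0 and p == 1.0


def test_friedman_dominant_algorithm_is_significant():
    # one algorithm ranked 1 in all 10 runs of 7; others shuffled
    rng = np.random.default_rng(0)
    ranks = np.array([[1] + list(rng.permutation(np.arange(2, 8))) for _ in range(10)], float)
    statistic, p = friedman_test(ranks)
    assert p < 0.05


def test_friedman_matches_scipy_on_untied_data():
    rng = np.random.default_rng(8)
    for _ in range(20):
        values = rng.normal(size=(12, 5))
        ranks = np.vstack([stats.rankdata(-row) for row in values])
        statistic, p = friedman_test(ranks)
        ref = stats.friedmanchisquare(*values.T)
        assert statistic == pytest.approx(ref.statistic, abs=1e-9)
        assert p == pytest.approx(ref.pvalue, abs=1e-9)


def test_friedman_k2_approximates_sign_test():
    """With two methods the Friedman test is the chi-square approximation
    of the two-sided sign test on paired wins; agreement is checked
    against the (continuity-free) mid-p sign test."""
    rng = np.random.default_rng(4)
    diffs = []
    for _ in range(100):
        n = 100
        values = rng.normal(size=(n, 2))
        ranks = np.vstack([stats.rankdata(-row) for row in values])
        _, p_f = friedman_test(ranks)
        wins = int((values[:, 0] > values[:, 1]).sum())
        upper = 2 * (stats.binom.sf(wins, n, 0.5) + 0.5 * stats.binom.pmf(wins, n, 0.5))
        lower = 2 * (stats.binom.cdf(wins, n, 0.5) - 0.5 * stats.binom.pmf(wins, n, 0.5))
        p_sign = min(1.0, upper, lower)
        diffs.append(abs(p_f - p_sign))
    assert np.mean(diffs) < 0.02
    assert max(diffs) < 0.05


def test_friedman_rejects_degenerate_shapes():
    with pytest.raises(InvalidInputError):
        friedman_test(np.ones((1, 3)))


# ------------------------------------------------------------------ Nemenyi

def test_nemenyi_cd_seven_algorithms_ten_runs():
    assert nemenyi_cd(7, 10, 0.05) == pytest.approx(2.849, abs=0.001)


def test_nemenyi_cd_two_algorithms_closed_form():
    for n in (5, 10, 20):
        assert nemenyi_cd(2, n, 0.05) == pytest.approx(1.960 / np.sqrt(n), abs=1e-3)


def test_nemenyi_cd_decreasing_in_n():
    cds = [nemenyi_cd(7, n) for n in (5, 10, 20, 50)]
    assert all(a > b for a, b in zip(cds, cds[1:]))


def test_nemenyi_q_matches_studentized_range_distribution():
    """The frozen q table equals the infinite-df studentized range critical
    value divided by sqrt(2) (independent recomputation via scipy)."""
    from radstrat.model_selection import nemenyi_q

    for k in (2, 5, 7, 10):
        ref = stats.studentized_range.ppf(0.95, k, np.inf) / np.sqrt(2)
        assert nemenyi_q(k, 0.05) == pytest.approx(ref, abs=2e-3)


def test_nemenyi_unsupported_parameters():
    with pytest.raises(UnsupportedParameterError):
        nemenyi_cd(25, 10)
    with pytest.raises(UnsupportedParameterError):
        nemenyi_cd(7, 10, alpha=0.01)


# -------------------------------------------------------------- rank analysis

def test_rank_rows_sum_to_k_choose_property(small_cv):
    _, _, _, results = small_cv
    analysis = rank_analysis(results, "auc")
    k = len(results.algorithms)
    assert np.allclose(analysis.rank_matrix.sum(axis=1), k * (k + 1) / 2)


def test_grouping_matches_pairwise_cd_oracle():
    rng = np.random.default_rng(2)
    algs = list("ABCDEFG")
    for _ in range(50):
        mean_ranks = np.sort(rng.uniform(1, 7, 7))
        rng.shuffle(mean_ranks)
        cd = rng.uniform(0.3, 3.0)
        groups = _grouping(algs, mean_ranks, cd)
        # oracle: every within-group pair differs by < cd, and each group
        # is maximal (cannot be extended by any other algorithm)
        for g in groups:
            idx = [algs.index(a) for a in g]
            for i in idx:
                for j in idx:
                    assert abs(mean_ranks[i] - mean_ranks[j]) < cd
            for other in set(range(7)) - set(idx):
                extended = idx + [other]
                span = mean_ranks[extended].max() - mean_ranks[extended].min()
                assert span >= cd or any(set(g) | {algs[other]} <= set(h) for h in groups)
        # every algorithm appears in at least one group
        assert set(algs) == {a for g in groups for a in g}


def test_select_best_prefers_dominant_algorithm(small_cv):
    table, specs, plan, results = small_cv
    analyses = analyze_all_measures(results)
    best, provenance = select_best(analyses)
    assert best in ("LogReg", "QSVM")
    best2, _ = select_best(analyses)
    assert best2 == best  # deterministic given results


def test_dominant_algorithm_alone_in_top_group():
    # synthetic results: algorithm A strictly best in every run/measure
    plan = CVPlan(folds=2, runs=10, base_seed=0)
    results = RunResults(algorithms=["A", "B", "C"], plan=plan)
    rng = np.random.default_rng(0)
    from radstrat.metrics import PredictionSet, evaluate

    labels = np.array(["high"] * 10 + ["lower"] * 10, dtype=object)
    for r in range(plan.runs):
        sep = {"A": 1.0, "B": 0.35 + 0.01 * rng.random(), "C": 0.3 + 0.01 * rng.random()}
        for alg, s in sep.items():
            scores = np.where(labels == "high", 0.5 + s / 2, 0.5 - s / 2)
            scores = np.clip(scores + rng.normal(0, 0.02, 20), 0, 1)
            results.predictions[(alg, r)] = PredictionSet(scores, labels)
            results.evaluations[(alg, r)] = evaluate(results.predictions[(alg, r)])
    analysis = rank_analysis(results, "auc")
    if analysis.nemenyi_cd < 1:
        assert analysis.top_group == ("A",)


# ------------------------------------------------------------- final training

def test_train_final_threshold_is_mean_of_run_thresholds(small_cv):
    table, specs, plan, results = small_cv
    final = train_final(LearnerSpec("QSVM", seed=plan.base_seed), table, results)
    ts = results.high_risk_thresholds("QSVM")
    assert final.threshold == pytest.approx(np.mean(ts), abs=1e-12)
    assert min(ts) <= final.threshold <= max(ts)
    assert final.per_run_thresholds == [pytest.approx(t) for t in ts]


# ------------------------------------------------------------------ Wilcoxon

def test_wilcoxon_exact_uniform_positive_shift():
    a = np.arange(10, dtype=float)
    assert wilcoxon_signed_rank(a, a + 1) == pytest.approx(2 / 1024)


def test_wilcoxon_all_zero_differences_undefined():
    a = np.arange(8, dtype=float)
    with pytest.raises(UndefinedMetricError):
        wilcoxon_signed_rank(a, a)


def test_wilcoxon_antisymmetry():
    rng = np.random.default_rng(1)
    a = rng.normal(size=12)
    b = a + rng.normal(0.4, 1.0, size=12)
    assert wilcoxon_signed_rank(a, b) == pytest.approx(wilcoxon_signed_rank(b, a))


def test_wilcoxon_exact_matches_scipy_on_tie_free_data():
    rng = np.random.default_rng(6)
    for _ in range(20):
        d = rng.normal(0.3, 1.0, size=15)
        a = rng.normal(size=15)
        p = wilcoxon_signed_rank(a, a + d)
        ref = stats.wilcoxon(a, a + d, method="exact").pvalue
        assert p == pytest.approx(ref, abs=1e-12)


# -------------------------------------------------------- oversampling impact

def test_compare_oversampling_report_shape_and_pairing():
    table = generate_feature_table(CohortSpec(6, 24, seed=3, effect_size=1.0), n_informative=10)
    specs = [LearnerSpec("LogReg")]
    plan = CVPlan(folds=3, runs=6, base_seed=2)
    report = compare_oversampling(specs, table, plan)
    assert len(report) == 7  # one row per (algorithm, measure)
    assert set(report["measure"]) == {
        "auc", "high_fmax", "high_pmax", "high_rmax",
        "lower_fmax", "lower_pmax", "lower_rmax",
    }
    assert (report["algorithm"] == "LogReg").all()
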