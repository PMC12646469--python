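"""Evaluation harness: folds, SMOTE geometry, metric arithmetic,
probability metrics, the paired fold test, and the comparison report."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hivefit.evaluation import (
    ConfusionCounts,
    CVConfig,
    ResamplingError,
    StratificationError,
    comparison_table,
    cross_validate,
    cross_validate_leaky_smote,
    format_percent,
    holdout_split,
    metrics_from_counts,
    paired_fold_test,
    probability_metrics,
    smote_oversample,
    stratified_folds,
)
from hivefit.models import ModelSpec, model_grid


# ----------------------------------------------------------------------
# folds
# ----------------------------------------------------------------------

def test_stratified_folds_on_study_dimensions():
    """n = 162 with 63 positives, k = 5: fold sizes {33,33,32,32,32} and
    per-fold positives {13,13,13,12,12}."""
    y = np.array([1] * 63 + [0] * 99)
    folds = stratified_folds(y, 5, seed=0)
    sizes = sorted(len(f) for f in folds)
    positives = sorted(int(y[f].sum()) for f in folds)
    assert sizes == [32, 32, 32, 33, 33]
    assert positives == [12, 12, 13, 13, 13]


def test_folds_partition_indices():
    y = np.array([0, 1] * 20)
    folds = stratified_folds(y, 4, seed=1)
    allidx = np.concatenate(folds)
    assert len(allidx) == 40
    assert len(np.unique(allidx)) == 40


def test_leave_one_out_boundary():
    y = np.array([0, 1] * 5)
    folds = stratified_folds(y, 10, seed=0)
    assert all(len(f) == 1 for f in folds)


def test_class_smaller_than_k_raises():
    y = np.array([1, 1, 0, 0, 0, 0, 0, 0])
    with pytest.raises(StratificationError):
        stratified_folds(y, 3, seed=0)


def test_folds_deterministic():
    y = np.array([0, 1] * 30)
    a = stratified_folds(y, 5, seed=7)
    b = stratified_folds(y, 5, seed=7)
    assert all(np.array_equal(x, z) for x, z in zip(a, b))


def test_holdout_split_fractions():
    y = np.array([1] * 63 + [0] * 99)
    tr, te = holdout_split(y, seed=0)
    assert len(te) == 33 and len(tr) == 129
    assert len(np.intersect1d(tr, te)) == 0


# ----------------------------------------------------------------------
# SMOTE
# ----------------------------------------------------------------------

def test_smote_balanced_input_unchanged():
    rng = np.random.default_rng(0)
    X = rng.random((10, 3))
    y = np.array([0] * 5 + [1] * 5)
    X2, y2 = smote_oversample(X, y, seed=0)
    assert np.array_equal(X, X2) and np.array_equal(y, y2)


def test_smote_synthetic_rows_lie_between_minority_rows():
    rng = np.random.default_rng(1)
    X_min = rng.random((5, 4))
    X_maj = rng.random((10, 4)) + 5.0
    X = np.vstack([X_min, X_maj])
    y = np.array([1] * 5 + [0] * 10)
    X2, y2 = smote_oversample(X, y, k_neighbors=3, seed=2)
    assert (y2 == 1).sum() == (y2 == 0).sum() == 10
    assert np.array_equal(X2[:15], X)
    synth = X2[15:]
    lo, hi = X_min.min(axis=0), X_min.max(axis=0)
    # componentwise betweenness: each synthetic row within the minority hull box
    assert np.all(synth >= lo - 1e-12) and np.all(synth <= hi + 1e-12)
    # and exactly on a segment between two minority rows
    for s in synth:
        on_segment = False
        for i in range(5):
            for j in range(5):
                if i == j:
                    continue
                d = X_min[j] - X_min[i]
                t = (s - X_min[i]) @ d / (d @ d)
                if 0 <= t <= 1 and np.allclose(X_min[i] + t * d, s, atol=1e-9):
                    on_segment = True
        assert on_segment


def test_smote_1d_convexity_bound():
    X = np.array([[0.0], [1.0], [5.0], [6.0], [7.0]])
    y = np.array([1, 1, 0, 0, 0])
    X2, y2 = smote_oversample(X, y, k_neighbors=1, seed=0)
    synth = X2[5:]
    assert np.all((synth >= 0) & (synth <= 1))


def test_smote_single_member_minority_raises():
    X = np.random.default_rng(0).random((6, 2))
    y = np.array([1, 0, 0, 0, 0, 0])
    with pytest.raises(ResamplingError):
        smote_oversample(X, y)


def test_smote_neighbor_autoshrink_warns():
    rng = np.random.default_rng(3)
    X = rng.random((13, 2))
    y = np.array([1] * 3 + [0] * 10)
    with pytest.warns(UserWarning, match="minority"):
        X2, y2 = smote_oversample(X, y, k_neighbors=5, seed=0)
    assert (y2 == 1).sum() == 10


# ----------------------------------------------------------------------
# confusion-count metrics
# ----------------------------------------------------------------------

def test_metrics_on_published_confusion_counts():
    """TP=60, TN=88, FP=11, FN=3 reproduces the printed overall accuracy."""
    vals = metrics_from_counts(ConfusionCounts(tp=60, tn=88, fp=11, fn=3))
    assert vals.accuracy == pytest.approx(148 / 162)
    assert round(100 * vals.accuracy, 2) == 91.36
    assert vals.sensitivity == pytest.approx(60 / 63)
    assert vals.precision == pytest.approx(60 / 71)


def test_metrics_symmetric_counts():
    vals = metrics_from_counts(ConfusionCounts(1, 1, 1, 1))
    assert (
        vals.accuracy == vals.sensitivity == vals.precision == vals.f1 == 0.5
    )


def test_metrics_undefined_precision_has_reason():
    vals = metrics_from_counts(ConfusionCounts(tp=0, tn=10, fp=0, fn=0))
    assert vals.accuracy == 1.0
    assert np.isnan(vals.precision)
    assert "no positive predictions" in vals.reasons["precision"]


def test_metrics_zero_total_raises():
    with pytest.raises(ValueError):
        metrics_from_counts(ConfusionCounts(0, 0, 0, 0))


@settings(max_examples=200, deadline=None)
@given(
    counts=st.tuples(*[st.integers(min_value=0, max_value=500)] * 4)
)
def test_metrics_agree_with_direct_count_oracle(counts):
    """Independent oracle: rebuild label vectors from the counts and measure
    rates by direct counting."""
    tp, tn, fp, fn = counts
    if tp + tn + fp + fn == 0:
        return
    y_true = np.array([1] * tp + [0] * tn + [0] * fp + [1] * fn)
    y_pred = np.array([1] * tp + [0] * tn + [1] * fp + [0] * fn)
    vals = metrics_from_counts(ConfusionCounts(tp, tn, fp, fn))
    assert vals.accuracy == pytest.approx(np.mean(y_true == y_pred))
    if tp + fn:
        assert vals.sensitivity == pytest.approx(
            np.mean(y_pred[y_true == 1] == 1)
        )
    if tp + fp:
        assert vals.precision == pytest.approx(np.mean(y_true[y_pred == 1] == 1))


# ----------------------------------------------------------------------
# probability metrics
# ----------------------------------------------------------------------

def test_perfect_predictions():
    y = np.array([0, 1, 1, 0, 1])
    pm = probability_metrics(y.astype(float), y)
    assert pm.brier == 0.0
    assert pm.roc_auc == 1.0


def test_uninformative_half_probabilities():
    y = np.array([0, 1] * 10)
    pm = probability_metrics(np.full(20, 0.5), y)
    assert pm.brier == pytest.approx(0.25)


def test_roc_auc_matches_pair_counting_oracle():
    probs = np.array([0.9, 0.8, 0.3, 0.1])
    y = np.array([1, 0, 1, 0])
    pm = probability_metrics(probs, y)
    # oracle: concordant pairs / total positive-negative pairs
    pos, neg = probs[y == 1], probs[y == 0]
    pairs = [(p, q) for p in pos for q in neg]
    auc = np.mean([1.0 if p > q else 0.5 if p == q else 0.0 for p, q in pairs])
    assert pm.roc_auc == pytest.approx(auc) == pytest.approx(0.75)


def test_roc_auc_pair_counting_oracle_random_vectors():
    rng = np.random.default_rng(4)
    for _ in range(20):
        n = int(rng.integers(6, 30))
        probs = rng.random(n).round(2)
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            continue
        pm = probability_metrics(probs, y)
        pos, neg = probs[y == 1], probs[y == 0]
        auc = np.mean(
            [1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg]
        )
        assert pm.roc_auc == pytest.approx(auc)


def test_single_class_aucs_undefined_with_reason():
    pm = probability_metrics(np.array([0.2, 0.4]), np.array([1, 1]))
    assert np.isnan(pm.roc_auc)
    assert pm.reasons["roc_auc"] == "single-class outcome"


def test_calibration_bins_partition_n():
    rng = np.random.default_rng(0)
    probs = rng.random(500)
    y = rng.integers(0, 2, 500)
    pm = probability_metrics(probs, y)
    assert pm.calibration.counts.sum() == 500
    obs = pm.calibration.observed_frequency
    assert np.nanmin(obs) >= 0 and np.nanmax(obs) <= 1


# ----------------------------------------------------------------------
# paired fold test
# ----------------------------------------------------------------------

def test_paired_t_closed_form():
    res = paired_fold_test([1, 2, 3, 4, 5], [0, 0, 0, 0, 0])
    # differences (1..5): mean 3, sd sqrt(2.5), t = 3*sqrt(5)/sqrt(2.5)
    assert res.t_statistic == pytest.approx(3 * np.sqrt(5) / np.sqrt(2.5))
    assert res.mean_difference == 3.0
    from scipy import stats

    assert res.p_value == pytest.approx(
        2 * stats.t.sf(res.t_statistic, df=4)
    )


def test_paired_t_exact_tie_report():
    res = paired_fold_test([0.8, 0.7, 0.9], [0.8, 0.7, 0.9])
    assert res.exact_tie
    assert res.mean_difference == 0.0
    assert np.isnan(res.t_statistic)


def test_paired_t_ci_symmetric_about_mean():
    rng = np.random.default_rng(6)
    a, b = rng.random(8), rng.random(8)
    res = paired_fold_test(a, b)
    assert (res.ci_low + res.ci_high) / 2 == pytest.approx(res.mean_difference)


def test_paired_t_type_one_error_near_nominal():
    """Under an exchangeable null the rejection rate at alpha = 0.05 stays
    within [0.03, 0.07] over 2000 simulations."""
    rng = np.random.default_rng(11)
    rejections = 0
    reps = 2000
    for _ in range(reps):
        a = rng.normal(size=5)
        b = rng.normal(size=5)
        res = paired_fold_test(a, b)
        if res.p_value < 0.05:
            rejections += 1
    assert 0.03 <= rejections / reps <= 0.07


# ----------------------------------------------------------------------
# cross-validation protocol
# ----------------------------------------------------------------------

def test_cross_validate_deterministic_and_pools_to_n(null_cohort):
    spec = ModelSpec(stage="simple", base_learner="cart", seed=2)
    cv = CVConfig(seed=3)
    a = cross_validate(spec, null_cohort, cv)
    b = cross_validate(spec, null_cohort, cv)
    assert a.pooled_counts.total == null_cohort.n
    assert a.as_dict() == b.as_dict()
    assert np.array_equal(a.fold_scores["f1"], b.fold_scores["f1"])


def test_fold_metrics_consistent_with_their_counts(null_cohort):
    spec = ModelSpec(stage="simple", base_learner="knn", seed=0)
    rep = cross_validate(spec, null_cohort, CVConfig(seed=1))
    for counts, acc in zip(rep.fold_counts, rep.fold_scores["accuracy"]):
        assert acc == pytest.approx(metrics_from_counts(counts).accuracy)
    assert sum(c.total for c in rep.fold_counts) == null_cohort.n


def test_label_permutation_leakage_canary(null_cohort):
    """On label-permuted data with SMOTE inside folds, mean CV accuracy sits
    within 3 binomial SEs of chance; oversampling before the split shows a
    positive optimism bias on the same data."""
    import pandas as pd

    from hivefit.cohort import CohortTable, OUTCOME_NAME

    rng = np.random.default_rng(13)
    frame = null_cohort.frame.copy()
    frame[OUTCOME_NAME] = rng.permutation(frame[OUTCOME_NAME].to_numpy())
    permuted = CohortTable(frame)

    spec = ModelSpec(stage="simple", base_learner="knn", seed=0)
    cv = CVConfig(seed=0)
    fair = cross_validate(spec, permuted, cv)
    acc = fair.pooled_metrics.accuracy
    se = np.sqrt(0.25 / permuted.n)
    assert abs(acc - 0.5) < 3 * se

    leaky = cross_validate_leaky_smote(spec, permuted, cv)
    assert leaky - acc > 0


def test_comparison_table_single_spec():
    from hivefit.synthetic import default_config, generate_cohort

    cohort = generate_cohort(default_config(n=120, seed=19))
    table = comparison_table(
        cohort, [ModelSpec(stage="simple", base_learner="rf", seed=0)], CVConfig(seed=0)
    )
    assert len(table) == 1
    assert table.loc[0, "Model"] == "RF"
    assert table.loc[0, "Model Type"] == "Simple"
    assert table.loc[0, "Best"]


def test_percent_formatting_two_decimals():
    assert format_percent(0.913580) == "91.36"
    assert format_percent(float("nan")) == "NA"


def test_comparison_table_isolates_failures(null_cohort):
    """A failing grid cell is marked failed and the run continues."""
    bad = ModelSpec(stage="simple", base_learner="rf", seed=0, base_params={"n_estimators": -5})
    good = ModelSpec(stage="simple", base_learner="cart", seed=0)
    table = comparison_table(null_cohort, [bad, good], CVConfig(seed=0))
    assert table["Status"].str.startswith("failed").sum() == 1
    assert (table["Status"] == "ok").sum() == 1
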