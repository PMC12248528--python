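"""MCC, repeated stratified CV, SVM selection, Wilcoxon, benchmark grid."""

import hashlib

import numpy as np
import pytest

from radsignet import (BenchmarkPlan, ConfusionCounts, CVResult, compare_wilcoxon,
                       make_pipeline, mcc, mcc_score, repeated_stratified_cv,
                       run_benchmark, summarize, svm_select)
from radsignet.experiments import naive_mcc, naive_signed_rank_p


def test_mcc_reference_values():
    assert mcc(ConfusionCounts(5, 0, 0, 5)) == 1.0
    assert mcc(ConfusionCounts(5, 5, 0, 0)) == 0.0  # zero-denominator convention
    assert mcc(ConfusionCounts(3, 1, 2, 4)) == pytest.approx(10 / np.sqrt(600))


def test_mcc_matches_correlation_definition_small_tables():
    """Exhaustive check against the Pearson-correlation definition on every
    confusion table with a modest total."""
    for tp in range(0, 13):
        for fp in range(0, 13 - tp):
            for fn in range(0, 13 - tp - fp):
                for tn in range(0, 13 - tp - fp - fn):
                    if tp + fp + fn + tn == 0:
                        continue
                    assert mcc(ConfusionCounts(tp, fp, fn, tn)) == \
                        pytest.approx(naive_mcc(tp, fp, fn, tn), abs=1e-12)


def _signal_data(rng, n=100, p=8, d=3.0):
    X = rng.normal(size=(n, p))
    y = np.tile([0, 1], n // 2)
    X[:, 0] += d * y
    return X, y


def test_repeated_cv_separable_data_is_perfect(rng):
    X, y = _signal_data(rng, d=6.0)
    res = repeated_stratified_cv(make_pipeline(), X, y, n_folds=5, n_repeats=3,
                                 seed=0)
    assert np.median(res.scores) == 1.0


def test_repeated_cv_label_permutation_is_null(rng):
    X, y = _signal_data(rng, d=0.0)
    res = repeated_stratified_cv(make_pipeline(), X, y, n_folds=10, n_repeats=10,
                                 seed=1)
    assert abs(np.median(res.scores)) <= 0.1
    assert len(res.scores) == 100


def test_repeated_cv_deterministic(rng):
    X, y = _signal_data(rng)
    a = repeated_stratified_cv(make_pipeline(), X, y, 5, 2, seed=7)
    b = repeated_stratified_cv(make_pipeline(), X, y, 5, 2, seed=7)
    np.testing.assert_array_equal(a.scores, b.scores)


def test_repeated_cv_rejects_too_many_folds(rng):
    X, y = _signal_data(rng, n=16)
    with pytest.raises(ValueError, match="folds"):
        repeated_stratified_cv(make_pipeline(), X, y, n_folds=10, n_repeats=1)


def test_fitted_parameters_ignore_test_fold_labels(rng):
    """Leakage guard: refitting on the same training fold after shuffling the
    held-out labels leaves every fitted parameter bit-identical."""
    X, y = _signal_data(rng)
    train, test = np.arange(0, 80), np.arange(80, 100)

    def fit_hash(y_full):
        model = make_pipeline()
        model.fit(X[train], y_full[train])
        blobs = [model.named_steps["scale"].mean_.tobytes(),
                 model.named_steps["select"].support_mask_.tobytes(),
                 model.named_steps["clf"].coef_.tobytes(),
                 model.named_steps["clf"].intercept_.tobytes()]
        return hashlib.sha256(b"".join(blobs)).hexdigest()

    y_shuffled = y.copy()
    y_shuffled[test] = np.random.default_rng(0).permutation(y[test])
    assert fit_hash(y) == fit_hash(y_shuffled)


def test_cv_scores_invariant_to_row_order_within_folds(rng):
    """Permuting patients while permuting the fold assignment the same way
    leaves the per-fold MCCs unchanged."""
    from sklearn.base import clone
    from sklearn.model_selection import StratifiedKFold

    X, y = _signal_data(rng, n=60, d=1.0)
    folds = list(StratifiedKFold(3, shuffle=True, random_state=0).split(X, y))
    perm = np.random.default_rng(1).permutation(60)
    inv = np.argsort(perm)
    Xp, yp = X[perm], y[perm]

    for train, test in folds:
        m1 = clone(make_pipeline()).fit(X[train], y[train])
        s1 = mcc_score(y[test], m1.predict(X[test]))
        train_p, test_p = inv[train], inv[test]  # same patients, new positions
        m2 = clone(make_pipeline()).fit(Xp[train_p], yp[train_p])
        s2 = mcc_score(yp[test_p], m2.predict(Xp[test_p]))
        assert s1 == pytest.approx(s2, abs=1e-12)


# ---------------------------------------------------------------------------
# SVM-coefficient selection


def test_svm_selection_retains_informative_feature():
    hits = 0
    for s in range(100):
        rng = np.random.default_rng(700 + s)
        X = rng.normal(size=(120, 21))
        y = np.tile([0, 1], 60)
        X[:, 7] += 3.0 * y
        X = (X - X.mean(0)) / X.std(0)
        hits += 7 in svm_select(X, y)
    assert hits >= 95


def test_svm_selection_never_empty(rng):
    X = rng.normal(size=(60, 10))
    y = np.tile([0, 1], 30)
    assert len(svm_select(X, y)) >= 1


def test_svm_selection_top_k_exact(rng):
    X = rng.normal(size=(80, 50))
    y = np.tile([0, 1], 40)
    assert len(svm_select(X, y, top_k=5)) == 5


# ---------------------------------------------------------------------------
# summaries and comparisons


def test_summarize_median_and_iqr():
    cell = summarize(CVResult([0.5, 0.6, 0.7], 1, 3, "m", 0))
    assert cell.median_mcc == pytest.approx(0.6)
    assert cell.iqr == pytest.approx(0.1)
    assert summarize(CVResult([0.4] * 5, 1, 5, "m", 0)).iqr == 0.0
    single = summarize(CVResult([0.3], 1, 1, "m", 0))
    assert (single.median_mcc, single.iqr) == (0.3, 0.0)


def test_wilcoxon_identical_results_give_p_one():
    a = CVResult(np.full(20, 0.5), 2, 10, "a", 0)
    b = CVResult(np.full(20, 0.5), 2, 10, "b", 0)
    assert compare_wilcoxon(a, b) == 1.0


def test_wilcoxon_strong_shift_detected(rng):
    base = rng.normal(0.5, 0.05, 50)
    a = CVResult(base, 5, 10, "a", 0)
    b = CVResult(base + 0.2, 5, 10, "b", 0)
    assert compare_wilcoxon(a, b, alternative="less") < 1e-3


def test_wilcoxon_matches_exact_enumeration(rng):
    from scipy import stats

    for trial in range(5):
        diff = rng.normal(0.05, 0.1, 10)
        p_scipy = stats.wilcoxon(diff, alternative="greater",
                                 method="exact").pvalue
        assert p_scipy == pytest.approx(naive_signed_rank_p(diff, "greater"),
                                        abs=1e-12)
    # and through the paired CVResult interface
    base = rng.normal(0.5, 0.05, 10)
    a = CVResult(base + np.abs(rng.normal(0, 0.05, 10)), 1, 10, "a", 0)
    b = CVResult(base, 1, 10, "b", 0)
    p = compare_wilcoxon(a, b, alternative="greater")
    assert p == pytest.approx(naive_signed_rank_p(a.scores - b.scores, "greater"),
                              abs=1e-9)


def test_unpaired_fallback_uses_rank_sum(rng):
    a = CVResult(rng.normal(0.6, 0.05, 30), 3, 10, "a", 0)
    b = CVResult(rng.normal(0.4, 0.05, 20), 2, 10, "b", 1)
    p = compare_wilcoxon(a, b, alternative="greater")
    assert p < 1e-3


# ---------------------------------------------------------------------------
# benchmark grid


def test_single_cell_plan(small_cohort):
    plan = BenchmarkPlan(sources=("radiomic",), modalities=(("CE_T1w",),),
                         categories=("LoG",), methods=("svm",),
                         n_folds=5, n_repeats=2)
    out = run_benchmark(small_cohort, plan, seed=0)
    assert len(out) == 1
    assert out.error.isna().all()
    assert -1 <= out.median_mcc.iloc[0] <= 1


def test_failed_cell_recorded_not_raised(small_cohort):
    plan = BenchmarkPlan(sources=("radiomic",), modalities=(("CE_T1w",),),
                         categories=("LoG",), methods=("nonsense",),
                         n_folds=5, n_repeats=1)
    out = run_benchmark(small_cohort, plan, seed=0)
    assert np.isnan(out.median_mcc.iloc[0])
    assert "nonsense" in out.error.iloc[0]
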