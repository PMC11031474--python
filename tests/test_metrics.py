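"""Evaluation metrics, bootstrap CIs, patient aggregation and paired tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn import metrics as skm

from sectorvit.metrics import (ConfusionMatrix, aggregate_patient, auc_roc,
                               bootstrap_ci, confusion, confusion_from_rates,
                               delong_test, evaluate_predictions, log_loss,
                               mcnemar_test, metrics_from_confusion)


# -- confusion reconstruction (printed-table arithmetic) -----------------------

def test_patient_level_confusion_reconstruction():
    # 30 test patients: 10 unmethylated (positive), 20 methylated;
    # sensitivity 0.600 and specificity 0.950 force integer cells
    cm = confusion_from_rates(n_pos=10, n_neg=20, sensitivity=0.600,
                              specificity=0.950)
    assert (cm.tp, cm.fn, cm.tn, cm.fp) == (6, 4, 19, 1)
    m = metrics_from_confusion(cm)
    assert round(m["accuracy"], 3) == 0.833
    assert round(m["ppv"], 3) == 0.857
    assert round(m["npv"], 3) == 0.826
    assert round(m["f_score"], 3) == 0.706
    assert round(m["kappa"], 3) == 0.595


def test_image_level_confusion_reconstruction():
    # 242 unmethylated / 242 methylated images, sens 0.612, spec 0.917
    cm = confusion_from_rates(n_pos=242, n_neg=242, sensitivity=0.612,
                              specificity=0.917)
    assert (cm.tp, cm.fn, cm.tn, cm.fp) == (148, 94, 222, 20)
    m = metrics_from_confusion(cm)
    assert round(m["accuracy"], 3) == 0.764
    assert round(m["ppv"], 3) == 0.881
    assert round(m["npv"], 3) == 0.703
    assert round(m["f_score"], 3) == 0.722
    assert round(m["kappa"], 3) == 0.529


def test_confusion_counts_and_positive_class_swap(rng):
    preds = rng.integers(0, 2, size=40)
    labels = rng.integers(0, 2, size=40)
    cm0 = confusion(preds, labels, positive_class=0)
    cm1 = confusion(preds, labels, positive_class=1)
    assert (cm0.tp, cm0.tn, cm0.fp, cm0.fn) == (cm1.tn, cm1.tp, cm1.fn, cm1.fp)
    same = confusion(labels, labels, positive_class=0)
    assert same.tp + same.tn == 40 and same.fp == same.fn == 0
    with pytest.raises(ValueError):
        confusion([1, 0], [1])


def test_metrics_match_sklearn_on_random_small_matrices(rng):
    """Brute-force oracle: expand random matrices (total <= 30) into
    prediction lists and compare against scikit-learn's implementations."""
    for _ in range(30):
        tp, fp, fn, tn = rng.integers(0, 8, size=4)
        if tp + fp + fn + tn == 0:
            continue
        preds = np.array([1] * tp + [1] * fp + [0] * fn + [0] * tn)
        labels = np.array([1] * tp + [0] * fp + [1] * fn + [0] * tn)
        m = metrics_from_confusion(ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn))
        assert m["accuracy"] == pytest.approx(skm.accuracy_score(labels, preds))
        if tp + fn:
            assert m["sensitivity"] == pytest.approx(
                skm.recall_score(labels, preds, zero_division=np.nan))
        if tp + fp:
            assert m["ppv"] == pytest.approx(
                skm.precision_score(labels, preds, zero_division=np.nan))
        if m["f_score"] is not None:
            assert m["f_score"] == pytest.approx(skm.f1_score(labels, preds))
        if m["kappa"] is not None and len(np.unique(labels)) == 2:
            assert m["kappa"] == pytest.approx(skm.cohen_kappa_score(labels, preds))


def test_kappa_equals_2acc_minus_1_under_balanced_marginals():
    m = metrics_from_confusion(ConfusionMatrix(tp=7, fp=3, fn=3, tn=7))
    assert m["kappa"] == pytest.approx(2 * m["accuracy"] - 1)


def test_undefined_ratios_reported_as_missing():
    m = metrics_from_confusion(ConfusionMatrix(tp=0, fp=0, fn=0, tn=5))
    assert m["sensitivity"] is None and m["ppv"] is None
    assert m["specificity"] == 1.0


# -- AUC -----------------------------------------------------------------------

def _pair_count_auc(scores, labels, positive=1):
    """Independent oracle: count concordant positive-negative pairs."""
    pos = [s for s, y in zip(scores, labels) if y == positive]
    neg = [s for s, y in zip(scores, labels) if y != positive]
    total = wins = 0
    for p in pos:
        for q in neg:
            total += 1
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / total


def test_auc_worked_example():
    assert auc_roc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1],
                   positive_class=1) == pytest.approx(0.75)


def test_auc_perfect_and_all_ties():
    assert auc_roc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], positive_class=1) == 1.0
    assert auc_roc([0.5] * 6, [1, 0, 1, 0, 1, 0], positive_class=1) == 0.5
    with pytest.raises(ValueError):
        auc_roc([0.1, 0.2], [1, 1], positive_class=1)


@settings(derandomize=True, max_examples=200)
@given(st.lists(st.tuples(st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0]),
                          st.integers(0, 1)), min_size=2, max_size=8))
def test_auc_matches_pair_counting_oracle(pairs):
    scores = [p[0] for p in pairs]
    labels = [p[1] for p in pairs]
    if len(set(labels)) < 2:
        return
    assert auc_roc(scores, labels, positive_class=1) == pytest.approx(
        _pair_count_auc(scores, labels))


def test_auc_matches_sklearn(rng):
    scores = rng.normal(size=100)
    labels = rng.integers(0, 2, size=100)
    labels[:2] = [0, 1]
    assert auc_roc(scores, labels, positive_class=1) == pytest.approx(
        skm.roc_auc_score(labels, scores))


# -- log loss -------------------------------------------------------------------

def test_log_loss_values():
    assert log_loss([0.5, 0.5], [0, 1]) == pytest.approx(np.log(2))
    assert log_loss([1.0, 0.0], [1, 0]) <= 3.5e-15
    probs = [0.2, 0.9, 0.4]
    labels = [0, 1, 1]
    perm = [2, 0, 1]
    assert log_loss([probs[i] for i in perm], [labels[i] for i in perm]) == \
        pytest.approx(log_loss(probs, labels))
    with pytest.raises(ValueError):
        log_loss([], [])


# -- bootstrap -------------------------------------------------------------------

def test_bootstrap_ci_constant_metric_and_determinism(rng):
    labels = rng.integers(0, 2, size=30)
    acc = lambda c, y: float((c == y).mean())
    lo, hi = bootstrap_ci(acc, labels, labels, n_boot=200, seed=1)
    assert (lo, hi) == (1.0, 1.0)
    preds = rng.integers(0, 2, size=30)
    ci1 = bootstrap_ci(acc, preds, labels, n_boot=200, seed=9)
    ci2 = bootstrap_ci(acc, preds, labels, n_boot=200, seed=9)
    assert ci1 == ci2
    with pytest.raises(ValueError):
        bootstrap_ci(acc, preds, labels, n_boot=50)


def test_bootstrap_ci_contains_point_estimate(rng):
    acc = lambda c, y: float((c == y).mean())
    hits = 0
    for trial in range(20):
        labels = rng.integers(0, 2, size=40)
        preds = np.where(rng.random(40) < 0.8, labels, 1 - labels)
        point = acc(preds, labels)
        lo, hi = bootstrap_ci(acc, preds, labels, n_boot=300, seed=trial)
        hits += int(lo <= point <= hi)
    assert hits >= 19


# -- patient aggregation -----------------------------------------------------------

def test_aggregate_patient_vote_mean_and_tiebreak():
    pids = ["a", "a", "a", "b", "b", "c", "c", "c"]
    calls = [1, 1, 0, 1, 0, 0, 0, 1]
    probs = [0.9, 0.8, 0.1, 0.9, 0.5, 0.2, 0.4, 0.9]
    order, pc, pp = aggregate_patient(calls, probs, pids)
    assert order == ["a", "b", "c"]
    assert pc.tolist() == [1, 1, 0]   # b: tie 1-1 -> mean prob 0.7 >= 0.5 -> 1
    assert pp == pytest.approx([0.6, 0.7, 0.5])
    assert pp[2] == pytest.approx(np.mean([0.2, 0.4, 0.9]))


# -- McNemar ----------------------------------------------------------------------

def test_mcnemar_exact_binomial_tail():
    labels = np.zeros(20, dtype=int)
    calls_a = np.zeros(20, dtype=int)          # A always correct
    calls_b = np.concatenate([np.ones(10), np.zeros(10)]).astype(int)  # b=10, c=0
    res = mcnemar_test(calls_a, calls_b, labels)
    assert res.method == "mcnemar-exact"
    assert res.p_value == pytest.approx(2 * 0.5 ** 10)
    assert res.extra == {"b": 10, "c": 0}


def test_mcnemar_symmetry_and_no_discordance():
    labels = np.array([0, 1] * 10)
    a = labels.copy(); b = labels.copy()
    a[:5] = 1 - a[:5]
    b[5:10] = 1 - b[5:10]   # b = c = 5
    res = mcnemar_test(a, b, labels)
    assert res.p_value == pytest.approx(1.0)
    res0 = mcnemar_test(labels, labels, labels)
    assert res0.p_value == 1.0 and res0.statistic == 0.0


def test_mcnemar_matches_statsmodels(rng):
    statsmodels = pytest.importorskip("statsmodels.stats.contingency_tables")
    labels = rng.integers(0, 2, size=200)
    a = np.where(rng.random(200) < 0.8, labels, 1 - labels)
    b = np.where(rng.random(200) < 0.7, labels, 1 - labels)
    ours = mcnemar_test(a, b, labels)
    bb, cc = ours.extra["b"], ours.extra["c"]
    table = [[0, bb], [cc, 0]]
    exact = bb + cc < 25
    sm = statsmodels.mcnemar(table, exact=exact, correction=True)
    assert ours.p_value == pytest.approx(float(sm.pvalue), rel=1e-9)


def test_mcnemar_order_invariance(rng):
    labels = rng.integers(0, 2, size=50)
    a = rng.integers(0, 2, size=50)
    b = rng.integers(0, 2, size=50)
    perm = rng.permutation(50)
    r1 = mcnemar_test(a, b, labels)
    r2 = mcnemar_test(a[perm], b[perm], labels[perm])
    assert r1.p_value == pytest.approx(r2.p_value)


# -- DeLong -----------------------------------------------------------------------

def test_delong_identical_scores_gives_p_one(rng):
    scores = rng.normal(size=60)
    labels = rng.integers(0, 2, size=60)
    labels[:2] = [0, 1]
    res = delong_test(scores, scores.copy(), labels, positive_class=1)
    assert res.p_value == 1.0 and res.statistic == 0.0


def test_delong_auc_consistent_with_midrank_auc(rng):
    scores_a = rng.normal(size=80)
    scores_b = rng.normal(size=80)
    labels = rng.integers(0, 2, size=80)
    labels[:2] = [0, 1]
    res = delong_test(scores_a, scores_b, labels, positive_class=1)
    assert abs(res.extra["auc_a"] - auc_roc(scores_a, labels, 1)) < 1e-12
    assert abs(res.extra["auc_b"] - auc_roc(scores_b, labels, 1)) < 1e-12


def test_delong_variance_close_to_bootstrap(rng):
    """DeLong's analytic AUC variance vs a large resampling estimate."""
    n = 50
    labels = np.array([1] * 25 + [0] * 25)
    scores = rng.normal(size=n) + 0.8 * labels
    res = delong_test(scores, rng.normal(size=n), labels, positive_class=1)
    boots = np.empty(10_000)
    for i in range(10_000):
        idx = rng.integers(0, n, size=n)
        while len(np.unique(labels[idx])) < 2:
            idx = rng.integers(0, n, size=n)
        boots[i] = auc_roc(scores[idx], labels[idx], 1)
    assert res.extra["var_a"] == pytest.approx(boots.var(ddof=1), rel=0.15)


def test_delong_detects_clear_auc_difference(rng):
    labels = np.array([1] * 40 + [0] * 40)
    good = labels + rng.normal(0, 0.3, size=80)
    noise = rng.normal(size=80)
    res = delong_test(good, noise, labels, positive_class=1)
    assert res.p_value < 0.001 and res.statistic > 0


# -- full report -------------------------------------------------------------------

def test_evaluate_predictions_report_structure(rng):
    labels = rng.integers(0, 2, size=60)
    probs = np.clip(0.7 * labels + 0.3 * rng.random(60), 0.01, 0.99)
    calls = (probs >= 0.5).astype(int)
    rep = evaluate_predictions(calls, probs, labels, positive_class=1,
                               n_boot=200, seed=0)
    for name in ("accuracy", "sensitivity", "specificity", "auc_roc", "kappa"):
        v = rep.point[name]
        assert v is not None
        assert rep.ci_low[name] <= v <= rep.ci_high[name]
    assert -1.0 <= rep.point["kappa"] <= 1.0
    assert rep.n == 60
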