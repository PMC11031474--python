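"""Evaluation statistics: confusion-matrix metrics with bootstrap 95% CIs,
midrank AUC, log loss, patient-level aggregation, and the paired tests
(McNemar on contingency tables, DeLong on correlated AUCs).

By default the *unmethylated* class is treated as positive (label 0 in the
1 = methylated encoding); this is configurable everywhere through
``positive_class``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

#: default positive class in the 1 = methylated / 0 = unmethylated encoding
POSITIVE_UNMETHYLATED = 0

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "ppv", "npv",
                "f_score", "auc_roc", "log_loss", "kappa")


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class PairedTestResult:
    statistic: float
    p_value: float
    method: str
    extra: dict = field(default_factory=dict)


@dataclass
class MetricsReport:
    """Point estimates and 95% CIs for the nine evaluation metrics."""
    point: dict[str, float | None]
    ci_low: dict[str, float | None] = field(default_factory=dict)
    ci_high: dict[str, float | None] = field(default_factory=dict)
    n: int = 0

    def as_dict(self) -> dict:
        out = {}
        for name in METRIC_NAMES:
            if name in self.point:
                out[name] = {"value": self.point[name],
                             "ci_low": self.ci_low.get(name),
                             "ci_high": self.ci_high.get(name)}
        out["n"] = self.n
        return out


# ---------------------------------------------------------------------------
# point metrics
# ---------------------------------------------------------------------------

def confusion(preds: Sequence[int], labels: Sequence[int],
              positive_class: int = POSITIVE_UNMETHYLATED) -> ConfusionMatrix:
    preds = np.asarray(preds)
    labels = np.asarray(labels)
    if preds.shape != labels.shape or preds.size == 0:
        raise ValueError("preds and labels must be equal-length and nonempty")
    p = preds == positive_class
    y = labels == positive_class
    return ConfusionMatrix(tp=int(np.sum(p & y)), fp=int(np.sum(p & ~y)),
                           fn=int(np.sum(~p & y)), tn=int(np.sum(~p & ~y)))


def _safe_div(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def metrics_from_confusion(cm: ConfusionMatrix) -> dict[str, float | None]:
    """Accuracy, sensitivity, specificity, PPV, NPV, F-score and Cohen's kappa.

    Undefined ratios (zero denominators) are reported as ``None`` rather
    than coerced to 0.
    """
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    acc = (cm.tp + cm.tn) / n
    sens = _safe_div(cm.tp, cm.tp + cm.fn)
    spec = _safe_div(cm.tn, cm.tn + cm.fp)
    ppv = _safe_div(cm.tp, cm.tp + cm.fp)
    npv = _safe_div(cm.tn, cm.tn + cm.fn)
    f = None
    if ppv is not None and sens is not None and (ppv + sens) > 0:
        f = 2 * ppv * sens / (ppv + sens)
    # chance agreement from marginals
    pe = ((cm.tp + cm.fp) * (cm.tp + cm.fn) + (cm.fn + cm.tn) * (cm.fp + cm.tn)) / n**2
    kappa = _safe_div(acc - pe, 1.0 - pe) if pe < 1.0 else None
    return {"accuracy": acc, "sensitivity": sens, "specificity": spec,
            "ppv": ppv, "npv": npv, "f_score": f, "kappa": kappa}


def confusion_from_rates(n_pos: int, n_neg: int,
                         sensitivity: float, specificity: float) -> ConfusionMatrix:
    """Reconstruct integer confusion cells from class counts and printed rates."""
    tp = round(sensitivity * n_pos)
    tn = round(specificity * n_neg)
    return ConfusionMatrix(tp=tp, fn=n_pos - tp, tn=tn, fp=n_neg - tn)


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def auc_roc(scores: Sequence[float], labels: Sequence[int],
            positive_class: int = POSITIVE_UNMETHYLATED) -> float:
    """AUC by the midrank (Mann-Whitney) formulation; ties get half credit."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive_class
    m, n = int(pos.sum()), int((~pos).sum())
    if m == 0 or n == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = _midranks(scores)
    return float((ranks[pos].sum() - m * (m + 1) / 2) / (m * n))


def log_loss(probs: Sequence[float], labels: Sequence[int],
             clip_eps: float = 1e-15) -> float:
    """Mean negative log-likelihood (natural log), probabilities clipped."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.size == 0:
        raise ValueError("empty input")
    p = np.clip(p, clip_eps, 1.0 - clip_eps)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


# ---------------------------------------------------------------------------
# bootstrap confidence intervals
# ---------------------------------------------------------------------------

def bootstrap_ci(metric_fn: Callable[[np.ndarray, np.ndarray], float | None],
                 values: Sequence[float], labels: Sequence[int],
                 n_boot: int = 1000, seed: int = 0,
                 alpha: float = 0.05, max_retries: int = 100) -> tuple[float, float]:
    """Percentile bootstrap over resampled sample indices.

    ``metric_fn(values[idx], labels[idx])`` is evaluated on each resample;
    resamples on which it is undefined (e.g. one class only for AUC) are
    redrawn, with a retry cap.
    """
    values = np.asarray(values)
    labels = np.asarray(labels)
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    n = len(labels)
    out = np.empty(n_boot)
    for b in range(n_boot):
        stat = None
        for _ in range(max_retries):
            idx = rng.integers(0, n, size=n)
            try:
                stat = metric_fn(values[idx], labels[idx])
            except ValueError:
                stat = None
            if stat is not None:
                break
        if stat is None:
            raise RuntimeError("degenerate resamples exceeded retry cap")
        out[b] = stat
    lo, hi = np.percentile(out, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def evaluate_predictions(calls: Sequence[int], probs: Sequence[float],
                         labels: Sequence[int],
                         positive_class: int = POSITIVE_UNMETHYLATED,
                         n_boot: int = 1000, seed: int = 0) -> MetricsReport:
    """Full metrics report with percentile-bootstrap 95% CIs."""
    calls = np.asarray(calls)
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    point: dict[str, float | None] = metrics_from_confusion(
        confusion(calls, labels, positive_class))
    try:
        point["auc_roc"] = auc_roc(probs, labels, positive_class)
    except ValueError:
        point["auc_roc"] = None
    # log loss is computed against the positive class probability
    pos_prob = probs if positive_class == 1 else 1.0 - probs
    y_pos = (labels == positive_class).astype(float)
    point["log_loss"] = log_loss(pos_prob, y_pos)

    report = MetricsReport(point=point, n=len(labels))
    call_fns = {
        "accuracy": lambda c, y: metrics_from_confusion(confusion(c, y, positive_class))["accuracy"],
        "sensitivity": lambda c, y: metrics_from_confusion(confusion(c, y, positive_class))["sensitivity"],
        "specificity": lambda c, y: metrics_from_confusion(confusion(c, y, positive_class))["specificity"],
        "ppv": lambda c, y: metrics_from_confusion(confusion(c, y, positive_class))["ppv"],
        "npv": lambda c, y: metrics_from_confusion(confusion(c, y, positive_class))["npv"],
        "f_score": lambda c, y: metrics_from_confusion(confusion(c, y, positive_class))["f_score"],
        "kappa": lambda c, y: metrics_from_confusion(confusion(c, y, positive_class))["kappa"],
    }
    for i, (name, fn) in enumerate(call_fns.items()):
        if point[name] is None:
            continue
        lo, hi = bootstrap_ci(fn, calls, labels, n_boot=n_boot, seed=seed + i)
        report.ci_low[name], report.ci_high[name] = lo, hi
    if point["auc_roc"] is not None:
        lo, hi = bootstrap_ci(lambda s, y: auc_roc(s, y, positive_class),
                              probs, labels, n_boot=n_boot, seed=seed + 7)
        report.ci_low["auc_roc"], report.ci_high["auc_roc"] = lo, hi
    lo, hi = bootstrap_ci(lambda p, y: log_loss(p, y), pos_prob, y_pos,
                          n_boot=n_boot, seed=seed + 8)
    report.ci_low["log_loss"], report.ci_high["log_loss"] = lo, hi
    return report


# ---------------------------------------------------------------------------
# patient-level aggregation
# ---------------------------------------------------------------------------

def aggregate_patient(calls: Sequence[int], probs: Sequence[float],
                      patient_ids: Sequence[str]) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Fold per-image outputs to one row per patient.

    Binary call: majority vote over the patient's images, ties broken by the
    mean probability (>= 0.5 votes positive).  Probability: arithmetic mean.
    Returns (patient ids, calls, probabilities) with patients in first-seen
    order.
    """
    calls = np.asarray(calls)
    probs = np.asarray(probs, dtype=float)
    pids = list(patient_ids)
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, pid in enumerate(pids):
        if pid not in groups:
            groups[pid] = []
            order.append(pid)
        groups[pid].append(i)
    agg_calls, agg_probs = [], []
    for pid in order:
        idx = groups[pid]
        mean_prob = float(probs[idx].mean())
        ones = int(calls[idx].sum())
        zeros = len(idx) - ones
        if ones > zeros:
            call = 1
        elif zeros > ones:
            call = 0
        else:
            call = int(mean_prob >= 0.5)
        agg_calls.append(call)
        agg_probs.append(mean_prob)
    return order, np.asarray(agg_calls), np.asarray(agg_probs)


# ---------------------------------------------------------------------------
# paired tests
# ---------------------------------------------------------------------------

def mcnemar_test(calls_a: Sequence[int], calls_b: Sequence[int],
                 labels: Sequence[int], exact_threshold: int = 25) -> PairedTestResult:
    """McNemar test on paired classifier calls.

    Discordant counts: b = A correct & B wrong, c = A wrong & B correct.
    Exact two-sided binomial p for b + c < ``exact_threshold``, otherwise the
    chi-square statistic with continuity correction.
    """
    a = np.asarray(calls_a) == np.asarray(labels)
    bb = np.asarray(calls_b) == np.asarray(labels)
    if a.shape != bb.shape:
        raise ValueError("paired calls must have equal length")
    b = int(np.sum(a & ~bb))
    c = int(np.sum(~a & bb))
    n = b + c
    if n == 0:
        return PairedTestResult(0.0, 1.0, "mcnemar-exact", {"b": b, "c": c})
    if n < exact_threshold:
        p = min(1.0, 2.0 * stats.binom.cdf(min(b, c), n, 0.5))
        return PairedTestResult(float(min(b, c)), float(p), "mcnemar-exact",
                                {"b": b, "c": c})
    chi2 = (abs(b - c) - 1.0) ** 2 / n
    p = float(stats.chi2.sf(chi2, df=1))
    return PairedTestResult(float(chi2), p, "mcnemar-cc", {"b": b, "c": c})


def _placements(scores: np.ndarray, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    m, n = int(pos.sum()), int((~pos).sum())
    ranks_all = _midranks(scores)
    ranks_pos = _midranks(scores[pos])
    ranks_neg = _midranks(scores[~pos])
    auc = (ranks_all[pos].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (ranks_all[pos] - ranks_pos) / n          # P(X_pos > X_neg) per positive
    v01 = 1.0 - (ranks_all[~pos] - ranks_neg) / m   # per negative
    return v10, v01, float(auc)


def delong_test(scores_a: Sequence[float], scores_b: Sequence[float],
                labels: Sequence[int],
                positive_class: int = POSITIVE_UNMETHYLATED) -> PairedTestResult:
    """DeLong's test for two correlated ROC AUCs via placement values."""
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    if sa.shape != sb.shape or sa.shape != labels.shape:
        raise ValueError("paired scores and labels must have equal length")
    pos = labels == positive_class
    m, n = int(pos.sum()), int((~pos).sum())
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    v10a, v01a, auc_a = _placements(sa, pos)
    v10b, v01b, auc_b = _placements(sb, pos)
    s10 = np.cov(np.stack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    extra = {"auc_a": auc_a, "auc_b": auc_b,
             "var_a": float(cov[0, 0]), "var_b": float(cov[1, 1])}
    if var_diff <= 0:
        if math.isclose(auc_a, auc_b, abs_tol=1e-12):
            return PairedTestResult(0.0, 1.0, "delong", extra)
        raise ValueError("degenerate variance with unequal AUCs")
    z = (auc_a - auc_b) / math.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return PairedTestResult(float(z), float(p), "delong", extra)
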