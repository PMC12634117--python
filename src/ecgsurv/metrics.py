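"""Evaluation metrics: AUROC with DeLong comparison, Harrell's C,
Kaplan-Meier curves, horizon Brier score, continuous NRI, threshold metrics,
and a seeded nonparametric bootstrap for confidence intervals.

Horizon-status convention (Brier, NRI): a subject is determinate at horizon
``h`` when they had the event at or before ``h`` (outcome 1) or were
followed beyond ``h`` (outcome 0). Subjects censored before the horizon are
excluded rather than inverse-probability weighted; this is the transparent
(slightly optimistic under heavy censoring) choice and is logged here once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lifelines import KaplanMeierFitter
from numba import njit
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score


@dataclass
class MetricReport:
    """A point estimate with its bootstrap percentile interval."""

    name: str
    estimate: float
    ci_low: float
    ci_high: float
    n: int
    settings: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("CI must contain the point estimate")


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return labels


# --------------------------------------------------------------------------
# AUROC and DeLong


def auroc(scores, labels) -> float:
    """Rank-based area under the ROC curve."""
    labels = _check_binary(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """Per-subject placement values (V10, V01) and the AUC (fast DeLong)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    tz = _midranks(np.concatenate([pos, neg]))
    tx = _midranks(pos)
    ty = _midranks(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return v10, v01, auc


def delong_variance(scores, labels) -> tuple[float, float]:
    """Returns (auc, variance of the AUC estimate) by DeLong's method."""
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    v10, v01, auc = _delong_components(scores, labels)
    var = (np.var(v10, ddof=1) / len(v10)) + (np.var(v01, ddof=1) / len(v01))
    return float(auc), float(var)


def delong_test(scores_a, scores_b, labels) -> dict:
    """Paired DeLong test comparing two correlated AUCs on the same subjects.

    Returns ``{"auc_a", "auc_b", "z", "p"}``. Identical scores give z=0, p=1.
    """
    labels = _check_binary(labels)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    va10, va01, auc_a = _delong_components(a, labels)
    vb10, vb01, auc_b = _delong_components(b, labels)
    m, n = len(va10), len(va01)
    var = (np.var(va10 - vb10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(va01 - vb01, ddof=1) / n if n > 1 else 0.0)
    diff = auc_a - auc_b
    if var <= 0:
        z = 0.0 if diff == 0 else np.inf * np.sign(diff)
    else:
        z = diff / np.sqrt(var)
    p = 1.0 if not np.isfinite(z) and diff == 0 else float(
        2.0 * stats.norm.sf(abs(z)))
    if diff == 0:
        z, p = 0.0, 1.0
    return {"auc_a": float(auc_a), "auc_b": float(auc_b), "z": float(z), "p": p}


# --------------------------------------------------------------------------
# Harrell's concordance index


@njit(cache=True)
def _concordance_pairs(risk, time, event):  # pragma: no cover - numba
    concordant = 0.0
    usable = 0.0
    n = len(time)
    for i in range(n):
        for j in range(i + 1, n):
            if time[i] == time[j]:
                continue  # tied times excluded (documented convention)
            if time[i] < time[j]:
                a, b = i, j
            else:
                a, b = j, i
            if event[a] == 0:
                continue  # shorter time censored: pair unusable
            usable += 1.0
            if risk[a] > risk[b]:
                concordant += 1.0
            elif risk[a] == risk[b]:
                concordant += 0.5
    return concordant, usable


def harrell_c(risk, time, event) -> float:
    """Harrell's concordance index for right-censored data.

    A pair is usable when the subject with the shorter observed time had the
    event; higher risk on that subject is concordant, tied risks count 1/2.
    Pairs with tied observed times are excluded. No usable pair is an error.
    """
    risk = np.ascontiguousarray(risk, dtype=np.float64)
    time = np.ascontiguousarray(time, dtype=np.float64)
    event = np.ascontiguousarray(np.asarray(event).astype(np.int64))
    if not (len(risk) == len(time) == len(event)):
        raise ValueError("risk, time, event must have equal length")
    concordant, usable = _concordance_pairs(risk, time, event)
    if usable == 0:
        raise ValueError("concordance undefined: no usable pairs")
    return float(concordant / usable)


# --------------------------------------------------------------------------
# Kaplan-Meier


def km_curve(time, event):
    """Product-limit survival estimate; returns ``(times, survival)``.

    The first point is (0, 1); the cumulative event rate is ``1 - survival``.
    """
    time = np.asarray(time, dtype=float)
    if len(time) == 0:
        raise ValueError("records must be non-empty")
    kmf = KaplanMeierFitter()
    kmf.fit(time, np.asarray(event).astype(int))
    sf = kmf.survival_function_
    return sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float)


# --------------------------------------------------------------------------
# horizon-status metrics


def _horizon_status(time, event, horizon):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    had_event = (event == 1) & (time <= horizon)
    determinate = had_event | (time >= horizon)
    return determinate, had_event.astype(float)


def brier_at_horizon(risk, time, event, horizon: float = 5.0) -> float:
    """Mean squared error between horizon risk and horizon outcome.

    Censored-before-horizon subjects are excluded (see module docstring).
    """
    risk = np.asarray(risk, dtype=float)
    det, outcome = _horizon_status(time, event, horizon)
    if not det.any():
        raise ValueError("no subjects with determinate status at the horizon")
    return float(np.mean((risk[det] - outcome[det]) ** 2))


def continuous_nri(old_risk, new_risk, time, event, horizon: float = 5.0) -> float:
    """Continuous (category-free) net reclassification improvement.

    ``[P(new>old | event) - P(new<old | event)] +
    [P(new<old | non-event) - P(new>old | non-event)]`` with horizon status
    as in :func:`brier_at_horizon`.
    """
    old_risk = np.asarray(old_risk, dtype=float)
    new_risk = np.asarray(new_risk, dtype=float)
    det, outcome = _horizon_status(time, event, horizon)
    delta = new_risk[det] - old_risk[det]
    ev = outcome[det] == 1
    if not ev.any() or ev.all():
        raise ValueError("NRI needs both events and non-events at the horizon")
    up_ev = np.mean(delta[ev] > 0) - np.mean(delta[ev] < 0)
    down_ne = np.mean(delta[~ev] < 0) - np.mean(delta[~ev] > 0)
    return float(up_ev + down_ne)


# --------------------------------------------------------------------------
# threshold metrics


def classification_threshold_metrics(scores, labels, threshold: float) -> dict:
    """Sensitivity/specificity/PPV/NPV at a threshold, plus AUPRC.

    Undefined ratios (empty denominator) are reported as NaN, never as 0.
    """
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))

    def _ratio(num, den):
        return num / den if den > 0 else float("nan")

    return {
        "sensitivity": _ratio(tp, tp + fn),
        "specificity": _ratio(tn, tn + fp),
        "ppv": _ratio(tp, tp + fp),
        "npv": _ratio(tn, tn + fn),
        "auprc": float(average_precision_score(labels, scores)),
    }


# --------------------------------------------------------------------------
# bootstrap


def bootstrap_ci(stat_fn, arrays, n_boot: int = 2000, seed: int = 0,
                 alpha: float = 0.05, clusters=None) -> tuple[float, float, float]:
    """Percentile bootstrap interval for ``stat_fn(*arrays)``.

    Resampling is by subject, or by cluster (e.g. patient) when ``clusters``
    is given. Replicates where the statistic is undefined are skipped.
    Returns ``(estimate, ci_low, ci_high)``.
    """
    arrays = [np.asarray(a) for a in arrays]
    n = len(arrays[0])
    rng = np.random.default_rng(seed)
    estimate = float(stat_fn(*arrays))
    stats_ = []
    if clusters is not None:
        clusters = np.asarray(clusters)
        uniq = np.unique(clusters)
        members = {c: np.flatnonzero(clusters == c) for c in uniq}
    for _ in range(n_boot):
        if clusters is None:
            idx = rng.integers(0, n, size=n)
        else:
            chosen = rng.choice(uniq, size=len(uniq), replace=True)
            idx = np.concatenate([members[c] for c in chosen])
        try:
            stats_.append(stat_fn(*[a[idx] for a in arrays]))
        except ValueError:
            continue
    if not stats_:
        raise ValueError("all bootstrap replicates were degenerate")
    lo, hi = np.percentile(stats_, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return estimate, float(lo), float(hi)
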