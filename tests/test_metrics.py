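"""Metric implementations against hand-worked examples and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from lifelines.utils import concordance_index as lifelines_cindex

from ecgsurv.metrics import (auroc, bootstrap_ci, brier_at_horizon,
                             classification_threshold_metrics, continuous_nri,
                             delong_test, delong_variance, harrell_c, km_curve)

from _oracles import (brier_oracle, km_product_limit, nri_oracle,
                      pairwise_auroc, pairwise_cindex)


# --------------------------------------------------------------------------
# AUROC / DeLong


def test_auroc_worked_example():
    assert auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)


def test_auroc_perfect_separation():
    assert auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0


def test_auroc_single_class_errors():
    with pytest.raises(ValueError):
        auroc([0.1, 0.2], [1, 1])


def test_delong_self_comparison_is_null():
    rng = np.random.default_rng(0)
    scores = rng.normal(0, 1, 100)
    labels = (rng.random(100) < 0.4).astype(int)
    res = delong_test(scores, scores, labels)
    assert res["z"] == 0.0 and res["p"] == 1.0


def test_delong_variance_positive_and_detects_difference():
    rng = np.random.default_rng(1)
    labels = (rng.random(400) < 0.5).astype(int)
    good = labels + rng.normal(0, 0.5, 400)
    bad = rng.normal(0, 1, 400)
    auc, var = delong_variance(good, labels)
    assert auc > 0.8 and var > 0
    res = delong_test(good, bad, labels)
    assert res["p"] < 0.01 and res["auc_a"] > res["auc_b"]


# --------------------------------------------------------------------------
# Harrell's C


def test_harrell_c_worked_example():
    """risks [0.2, 0.9, 0.5], times [1, 3, 5], all events: only (2nd, 3rd)
    concordant out of three usable pairs."""
    assert harrell_c([0.2, 0.9, 0.5], [1, 3, 5], [1, 1, 1]) == pytest.approx(1 / 3)


def test_harrell_c_degenerate_cases():
    assert harrell_c([0.5, 0.5, 0.5], [1, 2, 3], [1, 1, 1]) == 0.5  # all ties
    assert harrell_c([3, 2, 1], [1, 2, 3], [1, 1, 1]) == 1.0  # anti-ordered
    with pytest.raises(ValueError):
        harrell_c([1, 2], [1, 2], [0, 0])  # no usable pairs


def test_harrell_c_matches_lifelines():
    rng = np.random.default_rng(2)
    for _ in range(20):
        n = rng.integers(20, 120)
        time = rng.exponential(2, n).round(3)  # some exact ties possible
        time = time + rng.random(n) * 1e-6  # break ties: conventions differ there
        event = (rng.random(n) < 0.7).astype(int)
        risk = rng.normal(0, 1, n)
        if event.sum() == 0:
            continue
        ours = harrell_c(risk, time, event)
        theirs = lifelines_cindex(time, -risk, event)
        assert ours == pytest.approx(theirs, abs=1e-12)


def test_harrell_c_oracle_equality():
    rng = np.random.default_rng(3)
    for _ in range(30):
        n = int(rng.integers(5, 80))
        time = rng.integers(1, 20, n).astype(float)
        event = (rng.random(n) < 0.6).astype(int)
        risk = rng.integers(0, 6, n).astype(float)  # force score ties
        try:
            expected = pairwise_cindex(risk, time, event)
        except ValueError:
            with pytest.raises(ValueError):
                harrell_c(risk, time, event)
            continue
        assert harrell_c(risk, time, event) == pytest.approx(expected, abs=1e-12)


def test_uncensored_c_equals_time_rank_auroc_property():
    """Without censoring/ties, C equals pairwise ordering agreement."""
    rng = np.random.default_rng(4)
    for _ in range(10):
        n = 60
        time = rng.permutation(n) + 1.0
        risk = rng.normal(0, 1, n)
        c = harrell_c(risk, time, np.ones(n, dtype=int))
        assert c == pytest.approx(pairwise_cindex(risk, time, np.ones(n, int)),
                                  abs=1e-12)


# --------------------------------------------------------------------------
# Kaplan-Meier


def test_km_no_events_flat_at_one():
    t, s = km_curve([1, 2, 3], [0, 0, 0])
    assert np.all(s == 1.0)


def test_km_worked_example():
    """times [1, 2(censored), 3], events at 1 and 3: S(1)=2/3, S(3)=0."""
    t, s = km_curve([1, 2, 3], [1, 0, 1])
    lookup = dict(zip(t, s))
    assert lookup[1.0] == pytest.approx(2 / 3)
    assert lookup[3.0] == pytest.approx(0.0)


def test_km_all_events_at_once():
    t, s = km_curve([1, 1, 1], [1, 1, 1])
    assert s[-1] == 0.0


def test_km_matches_product_limit_oracle():
    rng = np.random.default_rng(5)
    for _ in range(20):
        n = int(rng.integers(5, 100))
        time = rng.integers(1, 15, n).astype(float)
        event = (rng.random(n) < 0.6).astype(int)
        t_ref, s_ref = km_product_limit(time, event)
        t_est, s_est = km_curve(time, event)
        ref = dict(zip(t_ref, s_ref))
        for tt, ss in zip(t_est, s_est):
            assert ss == pytest.approx(ref[tt], abs=1e-10)


# --------------------------------------------------------------------------
# Brier / NRI


def test_brier_worked_examples():
    assert brier_at_horizon([1.0, 0.0], [1, 9], [1, 0], 5) == 0.0  # perfect
    assert brier_at_horizon([0.5, 0.5, 0.5], [1, 9, 2], [1, 0, 1], 5) == 0.25
    assert brier_at_horizon([0.2, 0.8], [9, 1], [0, 1], 5) == pytest.approx(0.04)


def test_brier_excludes_censored_before_horizon():
    # second subject censored at 2y: indeterminate at 5y, dropped
    assert brier_at_horizon([0.0, 0.9, 1.0], [6, 2, 3], [0, 0, 1], 5) == 0.0


def test_brier_no_determinate_errors():
    with pytest.raises(ValueError):
        brier_at_horizon([0.5], [2], [0], 5)


def test_nri_worked_examples():
    t = [1, 2, 9]
    e = [1, 1, 0]
    old = np.array([0.5, 0.5, 0.5])
    assert continuous_nri(old, old, t, e) == 0.0
    # events moved +0.1 and -0.1; the non-event moved down 0.3 -> NRI = 1
    new = old + np.array([0.1, -0.1, -0.3])
    assert continuous_nri(old, new, t, e) == pytest.approx(1.0)
    # everyone up, half events half not -> 1 - 1 = 0
    half = np.array([0.3, 0.4])
    assert continuous_nri(half, half + 0.2, [1, 9], [1, 0]) == pytest.approx(0.0)


def test_nri_needs_both_outcomes():
    with pytest.raises(ValueError):
        continuous_nri([0.1], [0.2], [1], [1])


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 10_000))
def test_nri_identity_property(seed):
    rng = np.random.default_rng(seed)
    n = 30
    old = rng.random(n)
    time = rng.exponential(3, n)
    event = (rng.random(n) < 0.5).astype(int)
    try:
        assert continuous_nri(old, old.copy(), time, event) == 0.0
    except ValueError:
        pass  # no events or no non-events at horizon: rejected by design


# --------------------------------------------------------------------------
# threshold metrics


def test_threshold_metrics_worked_table():
    got = classification_threshold_metrics([0.9, 0.8, 0.2, 0.1], [1, 0, 1, 0], 0.5)
    assert got["sensitivity"] == 0.5 and got["specificity"] == 0.5
    assert got["ppv"] == 0.5 and got["npv"] == 0.5


def test_threshold_metrics_perfect_and_degenerate():
    got = classification_threshold_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 0.5)
    assert all(got[k] == 1.0 for k in ("sensitivity", "specificity", "ppv", "npv"))
    allpos = classification_threshold_metrics([0.9, 0.8], [1, 0], 0.0)
    assert allpos["sensitivity"] == 1.0 and allpos["specificity"] == 0.0
    assert np.isnan(allpos["npv"])  # no negative calls: undefined, not 0


# --------------------------------------------------------------------------
# permutation invariance and bootstrap


def test_metrics_invariant_to_subject_order():
    rng = np.random.default_rng(6)
    n = 80
    scores = rng.normal(0, 1, n)
    labels = (rng.random(n) < 0.4).astype(int)
    time = rng.exponential(3, n)
    event = (rng.random(n) < 0.6).astype(int)
    perm = rng.permutation(n)
    assert auroc(scores, labels) == pytest.approx(
        auroc(scores[perm], labels[perm]), abs=1e-12)
    assert harrell_c(scores, time, event) == pytest.approx(
        harrell_c(scores[perm], time[perm], event[perm]), abs=1e-12)
    assert brier_at_horizon(scores, time, event, 3) == pytest.approx(
        brier_at_horizon(scores[perm], time[perm], event[perm], 3), abs=1e-12)


def test_bootstrap_ci_brackets_estimate():
    rng = np.random.default_rng(7)
    labels = (rng.random(300) < 0.5).astype(int)
    scores = labels + rng.normal(0, 1, 300)
    est, lo, hi = bootstrap_ci(auroc, [scores, labels], n_boot=200, seed=1)
    assert lo <= est <= hi
    assert hi - lo < 0.2
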