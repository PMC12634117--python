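"""Independent brute-force oracles used to verify the package's metrics.

Everything here is written as plain enumeration / closed forms, kept
deliberately separate from the implementations under test.
"""

from __future__ import annotations

import numpy as np


def pairwise_auroc(scores, labels) -> float:
    """AUROC by enumerating every (positive, negative) pair."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def pairwise_cindex(risk, time, event) -> float:
    """Harrell's C by O(n^2) pair enumeration.

    Usable pairs: distinct observed times where the earlier subject had the
    event. Tied risks count 1/2; tied times are excluded.
    """
    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    concordant = 0.0
    usable = 0.0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if i == j or time[i] >= time[j] or event[i] == 0:
                continue
            usable += 1.0
            if risk[i] > risk[j]:
                concordant += 1.0
            elif risk[i] == risk[j]:
                concordant += 0.5
    if usable == 0:
        raise ValueError("no usable pairs")
    return concordant / usable


def km_product_limit(time, event):
    """Kaplan-Meier by the textbook product over distinct event times."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    times_out = [0.0]
    surv_out = [1.0]
    s = 1.0
    for t in np.unique(time):
        at_risk = np.sum(time >= t)
        deaths = np.sum((time == t) & (event == 1))
        if deaths > 0:
            s *= 1.0 - deaths / at_risk
        times_out.append(float(t))
        surv_out.append(s)
    return np.array(times_out), np.array(surv_out)


def brier_oracle(risk, time, event, horizon) -> float:
    """Horizon Brier score by explicit subject enumeration."""
    total, count = 0.0, 0
    for r, t, e in zip(risk, time, event):
        if e == 1 and t <= horizon:
            total += (r - 1.0) ** 2
            count += 1
        elif t >= horizon:
            total += r ** 2
            count += 1
    if count == 0:
        raise ValueError("no determinate subjects")
    return total / count


def nri_oracle(old, new, time, event, horizon) -> float:
    """Continuous NRI by direct counting."""
    up_e = down_e = n_e = 0
    up_n = down_n = n_n = 0
    for o, w, t, e in zip(old, new, time, event):
        if e == 1 and t <= horizon:
            n_e += 1
            up_e += w > o
            down_e += w < o
        elif t >= horizon:
            n_n += 1
            up_n += w > o
            down_n += w < o
    if n_e == 0 or n_n == 0:
        raise ValueError("need events and non-events")
    return (up_e - down_e) / n_e + (down_n - up_n) / n_n
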