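"""Cohort construction: grade recalibration, ECG-echo pairing, discrete-time
survival labels with prevalent-disease encoding, exclusions and splits.

The discrete-time grid defaults to eight edges / seven intervals:
``[0, 60 d]`` (the baseline/"first timepoint" interval, matching the 60-day
ECG-echo pairing window), then ``(60 d, 1 y]``, yearly through 5 years, and
``(5 y, inf)``. Significant disease at the paired baseline echo is encoded
as an event in the first interval; incident disease as an event in the
interval containing the first significant follow-up echo; censoring masks
every interval not fully observed.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GRADES, VALVES, grade_rank

logger = logging.getLogger(__name__)

#: Default interval edges in years (last interval open-ended).
DEFAULT_EDGES = np.array([0.0, 60.0 / 365.25, 1.0, 2.0, 3.0, 4.0, 5.0, np.inf])

PAIRING_WINDOW_DAYS = 60
BLANKING_DAYS = 60
MIN_AGE_YEARS = 14.0

_GRADE_TOKEN = re.compile("|".join(GRADES))


def recalibrate_grade(diagnostic_statement: str) -> str:
    """Map a diagnostic statement to the four-level scale.

    When a statement mentions a range ("moderate-severe", "mild to
    moderate"), the least severe grade mentioned is recorded.
    """
    tokens = _GRADE_TOKEN.findall(str(diagnostic_statement).lower())
    if not tokens:
        raise ValueError(f"unparseable grade: {diagnostic_statement!r}")
    return min(tokens, key=grade_rank)


@dataclass
class EcgEchoPair:
    """One ECG linked to its nearest echo within the pairing window."""

    ecg_id: str
    patient_id: str
    ecg_date: pd.Timestamp
    echo_date: pd.Timestamp
    interval_days: int  # signed, echo - ecg
    grades: dict[str, str]


def pair_ecg_echo(ecgs: pd.DataFrame, echos: pd.DataFrame,
                  window_days: int = PAIRING_WINDOW_DAYS) -> pd.DataFrame:
    """Pair each ECG with its nearest echo within ``window_days``.

    Each ECG receives at most one echo (the one with the shortest absolute
    interval; equidistant ties resolved toward the earlier exam). ECGs with
    no in-window echo are dropped. Output keeps the echo's grade and
    measurement columns plus ``interval_days`` (echo minus ECG).
    """
    ecgs = ecgs.rename(columns={"date": "ecg_date"})
    echos = echos.rename(columns={"date": "echo_date"})
    merged = ecgs.merge(echos, on="patient_id", how="inner")
    if merged.empty:
        out = merged.copy()
        out["interval_days"] = pd.Series(dtype=int)
        return out
    merged["interval_days"] = (merged["echo_date"] - merged["ecg_date"]).dt.days
    merged = merged[merged["interval_days"].abs() <= window_days]
    merged = merged.assign(_abs=merged["interval_days"].abs())
    merged = merged.sort_values(["ecg_id", "_abs", "echo_date"], kind="mergesort")
    paired = merged.groupby("ecg_id", as_index=False, sort=True).first()
    return paired.drop(columns="_abs").reset_index(drop=True)


@dataclass
class DiscreteSurvivalLabel:
    """Per-interval event/censor encoding for one ECG-echo pair.

    ``y[k]`` is 1 for the interval containing the event (the first interval
    for prevalent disease), 0 for fully observed event-free intervals;
    ``mask[k]`` marks intervals that contribute to the likelihood. ``time``
    is the observed follow-up (event or censoring) in years from the ECG.
    """

    ecg_id: str
    patient_id: str
    valve: str
    interval_edges: np.ndarray
    y: np.ndarray
    mask: np.ndarray
    prevalent: bool
    event: bool
    time: float
    ecg_date: pd.Timestamp = None

    def __post_init__(self) -> None:
        observed_events = self.y[self.mask].sum()
        if observed_events > 1:
            raise ValueError("at most one interval may carry the event")
        if self.prevalent != bool(self.mask[0] and self.y[0] == 1):
            raise ValueError("prevalent flag must mirror y=1 in the first interval")


def _significant(grade_statement) -> bool:
    """Grade statement -> significant?, via least-severe recalibration."""
    return grade_rank(recalibrate_grade(grade_statement)) >= 2


def _echo_series(echos: pd.DataFrame, valve: str):
    """Per-patient sorted arrays of (dates, significant?) for one valve."""
    col = f"{valve}_grade"
    sig = echos[col].map(_significant)
    frame = pd.DataFrame({
        "patient_id": echos["patient_id"],
        "date": echos["echo_date"] if "echo_date" in echos else echos["date"],
        "sig": sig.to_numpy(),
    }).sort_values(["patient_id", "date"], kind="mergesort")
    return {pid: (grp["date"].to_numpy(), grp["sig"].to_numpy(dtype=bool))
            for pid, grp in frame.groupby("patient_id", sort=False)}


def build_survival_labels(
    pairs: pd.DataFrame,
    echos: pd.DataFrame,
    valve: str,
    interval_edges: np.ndarray = DEFAULT_EDGES,
) -> list[DiscreteSurvivalLabel]:
    """Build one :class:`DiscreteSurvivalLabel` per ECG-echo pair.

    The outcome is the first follow-up echo with a moderate/severe grade for
    ``valve``; its time (years from the ECG date) places the event interval.
    Censoring is the last echo on record. A significant follow-up echo dated
    on or before the ECG of a pair whose baseline grade is below moderate is
    logged as a data inconsistency and treated as prevalent disease.
    """
    if valve not in VALVES:
        raise ValueError(f"unknown valve: {valve!r}")
    edges = np.asarray(interval_edges, dtype=float)
    if edges[0] != 0 or np.any(np.diff(edges) <= 0):
        raise ValueError("interval_edges must start at 0 and increase")
    k_total = len(edges) - 1
    series = _echo_series(echos, valve)

    labels: list[DiscreteSurvivalLabel] = []
    for row in pairs.itertuples(index=False):
        baseline_grade = getattr(row, f"{valve}_grade")
        prevalent = _significant(baseline_grade)
        ecg_date = pd.Timestamp(row.ecg_date)
        y = np.zeros(k_total)
        mask = np.zeros(k_total, dtype=bool)
        mask[0] = True  # the paired echo observes the baseline interval

        dates, sig = series.get(row.patient_id, (np.array([]), np.array([], dtype=bool)))
        event_time = np.inf
        if not prevalent and sig.any():
            first_sig = pd.Timestamp(dates[sig][0])
            t = (first_sig - ecg_date).days / 365.25
            if t <= 0:
                logger.warning(
                    "data inconsistency: significant %s echo on/before ECG %s "
                    "but baseline grade %r; treating as prevalent",
                    valve, row.ecg_id, baseline_grade)
                prevalent = True
            else:
                event_time = t
        censor_time = max((pd.Timestamp(dates[-1]) - ecg_date).days / 365.25, 0.0) \
            if len(dates) else 0.0

        if prevalent:
            y[0] = 1.0
            labels.append(DiscreteSurvivalLabel(
                ecg_id=str(row.ecg_id), patient_id=str(row.patient_id),
                valve=valve, interval_edges=edges, y=y, mask=mask,
                prevalent=True, event=True, time=0.0, ecg_date=ecg_date))
            continue

        if np.isfinite(event_time):
            k = int(np.searchsorted(edges, event_time, side="left")) - 1
            k = min(max(k, 0), k_total - 1)
            y[k] = 1.0
            mask[: k + 1] = True
            prevalent_now = k == 0  # event inside the baseline window
            labels.append(DiscreteSurvivalLabel(
                ecg_id=str(row.ecg_id), patient_id=str(row.patient_id),
                valve=valve, interval_edges=edges, y=y, mask=mask,
                prevalent=prevalent_now, event=True, time=float(event_time),
                ecg_date=ecg_date))
        else:
            for k in range(1, k_total):
                if edges[k + 1] <= censor_time:
                    mask[k] = True
            labels.append(DiscreteSurvivalLabel(
                ecg_id=str(row.ecg_id), patient_id=str(row.patient_id),
                valve=valve, interval_edges=edges, y=y, mask=mask,
                prevalent=False, event=False, time=float(censor_time),
                ecg_date=ecg_date))
    return labels


def labels_to_frame(labels: list[DiscreteSurvivalLabel]) -> pd.DataFrame:
    """Tidy view of labels (one row per pair) for evaluation joins."""
    return pd.DataFrame([{
        "ecg_id": lab.ecg_id, "patient_id": lab.patient_id, "valve": lab.valve,
        "ecg_date": lab.ecg_date, "prevalent": lab.prevalent,
        "event": lab.event, "time": lab.time,
    } for lab in labels])


def apply_exclusions(patients: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Remove device/valve-surgery flagged patients for evaluation only.

    Flagged patients stay in the training population but are excluded from
    model evaluation.
    """
    if mode not in ("training", "evaluation"):
        raise ValueError("mode must be 'training' or 'evaluation'")
    if mode == "training" or "exclusion_flag" not in patients.columns:
        return patients.copy()
    return patients[~patients["exclusion_flag"].astype(bool)].copy()


def filter_minimum_age(patients: pd.DataFrame,
                       min_age: float = MIN_AGE_YEARS) -> pd.DataFrame:
    """Drop patients below the adult-assessment age."""
    return patients[patients["age"] >= min_age].copy()


@dataclass
class CohortSplit:
    """Patient-level train/tune/test assignment (disjoint and exhaustive)."""

    assignment: dict[str, str]

    def ids(self, group: str) -> list[str]:
        return [pid for pid, g in self.assignment.items() if g == group]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"patient_id": list(self.assignment),
                             "split": list(self.assignment.values())})

    def group_of(self, patient_id: str) -> str:
        return self.assignment[patient_id]


def split_cohort(patient_ids, ratios: tuple[float, float, float] = (0.5, 0.1, 0.4),
                 seed: int = 0) -> CohortSplit:
    """Randomly split patients into train/tune/test at the given ratios.

    The split is at patient level (never per ECG) and deterministic under
    ``seed``. Ratios must sum to 1.
    """
    ratios = tuple(float(r) for r in ratios)
    if any(r < 0 for r in ratios) or abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must be nonnegative and sum to 1")
    ids = sorted(dict.fromkeys(str(p) for p in patient_ids))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n = len(ids)
    n_train = int(np.floor(n * ratios[0]))
    n_tune = int(np.floor(n * (ratios[0] + ratios[1]))) - n_train
    assignment: dict[str, str] = {}
    for rank, idx in enumerate(perm):
        group = "train" if rank < n_train else (
            "tune" if rank < n_train + n_tune else "test")
        assignment[ids[idx]] = group
    return CohortSplit(assignment=assignment)


def select_evaluation_ecgs(labelled: pd.DataFrame, mode: str,
                           blanking_days: int = BLANKING_DAYS) -> pd.DataFrame:
    """Reduce a labelled pair table to the evaluation set.

    Keeps the earliest ECG per patient. In ``prediction`` mode, patients
    with prevalent disease for the valve under test are removed, and
    follow-up shorter than the blanking window is dropped (events inside the
    blanking window are already encoded as prevalent by the label builder
    when the first interval spans the window). ``diagnosis`` mode keeps
    everyone and exposes ``prevalent`` as the binary label.
    """
    if mode not in ("diagnosis", "prediction"):
        raise ValueError("mode must be 'diagnosis' or 'prediction'")
    df = labelled.sort_values(["patient_id", "ecg_date", "ecg_id"],
                              kind="mergesort")
    first = df.groupby("patient_id", as_index=False, sort=True).first()
    if mode == "diagnosis":
        return first.reset_index(drop=True)
    out = first[~first["prevalent"].astype(bool)]
    blank_years = blanking_days / 365.25
    # events inside the blanking window are prevalent by construction; this
    # also removes subjects with no follow-up beyond the window
    out = out[out["time"] > blank_years]
    return out.reset_index(drop=True)
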