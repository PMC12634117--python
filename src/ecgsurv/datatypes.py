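"""Core record types shared across the package.

Grades follow the four-level echocardiographic regurgitation scale
``none < mild < moderate < severe``; "significant" disease means moderate
or severe throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Ordered regurgitation grades (index = severity rank).
GRADES: tuple[str, ...] = ("none", "mild", "moderate", "severe")

#: Valves modelled: mitral (mr), aortic (ar), tricuspid (tr) regurgitation.
VALVES: tuple[str, ...] = ("mr", "ar", "tr")

#: Conventional 12-lead names in standard order.
LEAD_NAMES: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

#: Optional chamber-measurement columns carried on echo reports.
MEASUREMENT_COLUMNS: tuple[str, ...] = (
    "la_volume", "la_dimension", "lvedd", "aortic_sinus_diameter",
    "ascending_aorta_diameter", "rv_diameter", "lvef",
)


def grade_rank(grade: str) -> int:
    """Severity rank of a grade (0=none .. 3=severe)."""
    try:
        return GRADES.index(grade)
    except ValueError:
        raise ValueError(f"unknown regurgitation grade: {grade!r}") from None


def is_significant(grade: str) -> bool:
    """True for moderate or severe regurgitation."""
    return grade_rank(grade) >= 2


@dataclass
class EcgSignal:
    """A multi-lead ECG waveform in millivolts.

    ``samples`` has shape (n_leads, n_samples); all leads share one
    sampling rate ``fs``.
    """

    patient_id: str
    ecg_id: str
    acquisition_date: pd.Timestamp
    fs: float
    leads: tuple[str, ...]
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.leads):
            raise ValueError(
                "samples must be a (n_leads, n_samples) matrix matching `leads`"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EchoAssessment:
    """One transthoracic echo report: per-valve grades plus optional measurements."""

    patient_id: str
    exam_date: pd.Timestamp
    grades: dict[str, str]  # valve -> grade
    measurements: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for valve, grade in self.grades.items():
            if valve not in VALVES:
                raise ValueError(f"unknown valve: {valve!r}")
            grade_rank(grade)  # validates

    def significant(self, valve: str) -> bool:
        return is_significant(self.grades[valve])


@dataclass
class MedianBeat:
    """Representative beat per lead: per-sample median across aligned beats.

    ``samples`` has shape (n_leads, window_samples) and is R-peak centred at
    ``r_index``.
    """

    ecg_id: str
    fs: float
    window_ms: float
    beats_used: int
    r_index: int
    leads: tuple[str, ...]
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.beats_used < 1:
            raise ValueError("a median beat requires at least one beat")
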