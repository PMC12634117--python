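"""Synthetic linked ECG-echocardiogram cohorts with known risk structure.

The generator produces, per patient, a latent log-hazard built from ECG
morphology (standardized QRS width and P-wave amplitude) plus a frailty
term; per-valve times to significant (moderate/severe) regurgitation drawn
from the implied exponential hazard; a schedule of echo exams whose grades
switch from none/mild to moderate at the event time (severe two years
later); and parametric 12-lead waveforms (Gaussian P/Q/R/S/T bumps) whose
morphology degrades as disease approaches and after it is established:
broader QRS, smaller P waves, higher QRS voltage and T-wave inversion.

Every stochastic choice derives from ``SimulationConfig.seed``, so the same
config reproduces the cohort bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GRADES, LEAD_NAMES, VALVES, EchoAssessment, EcgSignal

#: All dates are realized as day offsets from this epoch.
EPOCH = pd.Timestamp("2015-01-01")

# Stylized projections of the P, QRS and T dipole components onto the 12
# conventional leads (unitless gains applied to the lead-II reference
# amplitudes). Chosen to give plausible polarity patterns (aVR negative,
# R-wave progression across V1-V6), not to be physiological.
_F_P = np.array([0.40, 1.00, 0.60, -0.70, 0.15, 0.80,
                 0.35, 0.30, 0.30, 0.35, 0.40, 0.45])
_F_QRS = np.array([0.55, 1.00, 0.45, -0.75, 0.25, 0.70,
                   -0.50, -0.20, 0.40, 0.90, 1.05, 0.85])
_F_T = np.array([0.50, 1.00, 0.50, -0.75, 0.20, 0.75,
                 0.25, 0.60, 0.80, 0.90, 0.80, 0.60])


def _per_valve(value, name: str) -> dict[str, float]:
    """Broadcast a scalar to a per-valve dict; validate a dict."""
    if isinstance(value, dict):
        out = {v: float(value[v]) for v in VALVES if v in value}
        if set(out) != set(VALVES):
            raise ValueError(f"{name} must cover all valves {VALVES}")
        return out
    return {v: float(value) for v in VALVES}


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults emulate a hospital echo population at desk scale: per-valve
    baseline prevalence of significant regurgitation of 3-6%, annual
    progression hazards scaled up (relative to the sparse real-world rates)
    so that a cohort of ~1000 patients carries enough events for stable
    rank statistics, roughly annual echo surveillance with 20% jitter, and
    exponential loss to follow-up.
    """

    n_patients: int = 200
    n_leads: int = 12
    duration_s: float = 10.0
    fs: float = 500.0
    #: Probability of significant disease already present at entry, per valve.
    baseline_prevalence: dict[str, float] | float = field(
        default_factory=lambda: {"mr": 0.055, "ar": 0.030, "tr": 0.050})
    #: Baseline hazard of progression to significant disease, per valve, 1/year.
    annual_hazard_base: dict[str, float] | float = field(
        default_factory=lambda: {"mr": 0.08, "ar": 0.05, "tr": 0.08})
    #: Morphology feature -> log hazard ratio per SD of the feature's latent score.
    risk_effect_sizes: dict[str, float] = field(
        default_factory=lambda: {"qrs_width_ms": 0.5, "p_amplitude_mV": -0.5})
    #: SD of the patient-level log-hazard frailty (unexplained risk).
    frailty_sd: float = 0.3
    follow_up_years: float = 6.0
    echo_interval_days: float = 365.0
    #: Rate of exponential loss to follow-up, 1/year (0 = administrative only).
    censor_rate: float = 0.12
    #: Fraction of patients flagged for valve surgery / prosthesis / device.
    exclusion_fraction: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        self.baseline_prevalence = _per_valve(self.baseline_prevalence,
                                              "baseline_prevalence")
        self.annual_hazard_base = _per_valve(self.annual_hazard_base,
                                             "annual_hazard_base")
        self.validate()

    def validate(self) -> None:
        if self.n_leads < 1:
            raise ValueError("n_leads must be >= 1")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        for v, p in self.baseline_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"baseline_prevalence[{v}] must be in [0, 1]")
        for v, h in self.annual_hazard_base.items():
            if h < 0:
                raise ValueError(f"annual_hazard_base[{v}] must be >= 0")
        if self.frailty_sd < 0 or self.censor_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.follow_up_years <= 0 or self.echo_interval_days <= 0:
            raise ValueError("follow-up and echo interval must be positive")
        if not 0.0 <= self.exclusion_fraction <= 1.0:
            raise ValueError("exclusion_fraction must be in [0, 1]")

    def lead_names(self) -> tuple[str, ...]:
        if self.n_leads <= 12:
            return LEAD_NAMES[: self.n_leads]
        return tuple(f"L{i}" for i in range(self.n_leads))


@dataclass
class LatentPatientState:
    """Ground-truth state of one simulated patient."""

    patient_id: str
    age: float
    sex: str  # "male" | "female"
    frailty: float
    #: Baseline (disease-free) morphology parameters.
    morphology: dict[str, float]
    #: True time to significant disease per valve, years (0 if prevalent, inf never).
    true_event_time: dict[str, float]
    censor_time: float
    prevalent: dict[str, bool]
    #: Total log-hazard offset (morphology effects + frailty).
    log_hazard: float
    entry_date: pd.Timestamp
    exclusion_flag: bool
    mild_at_baseline: dict[str, bool]


# --------------------------------------------------------------------------
# waveform synthesis


def _gauss_train(t: np.ndarray, centers: np.ndarray, sigma: float) -> np.ndarray:
    """Sum of unit Gaussians at `centers` evaluated on time grid `t`."""
    if len(centers) == 0:
        return np.zeros_like(t)
    return np.exp(-((t[None, :] - centers[:, None]) ** 2) / (2.0 * sigma * sigma)).sum(axis=0)


def _lead_factors(n_leads: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if n_leads <= 12:
        return _F_P[:n_leads], _F_QRS[:n_leads], _F_T[:n_leads]
    reps = math.ceil(n_leads / 12)
    return (np.tile(_F_P, reps)[:n_leads], np.tile(_F_QRS, reps)[:n_leads],
            np.tile(_F_T, reps)[:n_leads])


def synthesize_waveform(
    rng: np.random.Generator,
    fs: float,
    duration_s: float,
    n_leads: int,
    qrs_width_ms: float,
    p_amplitude_mV: float,
    qrs_amplitude_mV: float = 1.1,
    t_amplitude_mV: float = 0.30,
    heart_rate_bpm: float | None = None,
    noise_sd: float = 0.02,
    baseline_wander: bool = True,
) -> np.ndarray:
    """Render one parametric multi-lead ECG, in mV, shape (n_leads, n_samples).

    Each beat is a sum of Gaussian bumps (P, Q, R, S, T). Q/R/S widths scale
    with ``qrs_width_ms``; white noise (sigma ``noise_sd`` mV) and a sub-0.5 Hz
    sinusoidal baseline wander are added so the preprocessing filters have
    something to remove.
    """
    n = int(round(fs * duration_s))
    t = np.arange(n) / fs
    if heart_rate_bpm is None:
        heart_rate_bpm = rng.uniform(50.0, 100.0)
    rr = 60.0 / heart_rate_bpm
    n_beats = int(duration_s / rr) + 3
    r_times = rng.uniform(0.15, 0.15 + rr) + np.arange(n_beats) * rr
    r_times = r_times + rng.normal(0.0, 0.008, size=n_beats)  # beat jitter
    r_times = r_times[(r_times > -0.5) & (r_times < duration_s + 0.5)]

    w = qrs_width_ms / 1000.0
    p_wave = _gauss_train(t, r_times - 0.17, 0.025)
    qrs = (
        _gauss_train(t, r_times, 0.16 * w)
        - 0.16 * _gauss_train(t, r_times - 0.35 * w, 0.11 * w)
        - 0.28 * _gauss_train(t, r_times + 0.35 * w, 0.11 * w)
    )
    t_wave = _gauss_train(t, r_times + 0.25 + w, 0.06)

    f_p, f_qrs, f_t = _lead_factors(n_leads)
    x = (
        np.outer(f_p, p_wave) * p_amplitude_mV
        + np.outer(f_qrs, qrs) * qrs_amplitude_mV
        + np.outer(f_t, t_wave) * t_amplitude_mV
    )
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=x.shape)
    if baseline_wander:
        freq = rng.uniform(0.05, 0.45, size=n_leads)
        amp = rng.uniform(0.02, 0.08, size=n_leads)
        phase = rng.uniform(0.0, 2 * np.pi, size=n_leads)
        x = x + amp[:, None] * np.sin(2 * np.pi * freq[:, None] * t[None, :] + phase[:, None])
    return x


# --------------------------------------------------------------------------
# latent simulation


#: Years before the qualifying echo over which morphology degrades.
RAMP_YEARS = 2.5


def _disease_ramp(t: float, event_time: float) -> float:
    """Disease-state factor in [0, 1] for one valve at time t (years).

    0 until ``RAMP_YEARS`` before the event, rising linearly to 0.8 at the
    event (grade turns moderate), and to 1.0 two years after (grade turns
    severe). The pre-event ramp encodes subclinical remodelling: ECGs taken
    closer to the event look progressively more diseased.
    """
    if not np.isfinite(event_time):
        return 0.0
    if t < event_time - RAMP_YEARS:
        return 0.0
    if t < event_time:
        return 0.8 * (t - (event_time - RAMP_YEARS)) / RAMP_YEARS
    if t < event_time + 2.0:
        return 0.8 + 0.2 * (t - event_time) / 2.0
    return 1.0


def _morphology_at(base: dict[str, float], d: float) -> dict[str, float]:
    """Physical morphology parameters at disease factor ``d``."""
    return {
        "qrs_width_ms": float(np.clip(base["qrs_width_ms"] + 30.0 * d, 55.0, 200.0)),
        "p_amplitude_mV": float(max(base["p_amplitude_mV"] * (1.0 - 0.55 * d), 0.0)),
        "qrs_amplitude_mV": float(max(base["qrs_amplitude_mV"] * (1.0 + 0.25 * d), 0.2)),
        "t_amplitude_mV": float(0.30 * base["t_polarity"] * (1.0 - 1.7 * d)),
    }


_FEATURE_Z = {"qrs_width_ms": "qrs_z", "p_amplitude_mV": "p_z",
              "qrs_amplitude_mV": "amp_z", "t_polarity": None}


def simulate_tables(config: SimulationConfig):
    """Simulate the latent cohort without rendering waveforms.

    Returns ``(patients, ecg_meta, echos)`` where ``ecg_meta`` is a DataFrame
    holding, per ECG, its date and the morphology parameters needed by
    :func:`render_ecg`.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    betas = dict(config.risk_effect_sizes)
    unknown = set(betas) - set(_FEATURE_Z)
    if unknown:
        raise ValueError(f"unknown risk_effect_sizes features: {sorted(unknown)}")

    patients: list[LatentPatientState] = []
    ecg_rows: list[dict] = []
    echos: list[EchoAssessment] = []
    ecg_counter = 0
    interval_y = config.echo_interval_days / 365.25

    for i in range(config.n_patients):
        pid = f"P{i:05d}"
        age = float(np.clip(rng.normal(62.0, 13.0), 18.0, 95.0))
        sex = "male" if rng.random() < 0.5 else "female"
        z = {"qrs_z": rng.normal(), "p_z": rng.normal(), "amp_z": rng.normal()}
        frailty = rng.normal(0.0, config.frailty_sd) if config.frailty_sd > 0 else 0.0
        eta = frailty
        for feat, beta in betas.items():
            zkey = _FEATURE_Z[feat]
            if zkey is not None:
                eta += beta * z[zkey]

        base_morph = {
            "qrs_width_ms": float(np.clip(96.0 + 11.0 * z["qrs_z"], 55.0, 170.0)),
            "p_amplitude_mV": float(max(0.15 * (1.0 + 0.30 * z["p_z"]), 0.01)),
            "qrs_amplitude_mV": float(max(1.1 * (1.0 + 0.22 * z["amp_z"]), 0.2)),
            "t_polarity": 1.0,
        }

        prevalent: dict[str, bool] = {}
        event_time: dict[str, float] = {}
        mild0: dict[str, bool] = {}
        for v in VALVES:
            prevalent[v] = bool(rng.random() < config.baseline_prevalence[v])
            if prevalent[v]:
                event_time[v] = 0.0
            else:
                rate = config.annual_hazard_base[v] * math.exp(eta)
                event_time[v] = float(rng.exponential(1.0 / rate)) if rate > 0 else math.inf
            mild0[v] = bool(rng.random() < 0.35)

        if config.censor_rate > 0:
            censor = float(min(rng.exponential(1.0 / config.censor_rate),
                               config.follow_up_years))
        else:
            censor = float(config.follow_up_years)
        censor = max(censor, 1e-6)
        entry = EPOCH + pd.Timedelta(days=int(rng.integers(0, 731)))
        excl = bool(rng.random() < config.exclusion_fraction)
        # event time discretized to whole days: the day from which an echo
        # exam records significant disease (grades live on exam dates)
        event_day = {v: (math.ceil(event_time[v] * 365.25)
                         if np.isfinite(event_time[v]) else math.inf)
                     for v in VALVES}

        patients.append(LatentPatientState(
            patient_id=pid, age=age, sex=sex, frailty=frailty,
            morphology=base_morph, true_event_time=event_time,
            censor_time=censor, prevalent=prevalent, log_hazard=float(eta),
            entry_date=entry, exclusion_flag=excl, mild_at_baseline=mild0,
        ))

        # echo schedule: baseline exam then roughly regular surveillance
        echo_times = [0.0]
        t_next = interval_y * float(rng.uniform(0.8, 1.2))
        while t_next <= censor:
            echo_times.append(t_next)
            t_next += interval_y * float(rng.uniform(0.8, 1.2))

        for et in echo_times:
            exam_day = int(round(et * 365.25))
            d_all = max(_disease_ramp(et, event_time[v]) for v in VALVES)
            eta_meas = eta
            grades = {}
            d_v = {}
            for v in VALVES:
                d_v[v] = _disease_ramp(et, event_time[v])
                if exam_day >= event_day[v] + 730:
                    grades[v] = "severe"
                elif exam_day >= event_day[v]:
                    grades[v] = "moderate"
                else:
                    grades[v] = "mild" if mild0[v] else "none"
            meas = {
                "la_volume": 55.0 + 30.0 * d_v["mr"] + 8.0 * d_all + 2.0 * eta_meas + rng.normal(0, 8.0),
                "la_dimension": 36.0 + 6.0 * d_v["mr"] + 3.0 * d_v["tr"] + rng.normal(0, 3.0),
                "lvedd": 47.0 + 6.0 * d_v["ar"] + 4.0 * d_v["mr"] + 1.5 * eta_meas + rng.normal(0, 4.0),
                "aortic_sinus_diameter": 32.0 + 5.0 * d_v["ar"] + rng.normal(0, 3.0),
                "ascending_aorta_diameter": 33.0 + 5.0 * d_v["ar"] + rng.normal(0, 3.0),
                "rv_diameter": 35.0 + 9.0 * d_v["tr"] + 1.5 * eta_meas + rng.normal(0, 4.0),
                "lvef": float(np.clip(64.0 - 9.0 * d_all + rng.normal(0, 6.0), 15.0, 78.0)),
            }
            # sporadic missingness to exercise complete-case handling
            for k in meas:
                if rng.random() < 0.05:
                    meas[k] = math.nan
            echos.append(EchoAssessment(
                patient_id=pid,
                exam_date=entry + pd.Timedelta(days=int(round(et * 365.25))),
                grades=grades, measurements=meas,
            ))

            # one ECG near each echo, with a jittered offset
            off_days = int(rng.integers(-15, 16))
            ecg_t = max(et + off_days / 365.25, 0.0)
            d_ecg = max(_disease_ramp(ecg_t, event_time[v]) for v in VALVES)
            morph = _morphology_at(base_morph, d_ecg)
            ecg_rows.append({
                "ecg_id": f"E{ecg_counter:06d}",
                "patient_id": pid,
                "ecg_index": ecg_counter,
                "time_years": ecg_t,
                "date": entry + pd.Timedelta(days=int(round(ecg_t * 365.25))),
                "disease_factor": d_ecg,
                **morph,
            })
            ecg_counter += 1

    ecg_meta = pd.DataFrame(
        ecg_rows,
        columns=["ecg_id", "patient_id", "ecg_index", "time_years", "date",
                 "disease_factor", "qrs_width_ms", "p_amplitude_mV",
                 "qrs_amplitude_mV", "t_amplitude_mV"],
    )
    return patients, ecg_meta, echos


def render_ecg(meta_row, config: SimulationConfig) -> EcgSignal:
    """Render the waveform for one row of the ``ecg_meta`` table.

    The per-ECG random stream is derived from (seed, ecg_index), so any ECG
    can be rendered in isolation and still match a full-cohort render.
    """
    idx = int(meta_row["ecg_index"])
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1, idx)))
    samples = synthesize_waveform(
        rng, config.fs, config.duration_s, config.n_leads,
        qrs_width_ms=float(meta_row["qrs_width_ms"]),
        p_amplitude_mV=float(meta_row["p_amplitude_mV"]),
        qrs_amplitude_mV=float(meta_row["qrs_amplitude_mV"]),
        t_amplitude_mV=float(meta_row["t_amplitude_mV"]),
    )
    return EcgSignal(
        patient_id=str(meta_row["patient_id"]), ecg_id=str(meta_row["ecg_id"]),
        acquisition_date=pd.Timestamp(meta_row["date"]), fs=config.fs,
        leads=config.lead_names(), samples=samples,
    )


def simulate_cohort(config: SimulationConfig):
    """Simulate a full cohort: ``(patients, ecgs, echos)``.

    ``ecgs`` holds rendered :class:`EcgSignal` waveforms; for large cohorts
    prefer :func:`simulate_tables` + :func:`render_ecg` to bound memory.
    """
    patients, ecg_meta, echos = simulate_tables(config)
    ecgs = [render_ecg(row, config) for _, row in ecg_meta.iterrows()]
    return patients, ecgs, echos


def ground_truth_outcomes(patients: list[LatentPatientState],
                          echos: list[EchoAssessment]) -> pd.DataFrame:
    """Observable ground truth per patient and valve.

    Derived from the latent event times and the echo schedule alone (grades
    are never consulted): the detected event date is the first exam on or
    after the true event time. One row per patient with, per valve,
    ``{valve}_prevalent`` (significant at the baseline exam) and
    ``{valve}_event_date``, plus the last exam date (censoring).
    """
    exam_dates: dict[str, list[pd.Timestamp]] = {}
    for e in echos:
        exam_dates.setdefault(e.patient_id, []).append(e.exam_date)
    rows = []
    for p in patients:
        dates = sorted(exam_dates.get(p.patient_id, []))
        if not dates:
            continue
        row: dict = {"patient_id": p.patient_id, "entry_date": p.entry_date,
                     "baseline_date": dates[0], "last_echo_date": dates[-1]}
        for v in VALVES:
            tev = p.true_event_time[v]
            event_day = math.ceil(tev * 365.25) if np.isfinite(tev) else math.inf
            event_date = pd.NaT
            if np.isfinite(event_day):
                for dte in dates:
                    if (dte - p.entry_date).days >= event_day:
                        event_date = dte
                        break
            row[f"{v}_prevalent"] = bool(p.prevalent[v])
            row[f"{v}_event_day"] = event_day
            row[f"{v}_event_date"] = event_date
        rows.append(row)
    return pd.DataFrame(rows)
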