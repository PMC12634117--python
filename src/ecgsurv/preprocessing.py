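"""ECG preprocessing chain and median-beat extraction.

The preprocessing pipeline is: zero-phase 4th-order Butterworth bandpass
(0.5-100 Hz) -> zero-phase IIR notch at the mains frequency (60 Hz default,
quality factor 30) -> polyphase rational resampling to 400 Hz -> length
normalization to 4096 samples (tail zero-padding if short, centre crop if
long). A 10-s recording therefore becomes exactly 4000 resampled samples
padded to 4096. Poor-quality recordings are not rejected.

R peaks are found with a Pan-Tompkins-style detector (bandpass ->
derivative -> squaring -> moving-window integration -> thresholding) on
lead II, falling back to the lead with the most QRS-band energy; beats are
aligned by cross-correlation before the per-sample median.
"""

from __future__ import annotations

import logging
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .datatypes import EcgSignal, MedianBeat

logger = logging.getLogger(__name__)

TARGET_FS = 400.0
TARGET_LEN = 4096
BAND = (0.5, 100.0)
NOTCH_HZ = 60.0
NOTCH_Q = 30.0


def _fit_length(x: np.ndarray, target_len: int) -> np.ndarray:
    """Tail zero-pad or centre-crop the last axis to ``target_len``."""
    n = x.shape[-1]
    if n == target_len:
        return x
    if n < target_len:
        pad = [(0, 0)] * (x.ndim - 1) + [(0, target_len - n)]
        return np.pad(x, pad)
    start = (n - target_len) // 2
    return x[..., start:start + target_len]


def preprocess_array(
    x: np.ndarray,
    fs: float,
    target_fs: float = TARGET_FS,
    target_len: int = TARGET_LEN,
    band: tuple[float, float] = BAND,
    notch_hz: float | None = NOTCH_HZ,
    notch_q: float = NOTCH_Q,
) -> np.ndarray:
    """Filter, resample and length-normalize waveforms along the last axis.

    Accepts any leading shape (leads, or batch x leads). NaNs are replaced
    by 0 with a warning. All filtering is forward-backward (zero phase).
    """
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] < fs:  # need at least 1 s of signal
        raise ValueError("signal shorter than 1 s cannot be preprocessed")
    if np.isnan(x).any():
        logger.warning("NaN samples found; replaced with 0")
        x = np.nan_to_num(x, nan=0.0)

    low, high = band
    nyq = fs / 2.0
    if high >= nyq:
        high = 0.45 * fs
        logger.warning("bandpass high cut reduced to %.1f Hz (fs=%g)", high, fs)
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, x, axis=-1)
    if notch_hz is not None and notch_hz < nyq:
        b, a = sps.iirnotch(notch_hz, notch_q, fs=fs)
        x = sps.filtfilt(b, a, x, axis=-1)

    if target_fs != fs:
        frac = Fraction(target_fs / fs).limit_denominator(1000)
        x = sps.resample_poly(x, frac.numerator, frac.denominator, axis=-1)
    return _fit_length(x, target_len)


def preprocess(
    ecg: EcgSignal,
    target_fs: float = TARGET_FS,
    target_len: int = TARGET_LEN,
    band: tuple[float, float] = BAND,
    notch_hz: float | None = NOTCH_HZ,
) -> EcgSignal:
    """Preprocess one ECG record; returns a new :class:`EcgSignal`."""
    samples = preprocess_array(ecg.samples, ecg.fs, target_fs=target_fs,
                               target_len=target_len, band=band, notch_hz=notch_hz)
    return EcgSignal(patient_id=ecg.patient_id, ecg_id=ecg.ecg_id,
                     acquisition_date=ecg.acquisition_date, fs=target_fs,
                     leads=ecg.leads, samples=samples)


# --------------------------------------------------------------------------
# R-peak detection


def _qrs_energy(samples: np.ndarray, fs: float) -> np.ndarray:
    """Per-lead RMS power in the 10-25 Hz QRS band."""
    sos = sps.butter(2, [10.0, min(25.0, 0.45 * fs)], btype="bandpass",
                     fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, samples, axis=-1)
    return np.sqrt((filtered ** 2).mean(axis=-1))


def _detect_on_lead(x: np.ndarray, fs: float) -> np.ndarray:
    """Pan-Tompkins-style detection on a single lead; returns R sample indices."""
    sos = sps.butter(2, [5.0, min(15.0, 0.45 * fs)], btype="bandpass",
                     fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    deriv = np.gradient(bp)
    sq = deriv ** 2
    win = max(int(round(0.150 * fs)), 1)
    integ = np.convolve(sq, np.ones(win) / win, mode="same")
    distance = max(int(round(0.25 * fs)), 1)
    candidates, props = sps.find_peaks(integ, distance=distance, height=0.0)
    if len(candidates) == 0:
        return np.array([], dtype=int)
    heights = props["peak_heights"]
    # Threshold from the median of the top candidates (at least the beat
    # count a 40 bpm rhythm would give): robust to one large artefact. The
    # floor relative to the maximum rejects filter-ringing ghost peaks.
    k = max(3, int(round(len(x) / fs / 1.5)))
    top = np.sort(heights)[::-1][:k]
    height = max(0.4 * np.median(top), 0.03 * heights.max())
    peaks = candidates[heights >= height]
    # refine each candidate to the local extremum of the bandpassed lead
    half = int(round(0.06 * fs))
    refined = []
    for p in peaks:
        lo, hi = max(p - half, 0), min(p + half + 1, len(x))
        refined.append(lo + int(np.argmax(np.abs(bp[lo:hi]))))
    refined = np.unique(refined)
    if len(refined) > 1:  # merge peaks closer than 200 ms
        keep = [refined[0]]
        for r in refined[1:]:
            if r - keep[-1] >= 0.2 * fs:
                keep.append(r)
        refined = np.array(keep)
    return refined


def detect_r_peaks(ecg: EcgSignal) -> tuple[np.ndarray, int]:
    """Detect R peaks; returns ``(sample_indices, detection_lead_index)``.

    Tries lead II first; if fewer than 3 beats are found there (or lead II
    is absent) the lead with maximal QRS-band energy is used.
    """
    leads = [str(name) for name in ecg.leads]
    order: list[int] = []
    if "II" in leads:
        order.append(leads.index("II"))
    order.append(int(np.argmax(_qrs_energy(ecg.samples, ecg.fs))))
    best: tuple[np.ndarray, int] | None = None
    for li in dict.fromkeys(order):
        peaks = _detect_on_lead(ecg.samples[li], ecg.fs)
        if len(peaks) >= 3:
            return peaks, li
        if best is None or len(peaks) > len(best[0]):
            best = (peaks, li)
    assert best is not None
    return best


# --------------------------------------------------------------------------
# median beats


def extract_median_beat(ecg: EcgSignal, window_ms: float = 600.0,
                        pre_ms: float = 200.0) -> MedianBeat:
    """Per-sample median across R-aligned beats, per lead.

    The window spans ``pre_ms`` before to ``window_ms - pre_ms`` after the R
    peak. Beats are aligned to the first full beat by cross-correlation on
    the detection lead within +-50 ms. Fewer than 3 usable beats is an error.
    """
    fs = ecg.fs
    win = int(round(window_ms / 1000.0 * fs))
    pre = int(round(pre_ms / 1000.0 * fs))
    peaks, det_lead = detect_r_peaks(ecg)
    n = ecg.samples.shape[1]
    peaks = peaks[(peaks - pre >= 0) & (peaks - pre + win <= n)]
    if len(peaks) < 3:
        raise ValueError("insufficient beats: need >= 3 detectable beats "
                         f"with a full {window_ms:g} ms window, got {len(peaks)}")

    max_lag = int(round(0.05 * fs))
    ref = ecg.samples[det_lead, peaks[0] - pre:peaks[0] - pre + win]
    segments = []
    for p in peaks:
        best_lag, best_score = 0, -np.inf
        for lag in range(-max_lag, max_lag + 1):
            lo = p - pre + lag
            if lo < 0 or lo + win > n:
                continue
            seg = ecg.samples[det_lead, lo:lo + win]
            score = float(seg @ ref)
            if score > best_score:
                best_score, best_lag = score, lag
        lo = p - pre + best_lag
        segments.append(ecg.samples[:, lo:lo + win])
    stack = np.stack(segments)  # (n_beats, n_leads, win)
    median = np.median(stack, axis=0)
    return MedianBeat(ecg_id=ecg.ecg_id, fs=fs, window_ms=window_ms,
                      beats_used=len(peaks), r_index=pre,
                      leads=ecg.leads, samples=median)
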