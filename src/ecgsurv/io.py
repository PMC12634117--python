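"""Cohort file I/O.

Waveforms are stored as WFDB records (``<id>.hea`` + ``<id>.dat``, signal
format 16: interleaved little-endian 16-bit integers, gain-scaled mV).
The writer/reader here covers exactly that single-segment, single-.dat
layout. Tabular data travel as CSV with ISO-8601 dates; preprocessed
tensors and median beats as HDF5 (one float32 dataset per ECG).
"""

from __future__ import annotations

import os
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .datatypes import MEASUREMENT_COLUMNS, VALVES, EchoAssessment, EcgSignal

#: ADC units per millivolt used when writing WFDB records (~1 uV resolution).
WFDB_GAIN = 1000.0
_INT16_MIN, _INT16_MAX = -32768, 32767


# --------------------------------------------------------------------------
# WFDB format-16 records


def write_wfdb(record_path: str | Path, samples_mv: np.ndarray, fs: float,
               leads: tuple[str, ...] | list[str]) -> None:
    """Write one WFDB record (``record_path`` without extension)."""
    record_path = Path(record_path)
    record_path.parent.mkdir(parents=True, exist_ok=True)
    name = record_path.name
    x = np.asarray(samples_mv, dtype=np.float64)
    n_sig, n_samp = x.shape
    adc = np.clip(np.round(x * WFDB_GAIN), _INT16_MIN, _INT16_MAX).astype(np.int16)
    # frame-interleaved: sample 0 of every signal, then sample 1, ...
    adc.T.astype("<i2").tofile(record_path.with_suffix(".dat"))

    checksums = (adc.astype(np.int64).sum(axis=1) & 0xFFFF).astype(np.int64)
    checksums = np.where(checksums >= 32768, checksums - 65536, checksums)
    lines = [f"{name} {n_sig} {fs:g} {n_samp}"]
    for i in range(n_sig):
        init = int(adc[i, 0]) if n_samp else 0
        lines.append(
            f"{name}.dat 16 {WFDB_GAIN:g}(0)/mV 16 0 {init} {int(checksums[i])} 0 {leads[i]}"
        )
    record_path.with_suffix(".hea").write_text("\n".join(lines) + "\n")


def read_wfdb(record_path: str | Path) -> tuple[np.ndarray, float, tuple[str, ...]]:
    """Read a WFDB record written by :func:`write_wfdb`.

    Returns ``(samples_mv, fs, lead_names)``.
    """
    record_path = Path(record_path)
    hea = record_path.with_suffix(".hea").read_text().strip().splitlines()
    head = hea[0].split()
    n_sig, fs, n_samp = int(head[1]), float(head[2]), int(head[3])
    leads, gains = [], []
    for line in hea[1:1 + n_sig]:
        parts = line.split()
        if parts[1] != "16":
            raise ValueError(f"unsupported WFDB signal format: {parts[1]}")
        gain_field = parts[2].split("/")[0]
        gains.append(float(gain_field.split("(")[0]))
        leads.append(parts[-1])
    raw = np.fromfile(record_path.with_suffix(".dat"), dtype="<i2")
    if raw.size != n_sig * n_samp:
        raise ValueError(f"WFDB .dat length mismatch for {record_path}")
    adc = raw.reshape(n_samp, n_sig).T
    samples = adc.astype(np.float64) / np.asarray(gains)[:, None]
    return samples, fs, tuple(leads)


# --------------------------------------------------------------------------
# cohort directory layout

ECG_MANIFEST = "ecgs.csv"
ECHO_TABLE = "echos.csv"
PATIENT_TABLE = "patients.csv"

_ECG_COLUMNS = ["patient_id", "ecg_id", "date", "path"]
_PATIENT_COLUMNS = ["patient_id", "age", "sex", "exclusion_flag"]


def echos_to_frame(echos: list[EchoAssessment]) -> pd.DataFrame:
    rows = []
    for e in echos:
        row = {"patient_id": e.patient_id, "date": e.exam_date.date().isoformat()}
        for v in VALVES:
            row[f"{v}_grade"] = e.grades[v]
        for m in MEASUREMENT_COLUMNS:
            row[m] = e.measurements.get(m, np.nan)
        rows.append(row)
    cols = ["patient_id", "date"] + [f"{v}_grade" for v in VALVES] + list(MEASUREMENT_COLUMNS)
    return pd.DataFrame(rows, columns=cols)


def write_cohort(patients, ecgs: list[EcgSignal], echos: list[EchoAssessment],
                 out_dir: str | Path) -> dict[str, Path]:
    """Write a simulated cohort: WFDB records + CSV manifests.

    Accepts the triple returned by :func:`ecgsurv.simulate.simulate_cohort`.
    An empty cohort yields valid, header-only CSVs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ecg_dir = out_dir / "ecgs"

    manifest_rows = []
    for ecg in ecgs:
        rel = os.path.join("ecgs", ecg.ecg_id)
        write_wfdb(ecg_dir / ecg.ecg_id, ecg.samples, ecg.fs, ecg.leads)
        manifest_rows.append({
            "patient_id": ecg.patient_id, "ecg_id": ecg.ecg_id,
            "date": ecg.acquisition_date.date().isoformat(), "path": rel,
        })
    pd.DataFrame(manifest_rows, columns=_ECG_COLUMNS).to_csv(
        out_dir / ECG_MANIFEST, index=False)

    echos_to_frame(echos).to_csv(out_dir / ECHO_TABLE, index=False)

    pat_rows = [{
        "patient_id": p.patient_id, "age": round(p.age, 2), "sex": p.sex,
        "exclusion_flag": bool(p.exclusion_flag),
    } for p in patients]
    pd.DataFrame(pat_rows, columns=_PATIENT_COLUMNS).to_csv(
        out_dir / PATIENT_TABLE, index=False)

    return {"ecgs": out_dir / ECG_MANIFEST, "echos": out_dir / ECHO_TABLE,
            "patients": out_dir / PATIENT_TABLE, "ecg_dir": ecg_dir}


def read_cohort_tables(cohort_dir: str | Path):
    """Read the three cohort CSVs; returns ``(patients, ecgs, echos)`` frames.

    Dates are parsed to timestamps; grades stay as the four-level strings.
    """
    cohort_dir = Path(cohort_dir)
    patients = pd.read_csv(cohort_dir / PATIENT_TABLE)
    if "exclusion_flag" in patients.columns and len(patients):
        patients["exclusion_flag"] = patients["exclusion_flag"].astype(bool)
    ecgs = pd.read_csv(cohort_dir / ECG_MANIFEST, parse_dates=["date"])
    echos = pd.read_csv(cohort_dir / ECHO_TABLE, parse_dates=["date"])
    return patients, ecgs, echos


def load_manifest_ecg(cohort_dir: str | Path, row) -> EcgSignal:
    """Load one ECG referenced by a manifest row."""
    samples, fs, leads = read_wfdb(Path(cohort_dir) / row["path"])
    return EcgSignal(patient_id=str(row["patient_id"]), ecg_id=str(row["ecg_id"]),
                     acquisition_date=pd.Timestamp(row["date"]), fs=fs,
                     leads=leads, samples=samples)


# --------------------------------------------------------------------------
# HDF5 tensors


def save_tensors(path: str | Path, arrays: dict[str, np.ndarray],
                 fs: float, group: str = "ecgs") -> None:
    """Store float32 arrays (one dataset per ECG id) with the sampling rate."""
    with h5py.File(path, "w") as f:
        g = f.create_group(group)
        g.attrs["fs"] = fs
        for key, arr in arrays.items():
            g.create_dataset(key, data=np.asarray(arr, dtype=np.float32))


def load_tensors(path: str | Path, group: str = "ecgs"):
    """Inverse of :func:`save_tensors`: returns ``(dict, fs)``."""
    out: dict[str, np.ndarray] = {}
    with h5py.File(path, "r") as f:
        g = f[group]
        fs = float(g.attrs["fs"])
        for key in g:
            out[key] = g[key][()]
    return out, fs
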