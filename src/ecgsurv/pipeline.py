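"""End-to-end pipeline: simulate -> preprocess -> build cohort -> train ->
evaluate -> explain.

Two entry styles share the same code path:

* :func:`assemble_model_data` builds everything in memory from a
  :class:`~ecgsurv.simulate.SimulationConfig` (used by the test suite and
  the acceptance script);
* :func:`run_pipeline` runs the staged, on-disk version with per-stage
  manifests, driven by a :class:`RunConfig` (used by the CLI).

The ``tiny`` profile trains on inputs decimated to 100 Hz / 1024 samples
(the same power-of-2 padding convention as the full 400 Hz / 4096 input)
with the 2-block backbone; the ``default`` profile uses the full-resolution
input and 4-block backbone and is correspondingly slower.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (DEFAULT_EDGES, CohortSplit, apply_exclusions,
                     build_survival_labels, filter_minimum_age, labels_to_frame,
                     pair_ecg_echo, select_evaluation_ecgs, split_cohort)
from .datatypes import VALVES, EcgSignal
from .io import (echos_to_frame, load_manifest_ecg, load_tensors,
                 read_cohort_tables, save_tensors, write_cohort)
from .metrics import (auroc, bootstrap_ci, brier_at_horizon,
                      classification_threshold_metrics, continuous_nri,
                      harrell_c, km_curve)
from .model import (BackboneConfig, EcgRiskModel, SurvivalDataset, TrainConfig,
                    cumulative_risk, load_model, save_model, train_model)
from .preprocessing import extract_median_beat, preprocess_array
from .simulate import (SimulationConfig, ground_truth_outcomes, render_ecg,
                       simulate_tables)

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# in-memory assembly


@dataclass
class ModelData:
    """Preprocessed tensors plus the paired/labelled/split cohort tables."""

    x: np.ndarray                       # (n_ecgs, leads, input_len) float32
    ecg_ids: list[str]
    fs: float
    patients: pd.DataFrame              # patient_id, age, sex, exclusion_flag
    ecg_meta: pd.DataFrame
    echos: pd.DataFrame
    pairs: pd.DataFrame
    labelled: dict[str, pd.DataFrame]   # valve -> labelled pair frame
    labels: dict[str, list]             # valve -> DiscreteSurvivalLabel list
    split: CohortSplit
    interval_edges: np.ndarray
    ground_truth: pd.DataFrame

    _row: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._row = {e: i for i, e in enumerate(self.ecg_ids)}

    def tensor_for(self, ecg_ids) -> np.ndarray:
        return self.x[[self._row[e] for e in ecg_ids]]


def patients_frame(patients) -> pd.DataFrame:
    return pd.DataFrame([{
        "patient_id": p.patient_id, "age": p.age, "sex": p.sex,
        "exclusion_flag": p.exclusion_flag,
    } for p in patients])


def preprocess_cohort_tensors(ecg_meta: pd.DataFrame, sim_cfg: SimulationConfig,
                              target_fs: float, input_len: int,
                              batch: int = 64) -> np.ndarray:
    """Render and preprocess all simulated ECGs into one float32 tensor."""
    x = np.empty((len(ecg_meta), sim_cfg.n_leads, input_len), dtype=np.float32)
    rows = list(ecg_meta.itertuples(index=False))
    for i0 in range(0, len(rows), batch):
        chunk = np.stack([render_ecg(r._asdict(), sim_cfg).samples
                          for r in rows[i0:i0 + batch]])
        x[i0:i0 + len(chunk)] = preprocess_array(
            chunk, sim_cfg.fs, target_fs=target_fs, target_len=input_len)
    return x


def assemble_model_data(sim_cfg: SimulationConfig, target_fs: float = 100.0,
                        input_len: int = 1024, split_seed: int | None = None,
                        interval_edges: np.ndarray = DEFAULT_EDGES,
                        min_age: float = 14.0) -> ModelData:
    """Simulate, preprocess and label a cohort ready for model training."""
    patients, ecg_meta, echo_list = simulate_tables(sim_cfg)
    pats = patients_frame(patients)
    echos = echos_to_frame(echo_list)
    if len(echos):
        echos["date"] = pd.to_datetime(echos["date"])
    x = preprocess_cohort_tensors(ecg_meta, sim_cfg, target_fs, input_len) \
        if len(ecg_meta) else np.zeros((0, sim_cfg.n_leads, input_len), np.float32)

    eligible = filter_minimum_age(pats, min_age)
    manifest = ecg_meta[["patient_id", "ecg_id", "date"]]
    manifest = manifest[manifest["patient_id"].isin(eligible["patient_id"])]
    pairs = pair_ecg_echo(manifest, echos)
    labels, labelled = {}, {}
    split = split_cohort(eligible["patient_id"],
                         seed=sim_cfg.seed if split_seed is None else split_seed)
    for valve in VALVES:
        labs = build_survival_labels(pairs, echos, valve, interval_edges)
        labels[valve] = labs
        frame = labels_to_frame(labs)
        frame["split"] = frame["patient_id"].map(split.assignment)
        labelled[valve] = frame
    return ModelData(
        x=x, ecg_ids=list(ecg_meta["ecg_id"]), fs=target_fs, patients=pats,
        ecg_meta=ecg_meta, echos=echos, pairs=pairs, labelled=labelled,
        labels=labels, split=split, interval_edges=np.asarray(interval_edges),
        ground_truth=ground_truth_outcomes(patients, echo_list))


def make_survival_sets(data: ModelData, valve: str) -> tuple[SurvivalDataset, SurvivalDataset]:
    """Training and tuning survival datasets (all pairs, exclusions kept)."""
    out = []
    frame = data.labelled[valve]
    labs = data.labels[valve]
    for grp in ("train", "tune"):
        sel = (frame["split"] == grp).to_numpy()
        ids = list(frame.loc[sel, "ecg_id"])
        y = np.stack([l.y for l, s in zip(labs, sel) if s])
        m = np.stack([l.mask for l, s in zip(labs, sel) if s]).astype(np.float32)
        out.append(SurvivalDataset(data.tensor_for(ids), y, m, ecg_ids=ids,
                                   patient_ids=list(frame.loc[sel, "patient_id"])))
    return out[0], out[1]


def make_classification_sets(data: ModelData, valve: str) -> tuple[SurvivalDataset, SurvivalDataset]:
    """Binary significant-regurgitation labels at the paired echo."""
    out = []
    frame = data.labelled[valve]
    for grp in ("train", "tune"):
        sel = (frame["split"] == grp).to_numpy()
        ids = list(frame.loc[sel, "ecg_id"])
        y = frame.loc[sel, "prevalent"].to_numpy().astype(np.float32)[:, None]
        out.append(SurvivalDataset(data.tensor_for(ids), y, np.ones_like(y),
                                   ecg_ids=ids,
                                   patient_ids=list(frame.loc[sel, "patient_id"])))
    return out[0], out[1]


def evaluation_frames(data: ModelData, valve: str) -> dict[str, pd.DataFrame]:
    """Evaluation-mode test-set frames: one per task (diagnosis/prediction).

    Applies the evaluation exclusions (device/surgery flags), restricts to
    the test split and the first ECG per patient, and in prediction mode
    removes prevalent patients and follow-up inside the blanking window.
    """
    keep = set(apply_exclusions(data.patients, "evaluation")["patient_id"])
    frame = data.labelled[valve]
    frame = frame[(frame["split"] == "test") & frame["patient_id"].isin(keep)]
    return {mode: select_evaluation_ecgs(frame, mode)
            for mode in ("diagnosis", "prediction")}


def score_frame(model: EcgRiskModel, data: ModelData, frame: pd.DataFrame) -> pd.DataFrame:
    """Attach model scores to an evaluation frame.

    Survival head: ``diagnosis_score`` (first-interval hazard) and
    ``risk_5y``. Classification head: the single score fills both columns.
    """
    ids = list(frame["ecg_id"])
    out = model.predict(data.tensor_for(ids), ids)
    frame = frame.copy()
    if model.head == "survival":
        frame["diagnosis_score"] = out.diagnosis_score
        frame["risk_5y"] = out.risk_5y
    else:
        frame["diagnosis_score"] = out.classification_score
        frame["risk_5y"] = out.classification_score
    return frame


def evaluate_model(model: EcgRiskModel, data: ModelData, valve: str,
                   n_boot: int = 0, seed: int = 0) -> dict:
    """Diagnosis AUROC and prediction C-index/Brier on the test split."""
    frames = evaluation_frames(data, valve)
    diag = score_frame(model, data, frames["diagnosis"])
    pred = score_frame(model, data, frames["prediction"])
    results = {
        "valve": valve, "head": model.head,
        "n_diagnosis": int(len(diag)), "n_prediction": int(len(pred)),
        "n_events": int(pred["event"].sum()),
        "auroc_diagnosis": auroc(diag["diagnosis_score"], diag["prevalent"].astype(int)),
        "c_index_prediction": harrell_c(pred["risk_5y"].to_numpy(),
                                        pred["time"].to_numpy(),
                                        pred["event"].to_numpy()),
        "brier_5y": brier_at_horizon(pred["risk_5y"].to_numpy(),
                                     pred["time"].to_numpy(),
                                     pred["event"].to_numpy(), horizon=5.0),
    }
    if n_boot:
        _, lo, hi = bootstrap_ci(
            harrell_c,
            [pred["risk_5y"].to_numpy(), pred["time"].to_numpy(),
             pred["event"].to_numpy()], n_boot=n_boot, seed=seed)
        results["c_index_ci"] = [lo, hi]
    return results


# --------------------------------------------------------------------------
# staged on-disk pipeline


@dataclass
class RunConfig:
    """Everything a full pipeline run needs, YAML-serializable."""

    out_dir: str = "runs/run"
    seed: int = 0
    profile: str = "tiny"               # "tiny" | "default"
    tasks: tuple[str, ...] = ("mr", "ar", "tr")
    heads: tuple[str, ...] = ("survival",)
    simulation: SimulationConfig = None
    train: TrainConfig = None
    target_fs: float = 100.0
    input_len: int = 1024
    latent_dim: int = 8
    vae_epochs: int = 15
    n_extreme: int = 50

    def __post_init__(self):
        if self.profile not in ("tiny", "default"):
            raise ValueError("profile must be 'tiny' or 'default'")
        if self.simulation is None:
            n = 80 if self.profile == "tiny" else 1000
            self.simulation = SimulationConfig(n_patients=n, seed=self.seed)
        if self.train is None:
            self.train = TrainConfig(max_epochs=3 if self.profile == "tiny" else 25)
        if self.profile == "default":
            self.target_fs, self.input_len = 400.0, 4096
        unknown = set(self.tasks) - set(VALVES)
        if unknown:
            raise ValueError(f"unknown tasks: {sorted(unknown)}")

    def backbone(self) -> BackboneConfig:
        if self.profile == "tiny":
            return BackboneConfig.tiny(input_len=self.input_len)
        return BackboneConfig(input_len=self.input_len)

    def to_yaml(self, path) -> None:
        # json round-trip turns tuples into lists, which YAML can represent
        payload = json.loads(json.dumps(dataclasses.asdict(self), default=str))
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        if payload.get("simulation"):
            payload["simulation"] = SimulationConfig(**payload["simulation"])
        if payload.get("train"):
            payload["train"] = TrainConfig(**payload["train"])
        for key in ("tasks", "heads"):
            if key in payload and payload[key] is not None:
                payload[key] = tuple(payload[key])
        return cls(**payload)


def _config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_manifest(stage_dir: Path, cfg: RunConfig, stage: str, info: dict) -> None:
    manifest = {"stage": stage, "version": __version__,
                "config_hash": _config_hash(cfg),
                "config": dataclasses.asdict(cfg),
                "finished_at": time.strftime("%Y-%m-%dT%H:%M:%S"), **info}
    (stage_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str))


def _stage_dir(cfg: RunConfig, stage: str) -> Path:
    d = Path(cfg.out_dir) / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


def stage_simulate(cfg: RunConfig) -> Path:
    """Write the simulated cohort (WFDB + CSV manifests + ground truth)."""
    out = _stage_dir(cfg, "cohort")
    patients, ecg_meta, echos = simulate_tables(cfg.simulation)
    ecgs = [render_ecg(row._asdict(), cfg.simulation)
            for row in ecg_meta.itertuples(index=False)]
    write_cohort(patients, ecgs, echos, out)
    ground_truth_outcomes(patients, echos).to_csv(
        out / "ground_truth.csv", index=False)
    _write_manifest(out, cfg, "simulate",
                    {"n_patients": len(patients), "n_ecgs": len(ecgs)})
    return out


def stage_preprocess(cfg: RunConfig) -> Path:
    """Read WFDB records, run the preprocessing chain, store HDF5 tensors."""
    cohort_dir = Path(cfg.out_dir) / "cohort"
    if not cohort_dir.exists():
        raise FileNotFoundError(f"missing cohort directory: {cohort_dir}")
    out = _stage_dir(cfg, "preprocessed")
    _, ecg_manifest, _ = read_cohort_tables(cohort_dir)
    tensors = {}
    for _, row in ecg_manifest.iterrows():
        ecg = load_manifest_ecg(cohort_dir, row)
        tensors[ecg.ecg_id] = preprocess_array(
            ecg.samples, ecg.fs, target_fs=cfg.target_fs, target_len=cfg.input_len)
    save_tensors(out / "tensors.h5", tensors, fs=cfg.target_fs)
    _write_manifest(out, cfg, "preprocess",
                    {"n_ecgs": len(tensors), "fs": cfg.target_fs,
                     "input_len": cfg.input_len})
    return out


def stage_build(cfg: RunConfig) -> Path:
    """Pair, label and split the cohort; persist per-valve label arrays."""
    cohort_dir = Path(cfg.out_dir) / "cohort"
    out = _stage_dir(cfg, "labels")
    patients, ecg_manifest, echos = read_cohort_tables(cohort_dir)
    eligible = filter_minimum_age(patients)
    manifest = ecg_manifest[ecg_manifest["patient_id"].isin(eligible["patient_id"])]
    pairs = pair_ecg_echo(manifest, echos)
    split = split_cohort(eligible["patient_id"], seed=cfg.seed)
    split.as_frame().to_csv(out / "split.csv", index=False)
    audit = {"n_patients": len(patients), "n_eligible": len(eligible),
             "n_ecgs": len(ecg_manifest), "n_paired": len(pairs)}
    for valve in cfg.tasks:
        labs = build_survival_labels(pairs, echos, valve)
        frame = labels_to_frame(labs)
        frame["split"] = frame["patient_id"].map(split.assignment)
        frame.to_csv(out / f"labelled_{valve}.csv", index=False)
        np.savez(out / f"labels_{valve}.npz",
                 ecg_ids=np.array([l.ecg_id for l in labs]),
                 y=np.stack([l.y for l in labs]),
                 mask=np.stack([l.mask for l in labs]),
                 interval_edges=labs[0].interval_edges if labs else DEFAULT_EDGES)
        audit[f"n_prevalent_{valve}"] = int(frame["prevalent"].sum())
        audit[f"n_events_{valve}"] = int(frame["event"].sum())
    _write_manifest(out, cfg, "build-cohort", audit)
    return out


def _load_training_arrays(cfg: RunConfig, valve: str):
    tensors, fs = load_tensors(Path(cfg.out_dir) / "preprocessed" / "tensors.h5")
    lab_dir = Path(cfg.out_dir) / "labels"
    with np.load(lab_dir / f"labels_{valve}.npz") as z:
        ecg_ids = [str(e) for e in z["ecg_ids"]]
        y, mask, edges = z["y"], z["mask"], z["interval_edges"]
    frame = pd.read_csv(lab_dir / f"labelled_{valve}.csv")
    return tensors, ecg_ids, y, mask, edges, frame


def stage_train(cfg: RunConfig, valve: str, head: str = "survival") -> Path:
    """Train one model; persist checkpoint and per-epoch log."""
    out = _stage_dir(cfg, f"model_{valve}_{head}")
    tensors, ecg_ids, y, mask, edges, frame = _load_training_arrays(cfg, valve)
    sets = {}
    for grp in ("train", "tune"):
        sel = frame["split"] == grp
        ids = list(frame.loc[sel, "ecg_id"])
        rows = [ecg_ids.index(e) for e in ids]
        if head == "survival":
            yy, mm = y[rows], mask[rows].astype(np.float32)
        else:
            yy = frame.loc[sel, "prevalent"].to_numpy().astype(np.float32)[:, None]
            mm = np.ones_like(yy)
        sets[grp] = SurvivalDataset(np.stack([tensors[e] for e in ids]), yy, mm,
                                    ecg_ids=ids,
                                    patient_ids=list(frame.loc[sel, "patient_id"]))
    model = EcgRiskModel(cfg.backbone(), head=head, interval_edges=edges,
                         seed=cfg.seed)
    log = train_model(model, sets["train"], sets["tune"], cfg.train, seed=cfg.seed)
    save_model(model, out / "checkpoint.npz")
    log.to_csv(out / "training_log.csv", index=False)
    _write_manifest(out, cfg, "train",
                    {"valve": valve, "head": head, "epochs": len(log),
                     "best_tune_loss": float(log.attrs["best_tune_loss"])})
    return out


def stage_evaluate(cfg: RunConfig, valve: str, head: str = "survival") -> Path:
    """Test-split metrics, KM curve points and quartile stratification."""
    from .evaluation import quartile_stratify  # deferred: heavy import chain

    out = _stage_dir(cfg, f"metrics_{valve}_{head}")
    model = load_model(Path(cfg.out_dir) / f"model_{valve}_{head}" / "checkpoint.npz")
    tensors, ecg_ids, y, mask, edges, frame = _load_training_arrays(cfg, valve)
    patients, _, _ = read_cohort_tables(Path(cfg.out_dir) / "cohort")
    keep = set(apply_exclusions(patients, "evaluation")["patient_id"])
    test = frame[(frame["split"] == "test") & frame["patient_id"].isin(keep)]
    test = test.copy()
    test["ecg_date"] = pd.to_datetime(test["ecg_date"])

    def _scores(ids):
        outp = model.predict(np.stack([tensors[e] for e in ids]), list(ids))
        if model.head == "survival":
            return outp.diagnosis_score, outp.risk_5y
        return outp.classification_score, outp.classification_score

    results = {"valve": valve, "head": head}
    diag = select_evaluation_ecgs(test, "diagnosis")
    d_score, _ = _scores(list(diag["ecg_id"]))
    results["n_diagnosis"] = int(len(diag))
    try:
        results["auroc_diagnosis"] = auroc(d_score, diag["prevalent"].astype(int))
        results["threshold_metrics"] = classification_threshold_metrics(
            d_score, diag["prevalent"].astype(int), threshold=0.5)
    except ValueError as exc:
        results["auroc_diagnosis"] = None
        logger.warning("diagnosis AUROC unavailable: %s", exc)

    pred = select_evaluation_ecgs(test, "prediction")
    _, p_risk = _scores(list(pred["ecg_id"]))
    results["n_prediction"] = int(len(pred))
    results["n_events"] = int(pred["event"].sum())
    times = pred["time"].to_numpy()
    events = pred["event"].to_numpy()
    results["c_index_prediction"] = harrell_c(p_risk, times, events)
    results["brier_5y"] = brier_at_horizon(p_risk, times, events)
    t_km, s_km = km_curve(times, events)
    pd.DataFrame({"time": t_km, "survival": s_km}).to_csv(
        out / "km_overall.csv", index=False)
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.step(t_km, 1.0 - s_km, where="post")
    ax.set_xlabel("years from index ECG")
    ax.set_ylabel("cumulative event rate")
    ax.set_title(f"{valve.upper()} progression, test set (n={len(pred)})")
    fig.tight_layout()
    fig.savefig(out / "km_overall.png", dpi=110)
    plt.close(fig)

    # risk quartiles frozen on tuning-set scores
    tune = frame[frame["split"] == "tune"]
    tune_pred = select_evaluation_ecgs(
        tune.assign(ecg_date=pd.to_datetime(tune["ecg_date"])), "prediction")
    if len(tune_pred) >= 8 and events.sum() >= 5:
        _, tune_risk = _scores(list(tune_pred["ecg_id"]))
        records = pred.merge(patients[["patient_id", "age", "sex"]], on="patient_id")
        records = records.assign(risk=p_risk)
        try:
            strat = quartile_stratify(tune_risk, records)
            strat.hazard_ratios.to_csv(out / "quartile_hr.csv")
            results["hr_top_vs_bottom"] = strat.top_vs_bottom_hr
        except Exception as exc:  # degenerate small-cohort fits
            logger.warning("quartile stratification failed: %s", exc)
    (out / "metrics.json").write_text(json.dumps(results, indent=2, default=float))
    _write_manifest(out, cfg, "evaluate", {"valve": valve, "head": head})
    return out


def stage_explain(cfg: RunConfig, valve: str, head: str = "survival") -> Path:
    """Median beats of test ECGs -> extreme-group waveforms + VAE panels."""
    from .explain import (extreme_group_waveforms, plot_extreme_groups,
                          rank_latents, train_vae, traverse)

    out = _stage_dir(cfg, f"explain_{valve}")
    model = load_model(Path(cfg.out_dir) / f"model_{valve}_{head}" / "checkpoint.npz")
    tensors, ecg_ids, y, mask, edges, frame = _load_training_arrays(cfg, valve)
    cohort_dir = Path(cfg.out_dir) / "cohort"
    _, ecg_manifest, _ = read_cohort_tables(cohort_dir)
    rows = ecg_manifest[ecg_manifest["ecg_id"].isin(frame["ecg_id"])]

    beats, ids = [], []
    for _, row in rows.iterrows():
        ecg = load_manifest_ecg(cohort_dir, row)
        pp = preprocess_array(ecg.samples, ecg.fs, target_fs=400.0,
                              target_len=4096)
        sig = EcgSignal(ecg.patient_id, ecg.ecg_id, ecg.acquisition_date,
                        400.0, ecg.leads, pp)
        try:
            mb = extract_median_beat(sig)
        except ValueError:
            continue
        beats.append(mb.samples)
        ids.append(ecg.ecg_id)
    beats = np.stack(beats)
    scores_all = model.predict(np.stack([tensors[e] for e in ids]), ids)
    scores = (scores_all.risk_5y if model.head == "survival"
              else scores_all.classification_score)

    extremes = extreme_group_waveforms(beats, scores, n_extreme=cfg.n_extreme)
    np.savez(out / "extreme_groups.npz",
             **{k: v for k, v in extremes.items() if isinstance(v, np.ndarray)})
    import matplotlib
    matplotlib.use("Agg")
    fig = plot_extreme_groups(extremes, fs=400.0,
                              leads=[str(i) for i in range(beats.shape[1])])
    fig.savefig(out / "extreme_groups.png", dpi=110)

    info = {"valve": valve, "n_beats": len(beats),
            "n_extreme": extremes["n_extreme"]}
    if len(beats) >= 100:
        vae = train_vae(beats, latent_dim=cfg.latent_dim,
                        epochs=cfg.vae_epochs, seed=cfg.seed)
        ranked = rank_latents(vae, beats, scores)
        info["top_latents"] = [[i, t] for i, t in ranked]
        for rank_pos, (latent, tval) in enumerate(ranked):
            panel = traverse(vae, latent)
            np.savez(out / f"traversal_{rank_pos}_latent{latent}.npz",
                     positions=panel.positions, beats=panel.beats,
                     t_value=tval)
    else:
        logger.warning("too few median beats (%d) for a VAE; skipped", len(beats))
    _write_manifest(out, cfg, "explain", info)
    return out


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Run every stage in order; returns the stage output directories.

    Re-running with the same config and seed reproduces the cohort CSVs
    byte for byte and the metric files to stochastic-training tolerance.
    """
    run_dir = Path(cfg.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(run_dir / "config.yaml")
    paths: dict[str, Path] = {}
    paths["cohort"] = stage_simulate(cfg)
    paths["preprocessed"] = stage_preprocess(cfg)
    paths["labels"] = stage_build(cfg)
    for valve in cfg.tasks:
        for head in cfg.heads:
            paths[f"model_{valve}_{head}"] = stage_train(cfg, valve, head)
            paths[f"metrics_{valve}_{head}"] = stage_evaluate(cfg, valve, head)
        paths[f"explain_{valve}"] = stage_explain(cfg, valve, head=cfg.heads[0])
    return paths
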