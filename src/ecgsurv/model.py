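"""Residual 1-D CNN with interchangeable heads: binary classification and
discrete-time survival with prevalent-disease encoding.

The survival head emits one logit per time interval; the hazard for
interval k is its logistic transform. The first interval covers the
baseline (diagnosis) window, so ``h_1`` is the diagnosis score, while the
5-year cumulative risk multiplies the post-baseline interval survivals:
``risk_5y = 1 - prod_{k>=2, end(k) <= 5y} (1 - h_k)``. The baseline hazard
is deliberately excluded from ``risk_5y``: prediction is conditional on
being free of prevalent disease, matching the evaluation protocol that
removes prevalent cases.

The likelihood is a product of per-interval Bernoulli terms over observed
intervals only; masked intervals contribute exactly zero loss and gradient.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .cohort import DEFAULT_EDGES

logger = logging.getLogger(__name__)

EPS = 1e-7


# --------------------------------------------------------------------------
# losses (hazard space, with analytic gradients for verification)


def _clamp_probs(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        warnings.warn(f"probabilities clamped to ({EPS}, {1 - EPS})", stacklevel=3)
        p = np.clip(p, EPS, 1.0 - EPS)
    return p


def survival_loss(hazards: np.ndarray, y: np.ndarray, mask: np.ndarray) -> float:
    """Discrete-time survival negative log-likelihood.

    ``sum_{k observed} -[y_k log h_k + (1 - y_k) log(1 - h_k)]`` per sample,
    averaged over samples. Accepts single vectors or (N, K) batches; masked
    intervals contribute exactly zero.
    """
    h = np.atleast_2d(_clamp_probs(hazards))
    y = np.atleast_2d(np.asarray(y, dtype=np.float64))
    m = np.atleast_2d(np.asarray(mask, dtype=np.float64))
    terms = -(y * np.log(h) + (1.0 - y) * np.log1p(-h)) * m
    return float(terms.sum(axis=1).mean())


def survival_loss_grad(hazards: np.ndarray, y: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Analytic gradient of :func:`survival_loss` with respect to hazards."""
    h = np.atleast_2d(_clamp_probs(hazards))
    y2 = np.atleast_2d(np.asarray(y, dtype=np.float64))
    m = np.atleast_2d(np.asarray(mask, dtype=np.float64))
    n = h.shape[0]
    g = ((h - y2) / (h * (1.0 - h))) * m / n
    return g.reshape(np.shape(hazards))


def classification_loss(score: np.ndarray, label: np.ndarray) -> float:
    """Binary cross-entropy between classification scores and 0/1 labels."""
    s = np.atleast_1d(_clamp_probs(score))
    t = np.atleast_1d(np.asarray(label, dtype=np.float64))
    if np.any((t != 0) & (t != 1)):
        raise ValueError("classification labels must be 0 or 1")
    return float(-(t * np.log(s) + (1 - t) * np.log1p(-s)).mean())


def _masked_bce_logits(logits: np.ndarray, y: np.ndarray, mask: np.ndarray):
    """Stable masked BCE on logits; returns (mean loss, dloss/dlogits)."""
    z = logits.astype(np.float64)
    # softplus(z) - y*z, elementwise
    loss_terms = (np.logaddexp(0.0, z) - y * z) * mask
    n = z.shape[0]
    loss = float(loss_terms.sum() / n)
    probs = 1.0 / (1.0 + np.exp(-z))
    dlogits = ((probs - y) * mask / n).astype(np.float32)
    return loss, dlogits


def cumulative_risk(hazards: np.ndarray, interval_edges: np.ndarray,
                    horizon_years: float = 5.0) -> np.ndarray:
    """1 minus the product of post-baseline interval survivals up to horizon."""
    edges = np.asarray(interval_edges, dtype=float)
    h = np.atleast_2d(hazards)
    ks = [k for k in range(1, len(edges) - 1) if edges[k + 1] <= horizon_years + 1e-9]
    if not ks:
        return np.zeros(h.shape[0])
    return 1.0 - np.prod(1.0 - h[:, ks], axis=1)


# --------------------------------------------------------------------------
# architecture


@dataclass
class BackboneConfig:
    """Residual CNN backbone hyperparameters."""

    n_leads: int = 12
    input_len: int = 4096
    stem_channels: int = 32
    stem_kernel: int = 17
    stem_stride: int = 2
    channels: tuple[int, ...] = (64, 128, 196, 256)
    kernel: int = 17
    strides: tuple[int, ...] = (4, 4, 4, 4)
    dropout: float = 0.2

    def __post_init__(self) -> None:
        if len(self.channels) != len(self.strides):
            raise ValueError("channels and strides must have equal length")
        if min(self.channels) <= 0:
            raise ValueError("channels must be positive")
        length = self.input_len // self.stem_stride
        for s in self.strides:
            length //= s
        if length < 1:
            raise ValueError("downsampling collapses the temporal axis")

    @classmethod
    def tiny(cls, input_len: int = 1024) -> "BackboneConfig":
        """CPU-friendly profile for tests and desk-scale experiments."""
        return cls(input_len=input_len, stem_channels=16, stem_kernel=9,
                   stem_stride=4, channels=(16, 32), kernel=9, strides=(4, 4),
                   dropout=0.1)


@dataclass
class RiskOutput:
    """Per-ECG model outputs.

    ``hazards`` is (N, K); ``diagnosis_score`` is the first-interval hazard;
    ``risk_5y`` the 5-year cumulative risk (survival head). For the
    classification head only ``classification_score`` is populated.
    """

    ecg_ids: list[str]
    hazards: np.ndarray | None
    diagnosis_score: np.ndarray | None
    risk_5y: np.ndarray | None
    classification_score: np.ndarray | None = None


class EcgRiskModel:
    """Residual CNN over (leads x time) with a survival or classification head."""

    def __init__(self, config: BackboneConfig | None = None,
                 head: str = "survival",
                 interval_edges: np.ndarray = DEFAULT_EDGES,
                 seed: int = 0):
        if head not in ("survival", "classification"):
            raise ValueError("head must be 'survival' or 'classification'")
        self.config = config or BackboneConfig()
        self.head = head
        self.interval_edges = np.asarray(interval_edges, dtype=float)
        self.n_outputs = (len(self.interval_edges) - 1 if head == "survival" else 1)
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        self._build(self.rng)

    def _build(self, rng: np.random.Generator) -> None:
        cfg = self.config
        layers: list[nn.Layer] = [
            nn.Conv1d(cfg.n_leads, cfg.stem_channels, cfg.stem_kernel,
                      cfg.stem_stride, rng=rng),
            nn.BatchNorm1d(cfg.stem_channels),
            nn.ReLU(),
        ]
        c_in = cfg.stem_channels
        for c_out, stride in zip(cfg.channels, cfg.strides):
            layers.append(nn.ResidualBlock(c_in, c_out, cfg.kernel, stride,
                                           cfg.dropout, rng))
            c_in = c_out
        layers += [nn.GlobalAvgPool(), nn.Dropout(cfg.dropout, rng),
                   nn.Dense(c_in, self.n_outputs, rng=rng)]
        self.net = nn.Sequential(*layers)

    def params(self) -> list[nn.Param]:
        return self.net.params()

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        expected = (self.config.n_leads, self.config.input_len)
        if x.shape[1:] != expected:
            raise ValueError(f"expected input shape (N, {expected[0]}, {expected[1]}), "
                             f"got {x.shape}")
        return self.net.forward(x, train=train)

    def predict(self, x: np.ndarray, ecg_ids: list[str] | None = None,
                batch_size: int = 256) -> RiskOutput:
        """Deterministic inference over a batch of preprocessed ECGs."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        logits = np.concatenate([
            self.forward_logits(x[i:i + batch_size], train=False)
            for i in range(0, len(x), batch_size)
        ]) if len(x) else np.zeros((0, self.n_outputs), dtype=np.float32)
        probs = 1.0 / (1.0 + np.exp(-logits.astype(np.float64)))
        ids = ecg_ids if ecg_ids is not None else [str(i) for i in range(len(x))]
        if self.head == "classification":
            return RiskOutput(ecg_ids=list(ids), hazards=None, diagnosis_score=None,
                              risk_5y=None, classification_score=probs[:, 0])
        return RiskOutput(
            ecg_ids=list(ids), hazards=probs, diagnosis_score=probs[:, 0],
            risk_5y=cumulative_risk(probs, self.interval_edges))


# --------------------------------------------------------------------------
# training


@dataclass
class TrainConfig:
    lr: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 40
    patience: int = 5          # early-stopping patience on tuning loss
    lr_patience: int = 2       # reduce-on-plateau patience
    lr_factor: float = 0.5
    min_lr: float = 1e-5
    weight_decay: float = 0.0


@dataclass
class SurvivalDataset:
    """Arrays for one split: inputs plus per-interval targets and masks.

    For the classification head, ``y``/``mask`` are (N, 1) with mask all ones.
    """

    x: np.ndarray
    y: np.ndarray
    mask: np.ndarray
    ecg_ids: list[str] = field(default_factory=list)
    patient_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=np.float32)
        self.y = np.atleast_2d(np.asarray(self.y, dtype=np.float32))
        self.mask = np.atleast_2d(np.asarray(self.mask, dtype=np.float32))
        if not (len(self.x) == len(self.y) == len(self.mask)):
            raise ValueError("x, y, mask must share the first dimension")

    def __len__(self):
        return len(self.x)


def _dataset_loss(model: EcgRiskModel, data: SurvivalDataset,
                  batch_size: int) -> float:
    total = 0.0
    for i in range(0, len(data), batch_size):
        logits = model.forward_logits(data.x[i:i + batch_size], train=False)
        loss, _ = _masked_bce_logits(logits, data.y[i:i + batch_size],
                                     data.mask[i:i + batch_size])
        total += loss * len(data.x[i:i + batch_size])
    return total / len(data)


def train_model(model: EcgRiskModel, train_set: SurvivalDataset,
                tune_set: SurvivalDataset, config: TrainConfig | None = None,
                seed: int = 0) -> pd.DataFrame:
    """Mini-batch Adam training with tuning-set model selection.

    Keeps the parameters of the epoch with the lowest tuning loss, reduces
    the learning rate on plateau, and stops early. Returns the per-epoch
    log. NaN loss aborts with a diagnostic.
    """
    if len(train_set) == 0 or len(tune_set) == 0:
        raise ValueError("training and tuning sets must be non-empty")
    cfg = config or TrainConfig()
    rng = np.random.default_rng(seed)
    # re-seed the dropout streams so training is reproducible end to end
    model.rng.bit_generator.state = np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(99,))).bit_generator.state

    opt = nn.Adam(model.params(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    best_state = nn.get_state(model.params())
    best_tune = np.inf
    bad_epochs = 0
    plateau = 0
    log_rows = []
    epoch0 = _dataset_loss(model, tune_set, cfg.batch_size)

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(train_set))
        train_loss = 0.0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            opt.zero_grad()
            logits = model.forward_logits(train_set.x[idx], train=True)
            loss, dlogits = _masked_bce_logits(logits, train_set.y[idx],
                                               train_set.mask[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged (non-finite loss) at epoch {epoch}")
            model.net.backward(dlogits)
            opt.step()
            train_loss += loss * len(idx)
        train_loss /= len(train_set)
        tune_loss = _dataset_loss(model, tune_set, cfg.batch_size)
        log_rows.append({"epoch": epoch, "train_loss": train_loss,
                         "tune_loss": tune_loss, "lr": opt.lr})
        logger.info("epoch %d train %.4f tune %.4f lr %.2e",
                    epoch, train_loss, tune_loss, opt.lr)
        if tune_loss < best_tune - 1e-6:
            best_tune, bad_epochs, plateau = tune_loss, 0, 0
            best_state = nn.get_state(model.params())
        else:
            bad_epochs += 1
            plateau += 1
            if plateau > cfg.lr_patience and opt.lr > cfg.min_lr:
                opt.lr = max(opt.lr * cfg.lr_factor, cfg.min_lr)
                plateau = 0
            if bad_epochs > cfg.patience:
                break
    nn.set_state(model.params(), best_state)
    log = pd.DataFrame(log_rows)
    log.attrs["epoch0_tune_loss"] = epoch0
    log.attrs["best_tune_loss"] = best_tune
    return log


# --------------------------------------------------------------------------
# checkpoints


def save_model(model: EcgRiskModel, path) -> None:
    """Self-describing checkpoint: backbone config, head, edges and weights."""
    meta = {"config": asdict(model.config), "head": model.head,
            "interval_edges": list(map(float, model.interval_edges)),
            "seed": model.seed}
    arrays = {f"param_{i}": p.value for i, p in enumerate(model.params())}
    bn_state = {}
    idx = 0
    for layer in _iter_layers(model.net):
        if isinstance(layer, nn.BatchNorm1d):
            bn_state[f"bn_{idx}_mean"] = layer.running_mean
            bn_state[f"bn_{idx}_var"] = layer.running_var
            idx += 1
    np.savez(path, meta=json.dumps(meta), **arrays, **bn_state)


def load_model(path) -> EcgRiskModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        cfg = BackboneConfig(**{**meta["config"],
                                "channels": tuple(meta["config"]["channels"]),
                                "strides": tuple(meta["config"]["strides"])})
        model = EcgRiskModel(cfg, head=meta["head"],
                             interval_edges=np.array(meta["interval_edges"]),
                             seed=meta["seed"])
        for i, p in enumerate(model.params()):
            p.value[...] = data[f"param_{i}"]
        idx = 0
        for layer in _iter_layers(model.net):
            if isinstance(layer, nn.BatchNorm1d):
                layer.running_mean = data[f"bn_{idx}_mean"]
                layer.running_var = data[f"bn_{idx}_var"]
                idx += 1
    return model


def _iter_layers(layer: nn.Layer):
    yield layer
    if isinstance(layer, nn.Sequential):
        for sub in layer.layers:
            yield from _iter_layers(sub)
    if isinstance(layer, nn.ResidualBlock):
        yield from _iter_layers(layer.main)
        if layer.shortcut is not None:
            yield from _iter_layers(layer.shortcut)
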