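"""Morphology explanations for model predictions.

Two complementary views: (1) a variational autoencoder trained on median
beats, whose latent coordinates are ranked by the t-value of a linear
regression of the model prediction on the latents and visualized by latent
traversal; (2) average +- SD waveforms of the median beats from the ECGs
with the most extreme (lowest and highest) predictions.

The VAE is a fully connected encoder/decoder on flattened lead x beat
matrices with a diagonal Gaussian posterior and Gaussian likelihood.
Inputs are standardized globally (one mean, one scale) so relative lead
amplitudes survive; the likelihood scale ``sigma_x`` (standardized units)
balances reconstruction against the KL term.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from . import nn

logger = logging.getLogger(__name__)


def kl_divergence(mu: np.ndarray, logvar: np.ndarray) -> float:
    """KL(q || N(0, I)) summed over latents, averaged over samples."""
    mu = np.atleast_2d(mu)
    logvar = np.atleast_2d(logvar)
    per = 0.5 * (np.exp(logvar) + mu ** 2 - 1.0 - logvar).sum(axis=1)
    return float(per.mean())


class BeatVAE:
    """Fully connected VAE over flattened median beats."""

    def __init__(self, beat_shape: tuple[int, int], latent_dim: int = 16,
                 hidden: int = 128, seed: int = 0):
        self.beat_shape = tuple(beat_shape)
        self.latent_dim = latent_dim
        self.hidden = hidden
        d_in = int(np.prod(beat_shape))
        rng = np.random.default_rng(seed)
        self.enc_hidden = nn.Dense(d_in, hidden, rng=rng)
        self.enc_out = nn.Dense(hidden, 2 * latent_dim, rng=rng)
        self.dec_hidden = nn.Dense(latent_dim, hidden, rng=rng)
        self.dec_out = nn.Dense(hidden, d_in, rng=rng)
        self._relu_e = nn.ReLU()
        self._relu_d = nn.ReLU()
        # set by train_vae
        self.mean_ = 0.0
        self.scale_ = 1.0
        self.posterior_mean_ = np.zeros(latent_dim)
        self.posterior_sd_ = np.ones(latent_dim)
        self.loss_history: list[float] = []

    # ---- plumbing

    def params(self) -> list[nn.Param]:
        return (self.enc_hidden.params() + self.enc_out.params()
                + self.dec_hidden.params() + self.dec_out.params())

    def _standardize(self, beats: np.ndarray) -> np.ndarray:
        flat = np.asarray(beats, dtype=np.float32).reshape(len(beats), -1)
        return (flat - self.mean_) / self.scale_

    def encode(self, beats: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and log-variance for each beat."""
        x = self._standardize(np.atleast_3d(beats))
        h = self._relu_e.forward(self.enc_hidden.forward(x))
        out = self.enc_out.forward(h)
        return out[:, :self.latent_dim], out[:, self.latent_dim:]

    def decode(self, z: np.ndarray) -> np.ndarray:
        """Decode latent vectors to beats in original units (N, leads, W)."""
        z = np.atleast_2d(np.asarray(z, dtype=np.float32))
        h = self._relu_d.forward(self.dec_hidden.forward(z))
        flat = self.dec_out.forward(h) * self.scale_ + self.mean_
        return flat.reshape(len(z), *self.beat_shape)

    def reconstruct(self, beats: np.ndarray) -> np.ndarray:
        mu, _ = self.encode(beats)
        return self.decode(mu)


def train_vae(median_beats: np.ndarray, latent_dim: int = 16, hidden: int = 128,
              epochs: int = 60, batch_size: int = 64, lr: float = 1e-3,
              beta: float = 1.0, sigma_x: float = 0.5, seed: int = 0) -> BeatVAE:
    """Train a :class:`BeatVAE` on median beats of shape (N, leads, window).

    Minimizes Gaussian reconstruction error (scale ``sigma_x``) plus
    ``beta`` times the KL divergence to the standard-normal prior, by Adam.
    Constant input is degenerate and rejected; fewer than 100 beats is an
    error (the latent statistics would be meaningless).
    """
    beats = np.asarray(median_beats, dtype=np.float32)
    if beats.ndim != 3:
        raise ValueError("median_beats must have shape (N, leads, window)")
    if len(beats) < 100:
        raise ValueError("need at least 100 median beats to train a VAE")
    if float(beats.std()) == 0.0:
        raise ValueError("degenerate (constant) input beats")

    vae = BeatVAE(beats.shape[1:], latent_dim=latent_dim, hidden=hidden, seed=seed)
    vae.mean_ = float(beats.mean())
    vae.scale_ = float(beats.std())
    x_all = vae._standardize(beats)

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(5,)))
    opt = nn.Adam(vae.params(), lr=lr)
    inv_var = 1.0 / (sigma_x ** 2)
    n = len(x_all)
    for _ in range(epochs):
        order = rng.permutation(n)
        total = 0.0
        for i in range(0, n, batch_size):
            idx = order[i:i + batch_size]
            x = x_all[idx]
            nb = len(idx)
            opt.zero_grad()
            h_e = vae._relu_e.forward(vae.enc_hidden.forward(x))
            out = vae.enc_out.forward(h_e)
            mu, logvar = out[:, :latent_dim], out[:, latent_dim:]
            std = np.exp(0.5 * logvar)
            eps = rng.standard_normal(mu.shape).astype(np.float32)
            z = mu + std * eps
            h_d = vae._relu_d.forward(vae.dec_hidden.forward(z))
            xhat = vae.dec_out.forward(h_d)

            recon = 0.5 * inv_var * float(((xhat - x) ** 2).sum()) / nb
            kl = kl_divergence(mu, logvar)
            total += (recon + beta * kl) * nb

            dxhat = (inv_var * (xhat - x) / nb).astype(np.float32)
            dz = vae.dec_hidden.backward(vae._relu_d.backward(
                vae.dec_out.backward(dxhat)))
            dmu = dz + beta * mu / nb
            dlogvar = (dz * 0.5 * std * eps
                       + beta * 0.5 * (np.exp(logvar) - 1.0) / nb)
            dout = np.concatenate([dmu, dlogvar], axis=1).astype(np.float32)
            vae.enc_hidden.backward(vae._relu_e.backward(vae.enc_out.backward(dout)))
            opt.step()
        vae.loss_history.append(total / n)

    mu_all, _ = vae.encode(beats)
    vae.posterior_mean_ = mu_all.mean(axis=0)
    vae.posterior_sd_ = mu_all.std(axis=0)
    return vae


# --------------------------------------------------------------------------
# latent ranking and traversal


def rank_latents(vae: BeatVAE, median_beats: np.ndarray, predictions,
                 top: int = 3) -> list[tuple[int, float]]:
    """Rank latent coordinates by |t| in a regression of predictions on latents.

    Posterior means (not samples) enter a multiple linear regression with
    the model prediction as outcome; the ``top`` latents by absolute
    t-value are returned as ``(latent_index, t_value)``. The ranking is
    invariant to affine rescaling of the predictions.
    """
    mu, _ = vae.encode(median_beats)
    y = np.asarray(predictions, dtype=float)
    if len(y) != len(mu):
        raise ValueError("predictions must match the number of beats")
    design = sm.add_constant(mu.astype(float))
    if np.linalg.matrix_rank(design) < design.shape[1]:
        warnings.warn("collinear latents: rank-deficient design, pseudo-inverse fit")
    fit = sm.OLS(y, design).fit()
    tvals = np.nan_to_num(fit.tvalues[1:], nan=0.0,
                          posinf=1e12, neginf=-1e12)
    order = np.argsort(-np.abs(tvals), kind="stable")
    return [(int(i), float(tvals[i])) for i in order[:top]]


@dataclass
class TraversalPanel:
    """Decoded beats along one latent coordinate's sweep."""

    latent_index: int
    positions: np.ndarray              # latent offsets in SD units
    beats: np.ndarray                  # (steps, leads, window), original units
    t_value: float | None = None


def traverse(vae: BeatVAE, latent_index: int, span_sd: float = 3.0,
             steps: int = 7) -> TraversalPanel:
    """Decode the dataset's mean latent code sweeping one coordinate.

    The coordinate moves symmetrically over mean +- ``span_sd`` posterior
    SDs in ``steps`` steps; all other coordinates stay at their means.
    """
    if not 0 <= latent_index < vae.latent_dim:
        raise IndexError(f"latent index {latent_index} out of range "
                         f"(latent_dim={vae.latent_dim})")
    positions = np.linspace(-span_sd, span_sd, steps)
    codes = np.tile(vae.posterior_mean_, (steps, 1)).astype(np.float32)
    codes[:, latent_index] += positions * vae.posterior_sd_[latent_index]
    return TraversalPanel(latent_index=latent_index, positions=positions,
                          beats=vae.decode(codes))


# --------------------------------------------------------------------------
# extreme-group waveform averaging


def extreme_group_waveforms(median_beats: np.ndarray, predictions,
                            n_extreme: int = 10000) -> dict:
    """Mean and SD waveforms of the lowest- and highest-prediction groups.

    ``n_extreme`` is shrunk (with a warning) to half the cohort when the
    cohort is smaller than ``2 * n_extreme``; at exactly half, the two
    groups partition the ranked cohort.
    """
    beats = np.asarray(median_beats, dtype=float)
    y = np.asarray(predictions, dtype=float)
    if beats.size == 0 or len(y) == 0:
        raise ValueError("empty input")
    if len(beats) != len(y):
        raise ValueError("median_beats and predictions must align")
    if n_extreme > len(y) // 2:
        n_extreme = max(len(y) // 2, 1)
        warnings.warn(f"n_extreme reduced to {n_extreme} (half the cohort)")
    order = np.argsort(y, kind="stable")
    low, high = order[:n_extreme], order[-n_extreme:]
    return {
        "n_extreme": int(n_extreme),
        "low_mean": beats[low].mean(axis=0), "low_sd": beats[low].std(axis=0),
        "high_mean": beats[high].mean(axis=0), "high_sd": beats[high].std(axis=0),
        "low_prediction_mean": float(y[low].mean()),
        "high_prediction_mean": float(y[high].mean()),
    }


def plot_extreme_groups(result: dict, fs: float, leads, axes=None):
    """Shaded mean +- SD bands per lead for the two extreme groups."""
    import matplotlib.pyplot as plt

    n_leads = result["low_mean"].shape[0]
    t_ms = np.arange(result["low_mean"].shape[1]) / fs * 1000.0
    if axes is None:
        fig, axes = plt.subplots(3, int(np.ceil(n_leads / 3)),
                                 figsize=(3 * np.ceil(n_leads / 3), 6),
                                 sharex=True)
        axes = np.ravel(axes)
    else:
        fig = axes[0].figure
    for i in range(n_leads):
        ax = axes[i]
        for grp, color in (("low", "tab:blue"), ("high", "tab:red")):
            m, s = result[f"{grp}_mean"][i], result[f"{grp}_sd"][i]
            ax.plot(t_ms, m, color=color, label=grp if i == 0 else None)
            ax.fill_between(t_ms, m - s, m + s, color=color, alpha=0.25)
        ax.set_title(str(leads[i]), fontsize=8)
    axes[0].legend(fontsize=7)
    fig.supxlabel("ms")
    fig.supylabel("mV")
    fig.tight_layout()
    return fig
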