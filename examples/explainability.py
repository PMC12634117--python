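"""Morphology explainability: VAE latent ranking and extreme-group averages.

Builds median beats whose QRS width is coupled to a risk score, then shows
that (1) the top-ranked VAE latent tracks the score and (2) the mean
waveform of the highest-scoring beats has a visibly broader QRS than the
lowest-scoring ones.
"""

import numpy as np

from ecgsurv import extreme_group_waveforms, rank_latents, train_vae, traverse

rng = np.random.default_rng(0)
n, width = 400, 120
t = np.linspace(0, 0.6, width)  # a 600 ms window
score = rng.uniform(0, 1, n)    # stand-in for a model's risk prediction
qrs_sd = 0.012 + 0.018 * score  # broader QRS at higher risk
beats = np.stack([np.exp(-((t - 0.2) ** 2) / (2 * s ** 2)) for s in qrs_sd])
beats += 0.3 * np.exp(-((t - 0.45) ** 2) / (2 * 0.04 ** 2))  # T wave
beats = np.repeat(beats[:, None, :], 2, axis=1)
beats += rng.normal(0, 0.01, beats.shape)

vae = train_vae(beats.astype(np.float32), latent_dim=6, epochs=60, seed=0)
ranked = rank_latents(vae, beats, score)
print("latents ranked by |t| against the risk score:",
      [(i, round(tv, 1)) for i, tv in ranked])

panel = traverse(vae, ranked[0][0], steps=7)
widths = [int(np.sum(b[0] > 0.5 * b[0].max())) for b in panel.beats]
print(f"QRS width (samples above half-max) along the top latent's traversal: {widths}")

groups = extreme_group_waveforms(beats, score, n_extreme=80)


def fwhm(x):
    return int(np.sum(x > 0.5 * x.max()))


print(f"mean QRS width, lowest-risk group:  {fwhm(groups['low_mean'][0])} samples")
print(f"mean QRS width, highest-risk group: {fwhm(groups['high_mean'][0])} samples")
print("\nThe top latent sweeps QRS width, and the high-prediction group's "
      "average beat is broader: both methods recover the planted morphology.")
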