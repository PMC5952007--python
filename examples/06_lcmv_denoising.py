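"""LCMV beamforming as a spatial denoiser.

Embeds a known rank-1 spatio-temporal pattern in correlated multichannel
noise, fits an LCMV filter from the class average and pooled covariance,
and compares the reconstruction quality of the beamformed component with
the best single channel.
"""

import numpy as np

from pacbci.core import EpochSet
from pacbci.spatial import (estimate_covariance, estimate_template,
                            lcmv_apply, lcmv_fit)

rng = np.random.default_rng(4)
n_channels, n_samples, n_epochs = 6, 250, 80
pattern = rng.standard_normal(n_channels)
pattern /= np.linalg.norm(pattern)
t = np.arange(n_samples) / 250.0
course = np.sin(2 * np.pi * 7 * t) * np.hanning(n_samples)
signal = np.outer(pattern, course)
mix = 0.4 * rng.standard_normal((n_channels, n_channels))
data = np.stack([signal + mix @ rng.standard_normal(signal.shape)
                 for _ in range(n_epochs)])
epochs = EpochSet(data, 250.0, [f"c{i}" for i in range(n_channels)],
                  np.ones(n_epochs, int), np.ones(n_epochs, int),
                  np.ones(n_epochs, bool))

model = lcmv_fit(estimate_template(epochs, 1),
                 estimate_covariance(epochs, gamma=0.05))
trial = epochs.data[0]
beamformed = lcmv_apply(model, trial)[0]

r_bf = abs(np.corrcoef(beamformed, course)[0, 1])
r_ch = max(abs(np.corrcoef(trial[i], course)[0, 1])
           for i in range(n_channels))
print(f"unit-gain check |W.T A - I| = "
      f"{np.max(np.abs(model.weights.T @ model.basis - 1)):.2e}")
print(f"correlation with the true time course:")
print(f"  beamformed component : {r_bf:.4f}")
print(f"  best single channel  : {r_ch:.4f}")
print("\nThe beamformer passes the template pattern with unit gain while")
print("minimising output variance, so its component tracks the true")
print("source better than any raw channel.")
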