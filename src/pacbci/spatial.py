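"""LCMV beamforming used purely as a denoising spatial filter.

A linearly constrained minimum-variance (LCMV) beamformer passes activity
matching a target spatial pattern with unit gain while minimising total
output variance, suppressing activity from other sources.  Here the target
pattern is estimated from class-averaged training epochs; the filtered
single-component trace then feeds the PAC feature chain.  The beamformer is
never used as a decoder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import EpochSet, ValidationError

__all__ = [
    "BeamformerModel",
    "estimate_template",
    "estimate_covariance",
    "lcmv_fit",
    "lcmv_apply",
]


@dataclass
class BeamformerModel:
    """Fitted LCMV filter.

    ``weights`` is channels x rank with the unit-gain property
    ``weights.T @ basis == I`` on the template subspace ``basis``.
    """

    template: np.ndarray      # channels x samples class-average pattern
    covariance: np.ndarray    # channels x channels, after shrinkage
    weights: np.ndarray       # channels x rank
    basis: np.ndarray         # channels x rank spatial pattern(s)
    shrinkage: float


def estimate_template(train: EpochSet, class_id: int,
                      segment_length: int | None = None) -> np.ndarray:
    """Sample-wise mean across all training segments of one class.

    Each training epoch is cut into maximal non-overlapping segments of
    ``segment_length`` samples (default: the whole epoch) and the segments
    are averaged into a channels x segment_length template.
    """
    mask = train.class_label == class_id
    if mask.sum() < 1:
        raise ValidationError(f"no training epochs of class {class_id}")
    seg = segment_length or train.n_samples
    if seg > train.n_samples:
        raise ValidationError(
            f"segment length {seg} exceeds epoch length {train.n_samples}"
        )
    n_seg = train.n_samples // seg
    pieces = []
    for trial in train.data[mask]:
        for k in range(n_seg):
            pieces.append(trial[:, k * seg:(k + 1) * seg])
    return np.mean(pieces, axis=0)


def estimate_covariance(train: EpochSet, gamma: float = 0.05) -> np.ndarray:
    """Pooled sample covariance over concatenated training epochs,
    shrunk as ``(1-gamma) C + gamma (trace(C)/m) I``."""
    if not 0 <= gamma <= 1:
        raise ValidationError(f"shrinkage gamma must be in [0,1], got {gamma}")
    m = train.n_channels
    x = np.concatenate(list(train.data), axis=1)  # channels x (trials*samples)
    if x.shape[1] <= m:
        raise ValidationError("need more total samples than channels")
    x = x - x.mean(axis=1, keepdims=True)
    c = (x @ x.T) / (x.shape[1] - 1)
    return (1 - gamma) * c + gamma * (np.trace(c) / m) * np.eye(m)


def lcmv_fit(template: np.ndarray, covariance: np.ndarray,
             rank: int = 1, gamma: float = 0.05) -> BeamformerModel:
    """LCMV weights ``W = C^-1 A (A^T C^-1 A)^-1`` for template basis A.

    By default A is the leading left singular vector of the template (its
    dominant spatial pattern); ``rank`` > 1 keeps more components.
    """
    template = np.asarray(template, float)
    covariance = np.asarray(covariance, float)
    u, s, _ = np.linalg.svd(template, full_matrices=False)
    if rank < 1 or rank > u.shape[1]:
        raise ValidationError(f"rank must be in 1..{u.shape[1]}")
    a = u[:, :rank]
    try:
        cinv_a = np.linalg.solve(covariance, a)
    except np.linalg.LinAlgError as e:
        raise ValidationError(
            "covariance is singular; increase shrinkage gamma"
        ) from e
    gram = a.T @ cinv_a
    cond = np.linalg.cond(gram)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValidationError(
            "A^T C^-1 A is ill-conditioned; increase gamma or reduce rank"
        )
    w = cinv_a @ np.linalg.inv(gram)
    return BeamformerModel(template=template, covariance=covariance,
                           weights=w, basis=a, shrinkage=gamma)


def lcmv_apply(model: BeamformerModel, epoch: np.ndarray) -> np.ndarray:
    """Project one ``channels x samples`` epoch: ``y = W.T x`` (rank x samples).

    Downstream PAC consumes row 0, the dominant component.
    """
    epoch = np.asarray(epoch, float)
    if epoch.ndim != 2 or epoch.shape[0] != model.weights.shape[0]:
        raise ValidationError(
            f"epoch has {epoch.shape[0] if epoch.ndim == 2 else '?'} channels, "
            f"model expects {model.weights.shape[0]}"
        )
    return model.weights.T @ epoch
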