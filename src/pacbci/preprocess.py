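"""Single-trial preprocessing: referencing, zero-phase Butterworth band
filtering, downsampling, epoch extraction and channel selection.

All band filtering is a 3rd-order Butterworth bandpass applied forward and
backward (``filtfilt``), giving effectively zero phase shift; signals are
reflect-padded before filtering so the short windows used downstream are not
dominated by edge ringing.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
from scipy import signal as sps

from .core import BandSpec, EpochSet, ValidationError

__all__ = [
    "FilterSpec",
    "rereference",
    "bandpass",
    "bandpass_epochs",
    "downsample",
    "downsample_epochs",
    "extract_epochs",
    "select_channels",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    """Bandpass filter description (order-3 zero-phase Butterworth)."""

    band: BandSpec
    order: int = 3
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValidationError(f"filter order must be >= 1, got {self.order}")


def rereference(
    epochs: EpochSet,
    mode: str,
    ref_channels: list[str] | None = None,
) -> EpochSet:
    """Re-reference every channel of every trial.

    ``mastoid_average`` subtracts the mean of the two named reference
    channels (classically the mastoids) from every channel;
    ``common_average`` subtracts the instantaneous across-channel mean.
    """
    if mode == "mastoid_average":
        if not ref_channels or len(ref_channels) != 2:
            raise ValidationError("mastoid_average needs exactly two ref_channels")
        idx = [epochs.channel_index(c) for c in ref_channels]
        ref = epochs.data[:, idx, :].mean(axis=1, keepdims=True)
    elif mode == "common_average":
        ref = epochs.data.mean(axis=1, keepdims=True)
    else:
        raise ValidationError(f"unknown referencing mode {mode!r}")
    out = epochs.data - ref
    log.info("rereference mode=%s shape=%s", mode, out.shape)
    return EpochSet(out, epochs.fs, list(epochs.channels), epochs.class_label,
                    epochs.session_id, epochs.attend, epochs.t0)


def _butter_sos(spec: FilterSpec, fs: float):
    nyq = fs / 2.0
    if spec.band.f_hi >= nyq:
        raise ValidationError(
            f"band {spec.band.name} upper edge {spec.band.f_hi} Hz >= Nyquist {nyq} Hz"
        )
    return sps.butter(spec.order, [spec.band.f_lo, spec.band.f_hi],
                      btype="bandpass", fs=fs, output="sos")


def bandpass(x: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    """Zero-phase Butterworth bandpass of a 1-D (or trailing-axis) signal.

    Reflect-pads by 3x the filter order's effective IIR length before the
    forward-backward pass and trims after, so that short epochs keep a flat
    passband response near their edges.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[-1]
    if n <= 3 * spec.order:
        raise ValidationError(
            f"signal length {n} too short for order-{spec.order} filtering"
        )
    sos = _butter_sos(spec, fs)
    # odd reflect padding; cap at n-1 as required by filtfilt-style edges
    padlen = min(n - 1, max(3 * spec.order * 2, 24))
    if not spec.zero_phase:
        return sps.sosfilt(sos, x, axis=-1)
    return sps.sosfiltfilt(sos, x, axis=-1, padtype="odd", padlen=padlen)


def bandpass_epochs(epochs: EpochSet, band: BandSpec, order: int = 3) -> EpochSet:
    """Apply :func:`bandpass` to every trial and channel."""
    out = bandpass(epochs.data, FilterSpec(band, order=order), epochs.fs)
    log.info("bandpass band=%s [%g,%g] Hz shape=%s", band.name,
             band.f_lo, band.f_hi, out.shape)
    return EpochSet(out, epochs.fs, list(epochs.channels), epochs.class_label,
                    epochs.session_id, epochs.attend, epochs.t0)


def downsample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Anti-alias low-pass then decimate by the integer factor fs_in/fs_out."""
    ratio = fs_in / fs_out
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9 or factor < 1:
        raise ValidationError(
            f"fs_in={fs_in} must be an integer multiple of fs_out={fs_out}"
        )
    x = np.asarray(x, dtype=np.float64)
    if factor == 1:
        return x.copy()
    return sps.decimate(x, factor, ftype="fir", zero_phase=True, axis=-1)


def downsample_epochs(epochs: EpochSet, fs_out: float) -> EpochSet:
    out = downsample(epochs.data, epochs.fs, fs_out)
    return EpochSet(out, fs_out, list(epochs.channels), epochs.class_label,
                    epochs.session_id, epochs.attend, epochs.t0)


def extract_epochs(
    continuous: np.ndarray,
    onsets: np.ndarray,
    t_start: float,
    t_end: float,
    fs: float,
    *,
    channels: list[str] | None = None,
    class_label: np.ndarray | None = None,
    session_id: np.ndarray | None = None,
    attend: np.ndarray | None = None,
) -> EpochSet:
    """Cut fixed-length epochs out of a continuous ``channels x samples`` record.

    Epoch length is round-half-up of ``(t_end - t_start) * fs``; the sample
    window is half-open, starting at ``onset + t_start*fs``.
    """
    continuous = np.atleast_2d(np.asarray(continuous, dtype=np.float64))
    onsets = np.asarray(onsets, dtype=np.int64)
    n_len = int(np.floor((t_end - t_start) * fs + 0.5))  # round half up
    starts = onsets + int(np.floor(t_start * fs + 0.5))
    n_rec = continuous.shape[1]
    trials = []
    for i, s in enumerate(starts):
        if s < 0 or s + n_len > n_rec:
            raise ValidationError(
                f"trial {i}: window [{s}, {s + n_len}) exceeds recording of {n_rec} samples"
            )
        trials.append(continuous[:, s:s + n_len])
    data = np.stack(trials) if trials else np.zeros((0, continuous.shape[0], n_len))
    n = len(trials)
    return EpochSet(
        data,
        fs,
        channels or [f"ch{i}" for i in range(continuous.shape[0])],
        class_label if class_label is not None else np.ones(n, dtype=int),
        session_id if session_id is not None else np.ones(n, dtype=int),
        attend if attend is not None else np.ones(n, dtype=bool),
        t0=t_start,
    )


def select_channels(epochs: EpochSet, labels: list[str]) -> EpochSet:
    """Return a channel-subset EpochSet in the requested order.

    Duplicate labels are rejected rather than silently deduplicated.
    """
    if len(set(labels)) != len(labels):
        raise ValidationError(f"duplicate channel labels in request: {labels}")
    idx = [epochs.channel_index(c) for c in labels]
    return EpochSet(epochs.data[:, idx, :], epochs.fs, list(labels),
                    epochs.class_label, epochs.session_id, epochs.attend, epochs.t0)
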