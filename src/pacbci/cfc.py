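"""Phase-to-amplitude cross-frequency coupling (PAC) estimators.

The PAC algorithm for a single sensor: bandpass the signal in a
low-frequency (LF) band and a high-frequency (HF) band; Hilbert-transform
both; take the HF amplitude envelope A_HF(t) and re-filter it inside the LF
band; Hilbert-transform the re-filtered envelope to obtain the phase
phi_LF->HF(t).  Coupling strength is then the phase consistency between
phi_LF(t) and phi_LF->HF(t), measured by

* ``plv``  — |mean exp(i(phi1 - phi2))|, the classical phase-locking value;
* ``iplv`` — |Im mean exp(i(phi1 - phi2))|, the imaginary part only, which
  discards zero-lag phase consistency (volume-conduction-like, self-
  interaction contributions) and is therefore the preferred estimator here;
* ``mvl``  — |mean A_HF(t) exp(i phi_LF(t))|, Canolty's mean vector length,
  which weights the LF phase by the *raw* HF envelope.

A comodulogram evaluates one estimator over every ordered (LF, HF) band
pair; the canonical seven bands give 7*6/2 = 21 pairs.  ``pac_timeseries``
slides a short window over the (precomputed, full-length) phase/envelope
vectors to produce a PAC trajectory across the trial.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import hilbert

from .core import BandSpec, ValidationError, normalize_estimator
from .preprocess import FilterSpec, bandpass

__all__ = [
    "AnalyticSignal",
    "PacEstimate",
    "Comodulogram",
    "PacTimeSeries",
    "PowerProfile",
    "analytic",
    "pac_phases",
    "plv",
    "iplv",
    "mvl",
    "pac",
    "comodulogram",
    "pac_timeseries",
    "signal_power",
    "relative_power",
    "surrogate_threshold",
]


@dataclass(frozen=True)
class AnalyticSignal:
    """Amplitude envelope A(t) >= 0 and instantaneous phase phi(t) in (-pi, pi]."""

    amplitude: np.ndarray
    phase: np.ndarray


@dataclass(frozen=True)
class PacEstimate:
    value: float
    method: str
    lf_band: BandSpec
    hf_band: BandSpec


@dataclass(frozen=True)
class Comodulogram:
    """Upper-triangular PAC matrix over an ordered band list (LF row < HF col)."""

    values: np.ndarray          # (B, B), NaN below/on the diagonal
    bands: tuple[BandSpec, ...]
    method: str

    @property
    def n_pairs(self) -> int:
        b = len(self.bands)
        return b * (b - 1) // 2

    def pairs(self):
        """Yield ((lf_band, hf_band), value) over the upper triangle."""
        b = len(self.bands)
        for i in range(b):
            for j in range(i + 1, b):
                yield (self.bands[i], self.bands[j]), self.values[i, j]

    def argmax_pair(self) -> tuple[BandSpec, BandSpec]:
        vals = np.where(np.isfinite(self.values), self.values, -np.inf)
        i, j = np.unravel_index(np.argmax(vals), vals.shape)
        return self.bands[i], self.bands[j]


@dataclass(frozen=True)
class PacTimeSeries:
    values: np.ndarray
    window: int
    step: int
    method: str
    lf_band: BandSpec
    hf_band: BandSpec


@dataclass(frozen=True)
class PowerProfile:
    """Per-band signal power (uV^2 * samples) and relative power (sums to 1)."""

    sp: np.ndarray
    rsp: np.ndarray
    bands: tuple[BandSpec, ...]


# ---------------------------------------------------------------------------

def analytic(x: np.ndarray) -> AnalyticSignal:
    """Hilbert analytic decomposition of a band-limited real signal."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size < 16:
        raise ValidationError("analytic() expects a 1-D signal of length >= 16")
    if not np.all(np.isfinite(x)):
        raise ValidationError("non-finite values in input")
    z = hilbert(x)
    return AnalyticSignal(amplitude=np.abs(z), phase=np.angle(z))


def _check_bands(lf: BandSpec, hf: BandSpec) -> None:
    if lf.f_hi > hf.f_lo:
        raise ValidationError(
            f"LF band {lf.name} [{lf.f_lo},{lf.f_hi}] must lie below HF band "
            f"{hf.name} [{hf.f_lo},{hf.f_hi}]"
        )


def pac_phases(
    x: np.ndarray, lf: BandSpec, hf: BandSpec, fs: float, order: int = 3
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run the PAC filtering chain; return (phi_LF, phi_LF->HF, A_HF).

    phi_LF      : phase of the LF-bandpassed signal
    phi_LF->HF  : phase of the LF-bandpassed HF amplitude envelope
    A_HF        : raw HF amplitude envelope (used by the MVL estimator)
    """
    _check_bands(lf, hf)
    x = np.asarray(x, dtype=np.float64)
    spec_lf = FilterSpec(lf, order=order)
    spec_hf = FilterSpec(hf, order=order)
    x_lf = bandpass(x, spec_lf, fs)
    x_hf = bandpass(x, spec_hf, fs)
    phi_lf = np.angle(hilbert(x_lf))
    a_hf = np.abs(hilbert(x_hf))
    # re-filter the HF envelope inside the LF band, then take its phase
    env_lf = bandpass(a_hf - a_hf.mean(), spec_lf, fs)
    phi_env = np.angle(hilbert(env_lf))
    return phi_lf, phi_env, a_hf


def plv(phi1: np.ndarray, phi2: np.ndarray) -> float:
    """Phase-locking value |mean exp(i(phi1 - phi2))| in [0, 1]."""
    phi1 = np.asarray(phi1, float)
    phi2 = np.asarray(phi2, float)
    if phi1.shape != phi2.shape or phi1.size < 1:
        raise ValidationError("phase vectors must be equal-length and non-empty")
    return float(np.abs(np.mean(np.exp(1j * (phi1 - phi2)))))


def iplv(phi1: np.ndarray, phi2: np.ndarray) -> float:
    """Imaginary phase-locking value |Im mean exp(i(phi1 - phi2))| in [0, 1]."""
    phi1 = np.asarray(phi1, float)
    phi2 = np.asarray(phi2, float)
    if phi1.shape != phi2.shape or phi1.size < 1:
        raise ValidationError("phase vectors must be equal-length and non-empty")
    return float(np.abs(np.imag(np.mean(np.exp(1j * (phi1 - phi2))))))


def mvl(a_hf: np.ndarray, phi_lf: np.ndarray) -> float:
    """Canolty mean vector length |mean A_HF(t) exp(i phi_LF(t))| >= 0."""
    a_hf = np.asarray(a_hf, float)
    phi_lf = np.asarray(phi_lf, float)
    if a_hf.shape != phi_lf.shape or a_hf.size < 1:
        raise ValidationError("vectors must be equal-length and non-empty")
    if np.any(a_hf < 0):
        raise ValidationError("amplitudes must be non-negative")
    return float(np.abs(np.mean(a_hf * np.exp(1j * phi_lf))))


_ESTIMATOR_FROM_PHASES = {"plv": plv, "iplv": iplv}


def _evaluate(method: str, phi_lf, phi_env, a_hf) -> float:
    if method == "mvl":
        return mvl(a_hf, phi_lf)
    return _ESTIMATOR_FROM_PHASES[method](phi_lf, phi_env)


def pac(
    x: np.ndarray,
    lf: BandSpec,
    hf: BandSpec,
    fs: float,
    method: str = "iplv",
) -> PacEstimate:
    """Coupling strength of LF phase onto HF amplitude for one signal."""
    method = normalize_estimator(method)
    phi_lf, phi_env, a_hf = pac_phases(x, lf, hf, fs)
    return PacEstimate(_evaluate(method, phi_lf, phi_env, a_hf), method, lf, hf)


def comodulogram(
    x: np.ndarray,
    bands: Sequence[BandSpec],
    fs: float,
    method: str = "iplv",
) -> Comodulogram:
    """PAC for every ordered band pair (LF earlier in the list, HF later)."""
    method = normalize_estimator(method)
    bands = tuple(bands)
    for a, b in zip(bands, bands[1:]):
        if a.f_lo >= b.f_lo or a.overlaps(b):
            raise ValidationError("bands must be ordered by f_lo and non-overlapping")
    x = np.asarray(x, dtype=np.float64)
    n = len(bands)
    # each band is filtered once; only the envelope re-filtering is per-pair
    filtered = [bandpass(x, FilterSpec(b), fs) for b in bands]
    phases = [np.angle(hilbert(f)) for f in filtered]
    envelopes = [np.abs(hilbert(f)) for f in filtered]
    vals = np.full((n, n), np.nan)
    for i in range(n):
        spec_lf = FilterSpec(bands[i])
        for j in range(i + 1, n):
            a_hf = envelopes[j]
            if method == "mvl":
                vals[i, j] = mvl(a_hf, phases[i])
            else:
                env_lf = bandpass(a_hf - a_hf.mean(), spec_lf, fs)
                phi_env = np.angle(hilbert(env_lf))
                vals[i, j] = _ESTIMATOR_FROM_PHASES[method](phases[i], phi_env)
    return Comodulogram(vals, bands, method)


def pac_timeseries(
    x: np.ndarray,
    lf: BandSpec,
    hf: BandSpec,
    fs: float,
    window: int,
    step: int = 1,
    method: str = "iplv",
    target_length: int | None = None,
) -> PacTimeSeries:
    """Sliding-window PAC trajectory.

    Phases and envelope are computed once on the full-length signal (the LF
    band is unresolvable inside a 100 ms window, so filtering is global);
    the estimator is then applied to each window
    ``[k*step, k*step + window)``.  Length is
    ``floor((n - window)/step) + 1`` unless ``target_length`` asks for a
    centred truncation.
    """
    method = normalize_estimator(method)
    x = np.asarray(x, float)
    n = x.size
    if window > n:
        raise ValidationError(f"window {window} exceeds signal length {n}")
    if step < 1:
        raise ValidationError("step must be >= 1")
    phi_lf, phi_env, a_hf = pac_phases(x, lf, hf, fs)
    n_win = (n - window) // step + 1
    vals = np.empty(n_win)
    for k in range(n_win):
        sl = slice(k * step, k * step + window)
        vals[k] = _evaluate(method, phi_lf[sl], phi_env[sl], a_hf[sl])
    if target_length is not None:
        if target_length > n_win:
            raise ValidationError(
                f"target_length {target_length} exceeds natural length {n_win}"
            )
        lo = (n_win - target_length) // 2
        vals = vals[lo:lo + target_length]
    return PacTimeSeries(vals, window, step, method, lf, hf)


# -- band power -------------------------------------------------------------

def signal_power(x_band: np.ndarray) -> float:
    """Signal power SP = sum_t x(t)^2 of one band-filtered segment."""
    x_band = np.asarray(x_band, float)
    if not np.all(np.isfinite(x_band)):
        raise ValidationError("non-finite values in input")
    return float(np.sum(x_band ** 2))


def relative_power(
    x: np.ndarray, bands: Sequence[BandSpec], fs: float
) -> PowerProfile:
    """Per-band SP and relative power RSP = SP(band) / sum over bands."""
    bands = tuple(bands)
    if len(bands) < 2:
        raise ValidationError("need at least 2 bands for relative power")
    sp = np.array([
        signal_power(bandpass(x, FilterSpec(b), fs)) for b in bands
    ])
    total = sp.sum()
    if total == 0:
        raise ValidationError("all-zero signal: relative power undefined")
    return PowerProfile(sp=sp, rsp=sp / total, bands=bands)


# -- surrogate helper --------------------------------------------------------

def surrogate_threshold(
    phi_lf: np.ndarray,
    phi_env: np.ndarray,
    a_hf: np.ndarray,
    method: str,
    fs: float,
    n_surrogates: int = 200,
    min_shift_s: float = 0.5,
    quantile: float = 0.95,
    seed: int = 0,
) -> float:
    """Circular time-shift surrogate null: the given quantile of the
    estimator under random relative shifts of the envelope phase/amplitude.

    Shifts are uniform over offsets at least ``min_shift_s`` seconds from
    zero (both directions), destroying phase alignment while keeping each
    marginal intact.
    """
    method = normalize_estimator(method)
    rng = np.random.default_rng(seed)
    n = len(phi_lf)
    min_shift = min(int(min_shift_s * fs), max(1, n // 4))
    shifts = rng.integers(min_shift, n - min_shift, size=n_surrogates)
    vals = np.empty(n_surrogates)
    for k, s in enumerate(shifts):
        vals[k] = _evaluate(
            method, phi_lf, np.roll(phi_env, s), np.roll(a_hf, s)
        )
    return float(np.quantile(vals, quantile))
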