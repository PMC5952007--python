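"""Synthetic EEG generator with injectable phase-to-amplitude coupling.

Signals are built as

    x(t) = a_L cos(2 pi f_L t)
         + a_H [(1 - m) + m (1 + cos(2 pi f_L t + offset)) / 2] cos(2 pi f_H t)
         + sigma * pink_noise(t)

so the phase of the low-frequency (LF) oscillation modulates the amplitude
envelope of the high-frequency (HF) carrier with depth m in [0, 1]; the
coupling phase ``offset`` sets the lag between LF phase and envelope peak
(the default pi/2 gives maximal imaginary phase-locking, mimicking a
non-zero-lag physiological interaction).  Pink noise is 1/f spectrally
shaped with seeded phases, sigma expressed relative to oscillation
amplitude.

Three dataset profiles emulate the experimental designs the pipeline is
meant for:

* ``cvep6``  — six flashing images, 1 s epochs at 512 Hz, with an
  attended/non-attended flag per trial and the alpha1 (8-10 Hz) relative
  power calibrated to the attended 0.09 +/- 0.02 versus non-attended
  0.06 +/- 0.01 regime; each class couples delta->theta on its own
  parieto-occipital channel.
* ``cvep32`` — 32-target matrix design, 5.25 s epochs at 250 Hz; targets
  are lagged by two frames of a length-63 m-sequence, so each class gets a
  coupling phase offset of 2 pi (2 (class-1)) / 63.
* ``ssvep5`` — five flicker frequencies (6.66, 7.50, 8.57, 10.00,
  12.00 Hz), 5 s epochs at 250 Hz, flicker sinusoid plus delta->theta
  coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import CANONICAL_BANDS, BandSpec, EpochSet, ValidationError
from .preprocess import FilterSpec, bandpass
from .cfc import signal_power

__all__ = [
    "CouplingSpec",
    "ClassRecipe",
    "gen_pink_noise",
    "gen_coupled_signal",
    "gen_msequence",
    "gen_dataset",
    "default_recipes",
    "SSVEP_FREQS",
]

SSVEP_FREQS = (6.66, 7.50, 8.57, 10.00, 12.00)

#: channel layout used by the generator: six parieto-occipital analysis
#: channels first, then two frontal/central noise-only channels
DEFAULT_CHANNELS = ["PZ", "OZ", "P3", "P4", "P7", "P8", "CZ", "FZ"]
PARIETO_OCCIPITAL = DEFAULT_CHANNELS[:6]


@dataclass(frozen=True)
class CouplingSpec:
    """One LF-phase -> HF-amplitude coupling to inject."""

    lf_hz: float = 2.0
    hf_hz: float = 6.0
    depth: float = 0.8
    offset: float = np.pi / 2
    amp_lf: float = 1.0
    amp_hf: float = 1.0

    def __post_init__(self) -> None:
        if not self.lf_hz < self.hf_hz:
            raise ValidationError("lf_hz must be < hf_hz")
        if not 0.0 <= self.depth <= 1.0:
            raise ValidationError(f"depth must be in [0,1], got {self.depth}")


@dataclass(frozen=True)
class ClassRecipe:
    """Per-class generation recipe: which channels couple, at what depth,
    plus the alpha1 relative-power targets for the attention contrast."""

    class_id: int
    couplings: dict = field(default_factory=dict)   # channel label -> CouplingSpec or tuple of them
    alpha1_rsp_attended: float = 0.09
    alpha1_rsp_nonattended: float = 0.06
    alpha1_rsp_sd_attended: float = 0.02
    alpha1_rsp_sd_nonattended: float = 0.01
    ssvep_hz: float | None = None
    noise_sigma: float = 0.5
    noise_alpha: float = 1.0

    def __post_init__(self) -> None:
        for r in (self.alpha1_rsp_attended, self.alpha1_rsp_nonattended):
            if not 0.0 < r < 1.0:
                raise ValidationError("alpha1 rsp targets must be in (0,1)")


# ---------------------------------------------------------------------------

def gen_pink_noise(n: int, fs: float, alpha: float = 1.0,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """1/f^alpha noise via spectral shaping with random phases, unit RMS."""
    rng = rng or np.random.default_rng()
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    mag = np.zeros_like(freqs)
    mag[1:] = freqs[1:] ** (-alpha / 2.0)
    phases = rng.uniform(0, 2 * np.pi, size=freqs.size)
    spec = mag * np.exp(1j * phases)
    x = np.fft.irfft(spec, n=n)
    return x / np.std(x)


def _coupled_core(spec: CouplingSpec, t: np.ndarray) -> np.ndarray:
    env = (1.0 - spec.depth) + spec.depth * (
        1.0 + np.cos(2 * np.pi * spec.lf_hz * t + spec.offset)) / 2.0
    return (spec.amp_lf * np.cos(2 * np.pi * spec.lf_hz * t)
            + spec.amp_hf * env * np.cos(2 * np.pi * spec.hf_hz * t))


def gen_coupled_signal(spec: CouplingSpec, fs: float, duration: float,
                       noise_sigma: float = 0.0, seed: int = 0,
                       noise_alpha: float = 1.0) -> np.ndarray:
    """One deterministic coupled trace plus seeded pink noise."""
    if spec.hf_hz >= fs / 2:
        raise ValidationError(
            f"hf_hz {spec.hf_hz} violates Nyquist at fs={fs}")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = _coupled_core(spec, t)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        x = x + noise_sigma * gen_pink_noise(n, fs, noise_alpha, rng)
    return x


def gen_msequence(taps: tuple[int, ...] = (6, 1), seed_state: int = 1,
                  n_lags: int = 0, lag_step: int = 2):
    """Maximal-length binary sequence from a degree-6 LFSR.

    ``taps`` are the polynomial exponents with nonzero coefficients besides
    x^0 (default x^6 + x + 1, which is primitive); the period must come out
    as 2^6 - 1 = 63 or the taps are rejected.  Returns the base sequence
    and, if requested, ``n_lags`` cyclic shifts by multiples of
    ``lag_step`` frames (targets lagged by integer multiples of two frames).
    """
    degree = 6
    if max(taps) != degree:
        raise ValidationError("taps must include the LFSR degree 6")
    state = [(seed_state >> i) & 1 for i in range(degree)]
    if not any(state):
        raise ValidationError("seed state must be nonzero")
    init = list(state)
    seq = []
    period = 0
    for step in range(1, 2 ** degree):
        out = state[-1]
        seq.append(out)
        fb = 0
        for tp in taps:
            fb ^= state[tp - 1]
        state = [fb] + state[:-1]
        if state == init:
            period = step
            break
    if period != 2 ** degree - 1:
        raise ValidationError(
            f"taps {taps} are not primitive: period {period} != 63")
    base = np.array(seq, dtype=int)
    if n_lags:
        lags = [np.roll(base, -lag_step * k) for k in range(n_lags)]
        return base, lags
    return base


# -- dataset profiles --------------------------------------------------------

_PROFILES = {
    "cvep6": dict(n_classes=6, fs=512.0, duration=1.0),
    "cvep32": dict(n_classes=32, fs=250.0, duration=5.25),
    "ssvep5": dict(n_classes=5, fs=250.0, duration=5.0),
}


def default_recipes(profile: str, n_classes: int | None = None,
                    noise_sigma: float | None = None,
                    depth: float = 0.8) -> list[ClassRecipe]:
    """Recipes embodying each profile's class structure.

    cvep6: every parieto-occipital channel carries delta-phase coupling
    onto two carriers (theta and beta1); the six classes differ in the
    coupling phase lags of the two carriers (a 2 x 3 lag grid), mimicking
    image-specific response latencies.  cvep32: all six analysis channels
    couple delta->theta with a class-specific coupling phase offset
    ``2 pi (2 (c-1)) / 63`` from the two-frame m-sequence lag.  ssvep5:
    class flicker frequency from :data:`SSVEP_FREQS` plus delta->theta
    coupling on the analysis channels.
    """
    if profile not in _PROFILES:
        raise ValidationError(f"unknown profile {profile!r}")
    n = n_classes or _PROFILES[profile]["n_classes"]
    recipes = []
    # cvep6 class code: each class delays the delta-coupled amplitude
    # envelope of the beta1 / beta2 / gamma1 carriers by either 0 or a
    # quarter delta-cycle (a 3-bit lag code, one codeword per flashed
    # image), mimicking image-specific response latencies; a class-
    # invariant delta->theta coupling (the headline physiological
    # signature) rides on top, well away from the alpha1 attention tone
    _lag_codes = ((0, 0, 1), (0, 1, 0), (1, 0, 0),
                  (0, 1, 1), (1, 0, 1), (1, 1, 0))
    _code_carriers = (16.0, 25.0, 37.0)
    for c in range(1, n + 1):
        if profile == "cvep6":
            code = _lag_codes[(c - 1) % len(_lag_codes)]
            specs = [CouplingSpec(2.0, 6.0, depth)]
            specs += [CouplingSpec(2.0, f_hf, depth,
                                   offset=(np.pi / 2) * bit,
                                   amp_lf=0.0, amp_hf=0.8)
                      for f_hf, bit in zip(_code_carriers, code)]
            coup = {ch: tuple(specs) for ch in PARIETO_OCCIPITAL}
            rec = ClassRecipe(class_id=c, couplings=coup,
                              noise_sigma=0.15 if noise_sigma is None else noise_sigma)
        elif profile == "cvep32":
            offset = 2 * np.pi * (2 * (c - 1)) / 63.0
            coup = {ch: CouplingSpec(depth=0.9, offset=offset)
                    for ch in PARIETO_OCCIPITAL}
            rec = ClassRecipe(class_id=c, couplings=coup,
                              noise_sigma=0.25 if noise_sigma is None else noise_sigma)
        else:  # ssvep5
            coup = {ch: CouplingSpec(depth=depth) for ch in PARIETO_OCCIPITAL}
            rec = ClassRecipe(class_id=c, couplings=coup,
                              ssvep_hz=SSVEP_FREQS[(c - 1) % len(SSVEP_FREQS)],
                              noise_sigma=0.5 if noise_sigma is None else noise_sigma)
        recipes.append(rec)
    return recipes


_ALPHA1 = next(b for b in CANONICAL_BANDS if b.name == "alpha1")
_ALPHA_TONE_HZ = 9.0


def _band_sp_profile(x: np.ndarray, fs: float) -> np.ndarray:
    return np.array([
        signal_power(bandpass(x, FilterSpec(b), fs)) for b in CANONICAL_BANDS
    ])


class _AlphaTone:
    """Quadrature 9 Hz tone pair with per-band filtered versions.

    Filtering is linear, so the band decomposition of
    ``cos(w t + phase) = cos(phase) c(t) - sin(phase) s(t)`` follows from
    the filtered cosine/sine components, letting the per-trial tone scale
    be solved exactly (a scalar quadratic) instead of iterated.
    """

    def __init__(self, n: int, fs: float):
        from scipy.signal.windows import tukey

        t = np.arange(n) / fs
        # tapered burst: alpha activity waxes and wanes, and the taper keeps
        # the tone's energy out of the delta band (no edge discontinuity)
        w = tukey(n, 0.5)
        self.cos = w * np.cos(2 * np.pi * _ALPHA_TONE_HZ * t)
        self.sin = w * np.sin(2 * np.pi * _ALPHA_TONE_HZ * t)
        self.cos_f = [bandpass(self.cos, FilterSpec(b), fs)
                      for b in CANONICAL_BANDS]
        self.sin_f = [bandpass(self.sin, FilterSpec(b), fs)
                      for b in CANONICAL_BANDS]

    def waveform(self, phase: float) -> np.ndarray:
        return np.cos(phase) * self.cos - np.sin(phase) * self.sin

    def filtered(self, phase: float) -> list[np.ndarray]:
        cp, sp_ = np.cos(phase), np.sin(phase)
        return [cp * c - sp_ * s for c, s in zip(self.cos_f, self.sin_f)]


def _calibrate_alpha(x: np.ndarray, fs: float, target_rsp: float,
                     tone: _AlphaTone, phase: float,
                     alpha_idx: int = 2) -> np.ndarray:
    """Add a scaled alpha1 tone so the 7-band alpha1 relative power of the
    result equals ``target_rsp`` exactly (under the package's own filter
    bank).  Per band, SP(x + s*tone) = A + 2 s C + s^2 B with A, B, C from
    the filtered components, so the target is a quadratic in s."""
    x_f = [bandpass(x, FilterSpec(b), fs) for b in CANONICAL_BANDS]
    t_f = tone.filtered(phase)
    a = np.array([float(xf @ xf) for xf in x_f])
    b = np.array([float(tf @ tf) for tf in t_f])
    c = np.array([float(xf @ tf) for xf, tf in zip(x_f, t_f)])
    r = target_rsp
    qa = b[alpha_idx] - r * b.sum()
    qb = 2.0 * (c[alpha_idx] - r * c.sum())
    qc = a[alpha_idx] - r * a.sum()
    disc = qb * qb - 4 * qa * qc
    if qa <= 0 or disc < 0:
        return x  # target unreachable from this base; leave unchanged
    s = (-qb + np.sqrt(disc)) / (2 * qa)
    if s <= 0:
        return x  # base already at/above target
    return x + s * tone.waveform(phase)


def gen_dataset(
    profile: str,
    recipes: list[ClassRecipe] | None = None,
    n_trials_per_class: int = 100,
    n_sessions: int = 4,
    fs: float | None = None,
    seed: int = 0,
    p_attend: float = 0.5,
    duration: float | None = None,
    channels: list[str] | None = None,
) -> EpochSet:
    """Generate a full epoch set for one dataset profile.

    Trials are assigned round-robin to sessions; the attend flag is
    Bernoulli(``p_attend``) for cvep6 (always True otherwise); everything
    is deterministic given ``seed``.
    """
    if profile not in _PROFILES:
        raise ValidationError(f"unknown profile {profile!r}")
    prof = _PROFILES[profile]
    fs = fs or prof["fs"]
    duration = duration or prof["duration"]
    channels = channels or list(DEFAULT_CHANNELS)
    recipes = recipes or default_recipes(profile)
    by_class = {r.class_id: r for r in recipes}
    n_classes = max(by_class)
    for c in range(1, n_classes + 1):
        if c not in by_class:
            raise ValidationError(f"missing recipe for class {c}")

    n = int(np.floor(duration * fs + 0.5))  # round half up, as in epoching
    t = np.arange(n) / fs
    rng = np.random.default_rng(seed)
    tone = _AlphaTone(n, fs) if profile == "cvep6" else None

    data, labels, sessions, attend = [], [], [], []
    trial_counter = 0
    for c in sorted(by_class):
        rec = by_class[c]
        for j in range(n_trials_per_class):
            att = bool(rng.random() < p_attend) if profile == "cvep6" else True
            trial = np.empty((len(channels), n))
            for ci, ch in enumerate(channels):
                x = rec.noise_sigma * gen_pink_noise(n, fs, rec.noise_alpha, rng)
                spec = rec.couplings.get(ch)
                if spec is not None:
                    for s in (spec if isinstance(spec, (tuple, list)) else (spec,)):
                        x = x + _coupled_core(s, t)
                if rec.ssvep_hz is not None and ch in rec.couplings:
                    # steady-state response is phase-locked to the flicker,
                    # so the flicker phase is stimulus-fixed across trials
                    x = x + 0.8 * np.cos(2 * np.pi * rec.ssvep_hz * t)
                trial[ci] = x
            if profile == "cvep6":
                mu = (rec.alpha1_rsp_attended if att
                      else rec.alpha1_rsp_nonattended)
                sd = (rec.alpha1_rsp_sd_attended if att
                      else rec.alpha1_rsp_sd_nonattended)
                target = float(np.clip(rng.normal(mu, sd), 0.01, 0.5))
                phase = rng.uniform(0, 2 * np.pi)
                for ci, ch in enumerate(channels):
                    if ch in PARIETO_OCCIPITAL:
                        trial[ci] = _calibrate_alpha(
                            trial[ci], fs, target, tone, phase)
            data.append(trial)
            labels.append(c)
            sessions.append(1 + (trial_counter % n_sessions))
            attend.append(att)
            trial_counter += 1

    return EpochSet(
        data=np.stack(data),
        fs=fs,
        channels=channels,
        class_label=np.array(labels),
        session_id=np.array(sessions),
        attend=np.array(attend),
        t0=0.0,
    )
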