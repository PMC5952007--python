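"""Core domain types shared by every stage of the pipeline.

The package operates on epoch-structured multichannel EEG: a real tensor of
``trials x channels x samples`` plus its sampling rate and per-trial
metadata (class label, session, attend flag).  Frequency content is always
described through :class:`BandSpec` objects; the seven canonical EEG bands
(delta through low gamma) used throughout are exposed as
:data:`CANONICAL_BANDS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "BandSpec",
    "EpochSet",
    "PipelineConfig",
    "CANONICAL_BANDS",
    "band_by_name",
    "ValidationError",
    "FormatError",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class FormatError(ValueError):
    """Raised when a file is structurally invalid (missing metadata etc.)."""


@dataclass(frozen=True)
class BandSpec:
    """A frequency band ``[f_lo, f_hi]`` in Hz with a display name."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValidationError(
                f"band {self.name!r}: need 0 < f_lo < f_hi, got "
                f"[{self.f_lo}, {self.f_hi}]"
            )

    def overlaps(self, other: "BandSpec") -> bool:
        return self.f_lo < other.f_hi and other.f_lo < self.f_hi


#: The seven-band decomposition used for all comodulograms: 7*6/2 = 21
#: low-frequency-phase x high-frequency-amplitude pairs.
CANONICAL_BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta", 0.5, 4.0),
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha1", 8.0, 10.0),
    BandSpec("alpha2", 10.0, 13.0),
    BandSpec("beta1", 13.0, 20.0),
    BandSpec("beta2", 20.0, 30.0),
    BandSpec("gamma1", 30.0, 45.0),
)

_ALIASES = {
    "delta": "delta", "d": "delta", "δ": "delta",
    "theta": "theta", "t": "theta", "θ": "theta",
    "alpha1": "alpha1", "a1": "alpha1", "α1": "alpha1",
    "alpha2": "alpha2", "a2": "alpha2", "α2": "alpha2",
    "beta1": "beta1", "b1": "beta1", "β1": "beta1",
    "beta2": "beta2", "b2": "beta2", "β2": "beta2",
    "gamma1": "gamma1", "g1": "gamma1", "γ1": "gamma1",
}


def band_by_name(name: str) -> BandSpec:
    """Look up a canonical band by name (``delta`` .. ``gamma1``)."""
    key = _ALIASES.get(name.strip().lower())
    if key is None:
        raise ValidationError(f"unknown band name {name!r}")
    return next(b for b in CANONICAL_BANDS if b.name == key)


@dataclass
class EpochSet:
    """Epoch-structured EEG: ``data[trial, channel, sample]`` in microvolts.

    Parameters
    ----------
    data
        Real tensor, shape ``(n_trials, n_channels, n_samples)``.
    fs
        Sampling rate in Hz, > 0.
    channels
        Ordered channel labels, length ``n_channels``.
    class_label
        Per-trial stimulus class in ``1..N`` (1-based, as in an N-class BCI).
    session_id
        Per-trial recording-session index.
    attend
        Per-trial flag: did the subject attend (count) the stimulus.
    t0
        Epoch start relative to stimulus onset, seconds (onset at t = 0).
    """

    data: np.ndarray
    fs: float
    channels: list[str]
    class_label: np.ndarray
    session_id: np.ndarray
    attend: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValidationError(
                f"data must be trials x channels x samples, got ndim={self.data.ndim}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("data contains non-finite values")
        if self.fs <= 0:
            raise ValidationError(f"fs must be > 0, got {self.fs}")
        n = self.n_trials
        self.channels = [str(c) for c in self.channels]
        if len(self.channels) != self.data.shape[1]:
            raise ValidationError("channel label count does not match data")
        self.class_label = np.asarray(self.class_label, dtype=np.int64)
        self.session_id = np.asarray(self.session_id, dtype=np.int64)
        self.attend = np.asarray(self.attend, dtype=bool)
        for name, vec in (
            ("class_label", self.class_label),
            ("session_id", self.session_id),
            ("attend", self.attend),
        ):
            if vec.shape != (n,):
                raise ValidationError(f"{name} must have length n_trials={n}")
        if n and self.class_label.min() < 1:
            raise ValidationError("class labels must be 1-based (>= 1)")

    # -- convenience ------------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def n_classes(self) -> int:
        return int(self.class_label.max()) if self.n_trials else 0

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise ValidationError(f"unknown channel label {label!r}") from None

    def subset_trials(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(
            data=self.data[mask],
            fs=self.fs,
            channels=list(self.channels),
            class_label=self.class_label[mask],
            session_id=self.session_id[mask],
            attend=self.attend[mask],
            t0=self.t0,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EpochSet):
            return NotImplemented
        return (
            np.array_equal(self.data, other.data)
            and self.fs == other.fs
            and self.channels == other.channels
            and np.array_equal(self.class_label, other.class_label)
            and np.array_equal(self.session_id, other.session_id)
            and np.array_equal(self.attend, other.attend)
            and self.t0 == other.t0
        )


VALID_ESTIMATORS = ("iplv", "plv", "mvl")


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings.

    ``window``/``step`` are in samples; ``selection_time`` is the seconds per
    selection T entering the information-transfer-rate computation; ``seed``
    controls every random choice and is echoed into all reports.
    """

    bands: Sequence[BandSpec] = field(default_factory=lambda: CANONICAL_BANDS)
    estimator: str = "iplv"
    window: int = 64
    step: int = 1
    channel_set: Sequence[str] | None = None
    selection_time: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        self.estimator = normalize_estimator(self.estimator)
        if self.window < 8:
            raise ValidationError(f"window must be >= 8 samples, got {self.window}")
        self.seed = int(self.seed)


def normalize_estimator(method: str) -> str:
    m = str(method).strip().lower()
    if m not in VALID_ESTIMATORS:
        raise ValidationError(
            f"unknown estimator {method!r}; expected one of {VALID_ESTIMATORS}"
        )
    return m


def as_replace(obj, **kw):
    """`dataclasses.replace` passthrough (kept for API symmetry)."""
    return replace(obj, **kw)
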