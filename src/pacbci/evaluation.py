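"""Performance evaluation: Wolpaw information transfer rate, accuracy,
cross-validation schemes and the channel / band-pair / window search.

The Wolpaw bits-per-selection for an N-class interface at accuracy P is

    B = log2(N) + P log2(P) + (1 - P) log2((1 - P)/(N - 1))

and ITR = B / (T / 60) bits per minute for a selection time of T seconds.
Below-chance accuracies (P < 1/N) are clipped to 0 bits with a warning:
the raw expression rebounds upward there, which has no operational meaning.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .core import EpochSet, ValidationError

__all__ = [
    "ItrResult",
    "CvScheme",
    "wolpaw_bits",
    "itr",
    "selection_time",
    "make_folds",
    "window_sweep",
    "optimize_decoding",
    "accuracy",
    "confusion_matrix",
]


@dataclass(frozen=True)
class ItrResult:
    n_classes: int
    accuracy: float
    t_seconds: float
    bits_per_selection: float
    bits_per_min: float


@dataclass
class CvScheme:
    """Cross-validation scheme.

    kind = 'session_holdout' (train sessions / test sessions),
    'cross_day' (second day's sessions train, first day's test) or
    'kfold' (stratified k-fold, seed-deterministic).
    """

    kind: str
    train_sessions: tuple[int, ...] = (1, 2, 3)
    test_sessions: tuple[int, ...] = (4,)
    k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("session_holdout", "cross_day", "kfold"):
            raise ValidationError(f"unknown CV scheme kind {self.kind!r}")
        if self.kind == "cross_day":
            self.train_sessions = (3, 4)
            self.test_sessions = (1, 2)


def wolpaw_bits(n_classes: int, p: float) -> float:
    """Wolpaw bits per selection; P below chance (1/N) clips to 0."""
    if n_classes < 2:
        raise ValidationError(f"need N >= 2 classes, got {n_classes}")
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"accuracy must be in [0,1], got {p}")
    if p < 1.0 / n_classes:
        warnings.warn(
            f"accuracy {p:.4f} below chance 1/{n_classes}; bits clipped to 0",
            stacklevel=2,
        )
        return 0.0
    b = np.log2(n_classes)
    if p > 0:
        b += p * np.log2(p)
    if p < 1:
        b += (1 - p) * np.log2((1 - p) / (n_classes - 1))
    return float(max(b, 0.0))


def itr(n_classes: int, p: float, t_seconds: float) -> ItrResult:
    """Information transfer rate in bits/min: wolpaw_bits * 60 / T."""
    if t_seconds <= 0:
        raise ValidationError(f"selection time T must be > 0, got {t_seconds}")
    b = wolpaw_bits(n_classes, p)
    return ItrResult(n_classes, p, t_seconds, b, b * 60.0 / t_seconds)


_PROFILE_OVERHEAD = {
    # flashing-image design: 300 ms stimulus presentation precedes the
    # decision window; matrix c-VEP: 500 ms gaze switch; SSVEP: 5 s switch
    "cvep6": 0.3,
    "cvep32": 0.5,
    "ssvep5": 5.0,
}


def selection_time(dataset_profile: str, decision_window: float) -> float:
    """Seconds per selection T = decision window + profile overhead."""
    if dataset_profile not in _PROFILE_OVERHEAD:
        raise ValidationError(f"unknown profile {dataset_profile!r}")
    if decision_window < 0:
        raise ValidationError("decision_window must be >= 0")
    return decision_window + _PROFILE_OVERHEAD[dataset_profile]


def make_folds(epochs: EpochSet, scheme: CvScheme) -> list[tuple[np.ndarray, np.ndarray]]:
    """Build (train_idx, test_idx) folds for the given scheme."""
    if scheme.kind in ("session_holdout", "cross_day"):
        sessions = set(np.unique(epochs.session_id))
        wanted = set(scheme.train_sessions) | set(scheme.test_sessions)
        missing = wanted - sessions
        if missing:
            raise ValidationError(f"sessions {sorted(missing)} absent from data")
        train = np.flatnonzero(np.isin(epochs.session_id, scheme.train_sessions))
        test = np.flatnonzero(np.isin(epochs.session_id, scheme.test_sessions))
        return [(train, test)]
    skf = StratifiedKFold(n_splits=scheme.k, shuffle=True, random_state=scheme.seed)
    idx = np.arange(epochs.n_trials)
    return [(idx[tr], idx[te]) for tr, te in skf.split(idx, epochs.class_label)]


def window_sweep(start: int = 32, stop: int = 256, step: int = 12) -> list[int]:
    """Decision-window lengths in samples: start, start+step, ...; the stop
    value is appended if the arithmetic sequence does not land on it."""
    if step <= 0:
        raise ValidationError("step must be > 0")
    if start > stop:
        raise ValidationError("start must be <= stop")
    seq = list(range(start, stop + 1, step))
    if seq[-1] != stop:
        seq.append(stop)
    return seq


def accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    return float(np.mean(y_true == y_pred)) if y_true.size else 0.0


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """Per-class confusion counts, rows = true class 1..N, cols = predicted."""
    cm = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(np.asarray(y_true), np.asarray(y_pred)):
        cm[int(t) - 1, int(p) - 1] += 1
    return cm


@dataclass
class SearchResult:
    channels: list
    pair: tuple
    length: int
    accuracy: float
    log: list = field(default_factory=list)


def optimize_decoding(
    evaluate,
    candidate_channels: list,
    candidate_pairs: list,
    length_grid: list[int],
    plateau_gain: float = 0.005,
    plateau_span: int = 25,
) -> SearchResult:
    """Search channels x band pairs x trajectory lengths for the best decoder.

    ``evaluate(channels, pair, length) -> accuracy`` is supplied by the
    caller (typically cross-validated).  Channels are grown greedily
    (forward selection), band pairs are scanned exhaustively, lengths
    ascend and stop early at absolute accuracy 1.0 or when no length in the
    last ``plateau_span`` increments improved by more than ``plateau_gain``.
    Returns the earliest configuration achieving the best accuracy.
    """
    if not candidate_channels or not candidate_pairs or not length_grid:
        raise ValidationError("empty candidate list")
    best = SearchResult(channels=[], pair=(), length=0, accuracy=-1.0)
    for pair in candidate_pairs:
        selected: list = []
        remaining = list(candidate_channels)
        current_best_acc = -1.0
        improved = True
        while remaining and improved:
            improved = False
            scores = []
            for ch in remaining:
                acc, length = _scan_lengths(
                    evaluate, selected + [ch], pair, length_grid,
                    plateau_gain, plateau_span)
                scores.append((acc, length, ch))
                best.log.append((tuple(selected + [ch]), pair, length, acc))
            acc, length, ch = max(scores, key=lambda s: (s[0], -s[1]))
            if acc > current_best_acc + plateau_gain:
                selected.append(ch)
                remaining.remove(ch)
                current_best_acc = acc
                improved = True
                if (acc, -length) > (best.accuracy, -best.length):
                    best = SearchResult(list(selected), pair, length, acc, best.log)
            if current_best_acc >= 1.0:
                break
        if best.accuracy >= 1.0:
            break
    return best


def _scan_lengths(evaluate, channels, pair, length_grid, gain, span):
    best_acc, best_len = -1.0, length_grid[0]
    since_improve = 0
    for length in length_grid:
        acc = evaluate(channels, pair, length)
        if acc > best_acc + gain:
            best_acc, best_len = acc, length
            since_improve = 0
        else:
            since_improve += 1
        if best_acc >= 1.0 or since_improve >= span:
            break
    return best_acc, best_len
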