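"""Symbolization of PAC time series and runs-test similarity classification.

A neural-gas codebook (Martinetz-style rank-based competitive learning)
summarises the sliding windows of training PAC trajectories into k
prototypical code waves.  A test trajectory is then compared to each
class's prototypes with the Wald-Wolfowitz two-sample runs test: pool the
two samples, count runs of sample-origin labels (univariately after
sorting; multivariately via the Friedman-Rafsky minimum-spanning-tree
generalisation) and standardise.  Samples from the same distribution
intermix, giving many runs and a high z — so the predicted class is the one
with the largest z.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist

from .core import ValidationError
from .cfc import PacTimeSeries

__all__ = [
    "Codebook",
    "SymbolSequence",
    "WwResult",
    "neural_gas_fit",
    "symbolize",
    "sliding_windows",
    "ww_statistic",
    "ww_classify",
]


@dataclass(frozen=True)
class Codebook:
    prototypes: np.ndarray          # k x dim
    meta: dict

    @property
    def k(self) -> int:
        return self.prototypes.shape[0]

    @property
    def dim(self) -> int:
        return self.prototypes.shape[1]


@dataclass(frozen=True)
class SymbolSequence:
    symbols: np.ndarray             # ints in 0..k-1
    source_length: int


@dataclass(frozen=True)
class WwResult:
    runs: int
    z: float
    n1: int
    n2: int


# ---------------------------------------------------------------------------

def neural_gas_fit(
    data: np.ndarray,
    k: int = 8,
    eps_i: float = 0.5,
    eps_f: float = 0.005,
    lam_i: float | None = None,
    lam_f: float = 0.01,
    t_max: int | None = None,
    seed: int = 0,
) -> Codebook:
    """Fit a k-prototype neural-gas codebook to a set of vectors.

    At each step a random sample x is drawn, prototypes are ranked by
    distance to x, and every prototype moves towards x with step size
    ``eps(t) * exp(-rank / lambda(t))``; both eps and lambda decay
    exponentially from their initial to final values over ``t_max`` steps
    (default ``50 * len(data)``).  Deterministic given the seed.
    """
    data = np.atleast_2d(np.asarray(data, float))
    n, dim = data.shape
    if k < 1 or k > n:
        raise ValidationError(f"need 1 <= k <= n data vectors, got k={k}, n={n}")
    lam_i = lam_i if lam_i is not None else max(k / 2.0, 1e-6)
    t_max = t_max if t_max is not None else 50 * n
    rng = np.random.default_rng(seed)
    protos = data[rng.choice(n, size=k, replace=False)].copy()
    for t in range(t_max):
        frac = t / max(t_max, 1)
        eps = eps_i * (eps_f / eps_i) ** frac
        lam = lam_i * (lam_f / lam_i) ** frac
        x = data[rng.integers(n)]
        d = np.linalg.norm(protos - x, axis=1)
        ranks = np.argsort(np.argsort(d, kind="stable"), kind="stable")
        protos += (eps * np.exp(-ranks / lam))[:, None] * (x - protos)
    meta = dict(k=k, eps_i=eps_i, eps_f=eps_f, lam_i=lam_i, lam_f=lam_f,
                t_max=t_max, seed=seed)
    return Codebook(prototypes=protos, meta=meta)


def sliding_windows(ts: PacTimeSeries | np.ndarray, window: int,
                    step: int = 1) -> np.ndarray:
    """Stack sliding windows of a 1-D trajectory into a (n_win, window) matrix."""
    x = ts.values if isinstance(ts, PacTimeSeries) else np.asarray(ts, float)
    if window > x.size:
        raise ValidationError(f"window {window} exceeds series length {x.size}")
    n_win = (x.size - window) // step + 1
    return np.stack([x[i * step:i * step + window] for i in range(n_win)])


def symbolize(ts: PacTimeSeries | np.ndarray, codebook: Codebook,
              window: int, step: int = 1) -> SymbolSequence:
    """Map each sliding window to its nearest prototype (ties: lowest index)."""
    if codebook.dim != window:
        raise ValidationError(
            f"codebook dimension {codebook.dim} != window {window}"
        )
    wins = sliding_windows(ts, window, step)
    d = cdist(wins, codebook.prototypes)
    # argmin returns the first (lowest-index) minimiser, the documented tie rule
    return SymbolSequence(symbols=np.argmin(d, axis=1),
                          source_length=wins.shape[0])


# -- Wald-Wolfowitz ----------------------------------------------------------

def _runs_moments(n1: int, n2: int) -> tuple[float, float]:
    n = n1 + n2
    mu = 2.0 * n1 * n2 / n + 1.0
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n ** 2 * (n - 1))
    return mu, var


def ww_statistic(sample_a, sample_b) -> WwResult:
    """Two-sample Wald-Wolfowitz runs test.

    Scalar samples are pooled and sorted and runs of origin labels counted;
    vector samples use the Friedman-Rafsky generalisation, where
    R = 1 + (number of mixed-origin edges of the Euclidean minimum spanning
    tree of the pooled points).  Either way z = (R - mu) / sigma with
    mu = 2 n1 n2/(n1+n2) + 1 and
    sigma^2 = 2 n1 n2 (2 n1 n2 - n1 - n2) / ((n1+n2)^2 (n1+n2-1)).
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if a.ndim == 1 and b.ndim == 1:
        n1, n2 = a.size, b.size
        if n1 < 2 or n2 < 2:
            raise ValidationError("both samples need n >= 2")
        pooled = np.concatenate([a, b])
        labels = np.concatenate([np.zeros(n1, int), np.ones(n2, int)])
        order = np.argsort(pooled, kind="stable")
        lab = labels[order]
        runs = 1 + int(np.sum(lab[1:] != lab[:-1]))
    elif a.ndim == 2 and b.ndim == 2 and a.shape[1] == b.shape[1]:
        n1, n2 = a.shape[0], b.shape[0]
        if n1 < 2 or n2 < 2:
            raise ValidationError("both samples need n >= 2")
        pts = np.vstack([a, b])
        labels = np.concatenate([np.zeros(n1, int), np.ones(n2, int)])
        d = cdist(pts, pts)
        mst = minimum_spanning_tree(d).tocoo()
        mixed = int(np.sum(labels[mst.row] != labels[mst.col]))
        runs = 1 + mixed
    else:
        raise ValidationError(
            "samples must both be 1-D (scalars) or 2-D with equal vector dim"
        )
    mu, var = _runs_moments(n1, n2)
    z = (runs - mu) / np.sqrt(var)
    return WwResult(runs=runs, z=float(z), n1=n1, n2=n2)


def ww_classify(
    test_windows: np.ndarray,
    class_prototypes: dict[int, np.ndarray],
) -> tuple[int, dict[int, float]]:
    """Predict the class whose prototype windows are most intermixed with
    the test windows (largest runs-test z).  Ties go to the lowest class id.
    """
    if len(class_prototypes) < 2:
        raise ValidationError("need prototypes for at least 2 classes")
    scores: dict[int, float] = {}
    for cls in sorted(class_prototypes):
        protos = np.atleast_2d(np.asarray(class_prototypes[cls], float))
        if protos.shape[0] < 1:
            raise ValidationError(f"empty prototype set for class {cls}")
        scores[cls] = ww_statistic(np.atleast_2d(test_windows), protos).z
    best = max(sorted(scores), key=lambda c: scores[c])
    return best, scores
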