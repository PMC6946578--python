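"""Weighted permutation entropy (WPE) of numeric time series.

Permutation entropy quantifies the complexity of a signal through the
Shannon entropy of ordinal patterns ("motifs"): each length-``m`` sub-vector
sampled at delay ``tau`` is reduced to the rank order of its elements, and
the entropy of the motif occurrence distribution is computed.  The weighted
variant reintroduces amplitude information by weighting every motif
occurrence with the variance of the raw samples that produced it, so that
large-amplitude structure dominates the estimate and near-flat segments
contribute little.

For EEG, strong low-frequency oscillations (synchronized cortical states)
concentrate probability mass on few motifs and drive WPE down; flat,
desynchronized activity spreads mass across all ``m!`` motifs and drives WPE
up.  WPE therefore serves as a time-resolved desynchronization proxy.

The sliding-window driver uses the production parameters of the closed-loop
setup as defaults: motif length 3, delay 1 sample, a 200-sample window moved
in steps of 10 samples (at 1000 Hz raw sampling this yields a 100 Hz entropy
series).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .signals import EntropyStream, SignalTrace

__all__ = [
    "WpeParams",
    "MotifDistribution",
    "motif_of",
    "weight_of",
    "motif_distribution",
    "wpe",
    "wpe_series",
]


@dataclass(frozen=True)
class WpeParams:
    """Parameters of the weighted-permutation-entropy estimator.

    Attributes
    ----------
    m : int
        Motif length (>= 2); there are ``m!`` possible ordinal motifs.
    tau : int
        Time-delay factor in samples between motif elements (>= 1).
    window_length : int
        Sliding-window length in samples; must admit at least one
        sub-vector, i.e. ``window_length >= (m - 1) * tau + 1``.
    step : int
        Window advance in samples; the entropy series is sampled at
        ``fs / step`` Hz.
    normalize : bool
        If True (default) divide by ``log(m!)`` so WPE lies in [0, 1].
    log_base : str
        ``"natural"`` (nats, default) or ``"two"`` (bits).
    """

    m: int = 3
    tau: int = 1
    window_length: int = 200
    step: int = 10
    normalize: bool = True
    log_base: str = "natural"

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("motif length m must be >= 2")
        if self.tau < 1:
            raise ValueError("delay tau must be >= 1")
        if self.window_length < (self.m - 1) * self.tau + 1:
            raise ValueError("window_length must be >= (m-1)*tau + 1")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.log_base not in ("natural", "two"):
            raise ValueError("log_base must be 'natural' or 'two'")

    @property
    def n_motifs(self) -> int:
        return math.factorial(self.m)

    @property
    def span(self) -> int:
        """Samples covered by one sub-vector: (m-1)*tau + 1."""
        return (self.m - 1) * self.tau + 1

    def _log(self, x: np.ndarray) -> np.ndarray:
        return np.log2(x) if self.log_base == "two" else np.log(x)


@dataclass
class MotifDistribution:
    """Variance-weighted motif occurrence probabilities within one window."""

    weighted_probs: dict
    total_weight: float
    degenerate: bool = False      # all sub-vectors constant -> zero total weight


def _check_finite(x: np.ndarray) -> None:
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")


def motif_of(sub) -> Tuple[int, ...]:
    """Ordinal motif of one sub-vector: each element replaced by its rank.

    Ranks run 0..m-1, smallest value first.  Ties are broken by temporal
    order (the earlier sample receives the lower rank), the stable
    Bandt-Pompe convention, so e.g. ``(7, 7, 7) -> (0, 1, 2)``.
    """
    sub = np.asarray(sub, dtype=float)
    _check_finite(sub)
    order = np.argsort(sub, kind="stable")
    ranks = np.empty(len(sub), dtype=int)
    ranks[order] = np.arange(len(sub))
    return tuple(int(r) for r in ranks)


def weight_of(sub) -> float:
    """Occurrence weight of one sub-vector: its population variance.

    ``w = (1/m) * sum((x_k - mean)^2)``; constant sub-vectors weigh zero.
    """
    sub = np.asarray(sub, dtype=float)
    _check_finite(sub)
    return float(np.mean((sub - sub.mean()) ** 2))


# --- vectorized internals -------------------------------------------------

def _subvectors(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    """All N = len(x) - (m-1)*tau sub-vectors as an (N, m) view-like array."""
    n = len(x) - (m - 1) * tau
    if n < 1:
        raise ValueError("window too short for the requested motif length/delay")
    idx = np.arange(n)[:, None] + tau * np.arange(m)[None, :]
    return x[idx]

# motif code: ranks encoded in base m (injective for permutations)
def _motif_codes(subs: np.ndarray) -> np.ndarray:
    m = subs.shape[1]
    order = np.argsort(subs, axis=1, kind="stable")
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(m)[None, :].repeat(len(subs), 0), axis=1)
    base = m ** np.arange(m)
    return ranks @ base


def _weights(subs: np.ndarray) -> np.ndarray:
    return ((subs - subs.mean(axis=1, keepdims=True)) ** 2).mean(axis=1)


def motif_distribution(x, p: WpeParams) -> MotifDistribution:
    """Weighted motif probabilities of one window.

    Each motif's probability is the summed variance-weight of its
    occurrences divided by the total weight of all sub-vectors.  A window in
    which every sub-vector is constant has zero total weight; it is returned
    with ``degenerate=True`` and an empty probability table (treated as a
    single-motif limit by :func:`wpe`).
    """
    x = np.asarray(x, dtype=float)
    _check_finite(x)
    subs = _subvectors(x, p.m, p.tau)
    codes = _motif_codes(subs)
    w = _weights(subs)
    total = float(w.sum())
    if total == 0.0:
        return MotifDistribution({}, 0.0, degenerate=True)
    probs: dict = {}
    for code in np.unique(codes):
        mask = codes == code
        ranks = tuple(int(r) for r in _decode(code, p.m))
        probs[ranks] = float(w[mask].sum() / total)
    return MotifDistribution(probs, total, degenerate=False)


def _decode(code: int, m: int) -> np.ndarray:
    digits = np.empty(m, dtype=int)
    for k in range(m):
        digits[k] = code % m
        code //= m
    return digits


def wpe(x, p: WpeParams = WpeParams()) -> float:
    """Weighted permutation entropy of a single window.

    ``H = -sum P_w log P_w`` over motifs with positive probability, in the
    base selected by ``p.log_base``; normalized by ``log(m!)`` when
    ``p.normalize``.  Degenerate (all-constant) windows return 0, the limit
    of a single-motif distribution.
    """
    dist = motif_distribution(x, p)
    if dist.degenerate:
        return 0.0
    probs = np.array(list(dist.weighted_probs.values()))
    h = float(-(probs * p._log(probs)).sum())
    if p.normalize:
        h /= float(p._log(np.array(p.n_motifs)))
    return h


def wpe_series(x, p: WpeParams = WpeParams(), fs: float | None = None,
               t0: float = 0.0) -> EntropyStream:
    """Sliding-window WPE of a full signal.

    Accepts a :class:`SignalTrace` or a 1-D array (then ``fs`` is required).
    Produces ``floor((len - window_length)/step) + 1`` values, each stamped
    at the time of its window's **last** sample so downstream state
    decisions are strictly causal.  The entropy series is sampled at
    ``fs / step`` Hz.

    Implementation: motif codes and weights are computed once per
    sub-vector; per-window motif masses are then window sums obtained from
    cumulative sums per motif, which makes the sliding estimate O(T * m!).
    """
    if isinstance(x, SignalTrace):
        if x.data.ndim != 1:
            raise ValueError("wpe_series expects a single-channel trace")
        sig, fs, t0 = x.data, x.fs, x.t0
    else:
        sig = np.asarray(x, dtype=float)
        if fs is None:
            raise ValueError("fs is required for array input")
    _check_finite(sig)
    T, L, s = len(sig), p.window_length, p.step
    if T < L:
        raise ValueError("signal shorter than one window")

    subs = _subvectors(sig, p.m, p.tau)
    codes = _motif_codes(subs)
    w = _weights(subs)

    n_win = (T - L) // s + 1
    starts = np.arange(n_win) * s
    n_sub = L - (p.m - 1) * p.tau          # sub-vectors per window
    ends = starts + n_sub

    # per-motif mass in each window via cumulative sums
    masses = np.zeros((n_win, p.n_motifs))
    for i, code in enumerate(np.unique(codes)):
        csum = np.concatenate(([0.0], np.cumsum(w * (codes == code))))
        masses[:, i] = csum[ends] - csum[starts]

    totals = masses.sum(axis=1)
    degenerate = totals == 0.0
    values = np.zeros(n_win)
    ok = ~degenerate
    if np.any(ok):
        probs = masses[ok] / totals[ok, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(probs > 0, probs * p._log(probs), 0.0)
        h = -terms.sum(axis=1)
        if p.normalize:
            h /= float(p._log(np.array(p.n_motifs)))
        values[ok] = h

    last_sample = starts + L - 1
    times = t0 + last_sample / fs
    return EntropyStream(times=times, values=values, fs=fs / s,
                         window_length=L, step=s, degenerate=degenerate)
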