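"""Core time-series containers and plain-text signal I/O.

Continuous signals are uniformly sampled arrays with a sampling rate and a
time origin.  Epoched data are trial x channel x time arrays cut around
stimulus events, with half-open peristimulus windows ``[tmin, tmax)`` and
stimulus onset at t = 0.

On-disk format for continuous signals is columnar delimited text: a ``#``
header carrying ``fs`` and ``t0``, then one row per sample, one column per
channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SignalTrace:
    """A uniformly sampled single- or multi-channel time series.

    Parameters
    ----------
    data : ndarray
        Shape ``(n_samples,)`` for one channel or ``(n_channels, n_samples)``.
    fs : float
        Sampling rate in Hz.
    t0 : float
        Time of the first sample in seconds.
    """

    data: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (1, 2):
            raise ValueError("data must be 1-D (single channel) or 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_channels(self) -> int:
        return 1 if self.data.ndim == 1 else self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[-1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channel(self, idx: int) -> "SignalTrace":
        if self.data.ndim == 1:
            if idx != 0:
                raise IndexError("single-channel trace")
            return self
        return SignalTrace(self.data[idx], self.fs, self.t0)


@dataclass
class EntropyStream:
    """Time-stamped entropy estimates from a sliding window.

    Each value is stamped at the time of its window's final sample, so a
    downstream classifier never sees information from the future.
    """

    times: np.ndarray
    values: np.ndarray
    fs: float                      # entropy sampling rate, Hz (= signal fs / step)
    window_length: int             # samples of the underlying signal
    step: int
    degenerate: np.ndarray = field(default=None)  # bool per value: all-constant window

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.degenerate is None:
            self.degenerate = np.zeros(self.values.shape, dtype=bool)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must align")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class EpochSet:
    """Trials cut around events: ``epochs`` has shape (trial, channel, time).

    ``tmin`` is the time of the first sample relative to the event; windows
    are half-open ``[tmin, tmin + n_times/fs)``.
    """

    epochs: np.ndarray
    fs: float
    tmin: float = 0.0

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim == 2:          # trials x time, single channel
            self.epochs = self.epochs[:, None, :]
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be (trial, channel, time)")

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_times(self) -> int:
        return self.epochs.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.n_times) / self.fs


def average_reference(trace: SignalTrace) -> SignalTrace:
    """Re-reference a multichannel trace to the mean over channels.

    After re-referencing, the channel mean of every sample is exactly zero;
    this mirrors the common-average reference applied before spatial
    filtering and online entropy tracking.
    """
    if trace.data.ndim != 2 or trace.n_channels < 2:
        raise ValueError("average reference requires >= 2 channels")
    data = trace.data - trace.data.mean(axis=0, keepdims=True)
    return SignalTrace(data, trace.fs, trace.t0)


def epochs_from_trace(trace: SignalTrace, event_times: np.ndarray,
                      tmin: float, tmax: float) -> EpochSet:
    """Cut half-open ``[tmin, tmax)`` epochs around event times (seconds)."""
    data = trace.data if trace.data.ndim == 2 else trace.data[None, :]
    n0 = int(round(tmin * trace.fs))
    n1 = int(round(tmax * trace.fs))
    if n1 <= n0:
        raise ValueError("empty epoch window")
    out = []
    for t in np.atleast_1d(event_times):
        i = int(round((t - trace.t0) * trace.fs))
        lo, hi = i + n0, i + n1
        if lo < 0 or hi > trace.n_samples:
            raise ValueError(f"epoch around t={t:.3f}s exceeds trace bounds")
        out.append(data[:, lo:hi])
    return EpochSet(np.stack(out), trace.fs, tmin=n0 / trace.fs)


def write_trace(path, trace: SignalTrace, fmt: str = "%.10g") -> None:
    """Write a trace as delimited text with a ``#`` metadata header."""
    data = trace.data if trace.data.ndim == 2 else trace.data[None, :]
    header = f"fs={trace.fs!r} t0={trace.t0!r} n_channels={data.shape[0]}"
    np.savetxt(path, data.T, fmt=fmt, delimiter="\t", header=header)


def read_trace(path) -> SignalTrace:
    """Read a trace written by :func:`write_trace`."""
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("#"):
        raise ValueError("missing metadata header")
    meta = dict(kv.split("=") for kv in first[1:].split())
    data = np.loadtxt(path, delimiter="\t", ndmin=2).T
    if data.shape[0] == 1:
        data = data[0]
    return SignalTrace(data, fs=float(meta["fs"]), t0=float(meta["t0"]))
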