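"""Time-frequency decomposition and phase-coherence metrics.

Single-trial complex Fourier representations are obtained by convolving the
(virtual-channel) epochs with frequency-adaptive Hann-tapered complex
exponentials of four cycles per frequency, evaluated on a 100 Hz output
grid (10 ms steps).  Edge points lacking full taper support are masked
invalid rather than zero-padded; power and coherence are computed on valid
points only.

Power is expressed in dB relative to the per-trial, per-frequency mean over
a baseline window (default the whole trial, -1 to 1.5 s peristimulus).

Inter-trial phase coherence (ITC) is the magnitude of the trial average of
unit-normalized coefficients.  Its jackknifed single-trial companion jITC
assigns each trial the ITC of all *other* trials; a trial phase-coherent
with the rest therefore receives a relatively low jITC, and ``1 - jITC``
serves as a single-trial phase-coherence score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve
from scipy.signal.windows import hann

from .signals import EpochSet

__all__ = [
    "TfRepresentation",
    "PowerMap",
    "linear_freq_grid",
    "gamma_freq_grid",
    "tf_transform",
    "power_db",
    "itc",
    "jitc",
    "single_trial_coherence",
    "autocorrelation",
    "band_mean",
]

OUTPUT_RATE = 100.0          # Hz: 10 ms time grid of the TF representation

BANDS = {                    # unweighted band summaries, Hz (inclusive)
    "low": (1.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (14.0, 30.0),
    "gamma": (40.0, 70.0),
}


def linear_freq_grid() -> np.ndarray:
    """1-40 Hz in 0.5 Hz steps (79 frequencies)."""
    return np.arange(1.0, 40.0 + 0.25, 0.5)


def gamma_freq_grid() -> np.ndarray:
    """40-70 Hz in 14 exponentially increasing steps (endpoints included)."""
    return np.geomspace(40.0, 70.0, 14)


@dataclass
class TfRepresentation:
    """Complex TF coefficients: (trial, frequency, time) on the 100 Hz grid.

    ``valid`` masks time points with full taper support per frequency.
    """

    coefficients: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    valid: np.ndarray            # (frequency, time) bool
    taper_cycles: float = 4.0


@dataclass
class PowerMap:
    """Per-trial power in dB relative to a per-trial/frequency baseline."""

    power: np.ndarray            # (trial, frequency, time), NaN where invalid
    freqs: np.ndarray
    times: np.ndarray
    baseline_window: tuple


def _epochs_2d(epochs: EpochSet) -> np.ndarray:
    if epochs.n_channels != 1:
        raise ValueError("time-frequency transform expects virtual-channel "
                         "(single-channel) epochs")
    return epochs.epochs[:, 0, :]


def tf_transform(epochs: EpochSet, freqs, cycles: float = 4.0) -> TfRepresentation:
    """Hann-taper wavelet convolution of epoched data.

    For each frequency f the kernel is a complex exponential under a Hann
    envelope of length ``cycles / f`` seconds, scaled so a unit-amplitude
    sinusoid at f yields coefficients of magnitude ~1.  Output is
    down-sampled to the 100 Hz analysis grid; points within half a kernel
    of either epoch edge are flagged invalid.
    """
    freqs = np.asarray(freqs, dtype=float)
    data = _epochs_2d(epochs)
    fs = epochs.fs
    n_times = data.shape[1]
    dec = int(round(fs / OUTPUT_RATE))
    if abs(fs / OUTPUT_RATE - dec) > 1e-9:
        raise ValueError("sampling rate must be an integer multiple of 100 Hz")
    out_idx = np.arange(0, n_times, dec)
    times = epochs.times[out_idx]

    n_trials = data.shape[0]
    coefs = np.empty((n_trials, len(freqs), len(out_idx)), dtype=complex)
    valid = np.zeros((len(freqs), len(out_idx)), dtype=bool)
    for i, f in enumerate(freqs):
        n_k = int(round(cycles / f * fs))
        if n_k < 3:
            n_k = 3
        if n_k > n_times:
            raise ValueError(f"taper at {f:g} Hz ({n_k} samples) longer than epoch")
        t_k = (np.arange(n_k) - (n_k - 1) / 2) / fs
        env = hann(n_k, sym=True)
        kernel = env * np.exp(2j * np.pi * f * t_k)
        kernel = kernel / (env.sum() / 2.0)     # unit gain at f
        full = fftconvolve(data, kernel[None, :], mode="same", axes=1)
        coefs[:, i, :] = full[:, out_idx]
        half = n_k // 2
        valid[i] = (out_idx >= half) & (out_idx < n_times - half)
    return TfRepresentation(coefficients=coefs, freqs=freqs, times=times,
                            valid=valid, taper_cycles=cycles)


def power_db(tf: TfRepresentation, baseline: tuple = (-1.0, 1.5)) -> PowerMap:
    """Power as dB change relative to each trial's mean power per frequency
    over the baseline window (half-open, defaults to the whole trial)."""
    t0, t1 = baseline
    in_base = (tf.times >= t0) & (tf.times < t1)
    power = np.abs(tf.coefficients) ** 2
    power = np.where(tf.valid[None, :, :], power, np.nan)
    base_mask = in_base[None, None, :] & tf.valid[None, :, :]
    if not base_mask.any():
        raise ValueError("baseline window contains no valid time points")
    with np.errstate(invalid="ignore"):
        base = np.nanmean(np.where(base_mask, power, np.nan), axis=2, keepdims=True)
    db = 10.0 * np.log10(power / base)
    return PowerMap(power=db, freqs=tf.freqs, times=tf.times,
                    baseline_window=baseline)


def _unit_phases(tf: TfRepresentation) -> np.ndarray:
    coefs = tf.coefficients
    mag = np.abs(coefs)
    zero = mag == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(zero, 0.0, coefs / np.where(zero, 1.0, mag))
    unit = np.where(tf.valid[None, :, :], unit, np.nan + 0j)
    return unit


def itc(tf: TfRepresentation) -> np.ndarray:
    """Inter-trial phase coherence in [0, 1]: |trial mean of coef/|coef||.

    Zero-magnitude coefficients are excluded from the average; invalid edge
    points are NaN.
    """
    if tf.coefficients.shape[0] < 2:
        raise ValueError("ITC requires >= 2 trials")
    unit = _unit_phases(tf)
    with np.errstate(invalid="ignore"):
        nonzero = np.abs(unit) > 0
        n = nonzero.sum(axis=0)
        s = np.where(nonzero, unit, 0.0).sum(axis=0)
        out = np.where(n > 0, np.abs(s) / np.maximum(n, 1), np.nan)
    out = np.where(tf.valid, out, np.nan)
    return out


def jitc(tf: TfRepresentation) -> np.ndarray:
    """Jackknife ITC: for each trial, the ITC of all remaining trials.

    Computed via the leave-one-out identity on the summed unit phasors,
    equivalent to literally dropping each trial and recomputing ITC.
    """
    n_trials = tf.coefficients.shape[0]
    if n_trials < 3:
        raise ValueError("jackknife ITC requires >= 3 trials")
    unit = _unit_phases(tf)
    with np.errstate(invalid="ignore"):
        nonzero = np.abs(unit) > 0
    total = np.nansum(unit, axis=0, keepdims=True)
    loo = total - np.where(np.isnan(unit), 0.0, unit)
    n_loo = nonzero.sum(axis=0, keepdims=True) - nonzero   # zero-mag excluded
    out = np.where(n_loo > 0, np.abs(loo) / np.maximum(n_loo, 1), np.nan)
    out = np.where(tf.valid[None, :, :], out, np.nan)
    return out


def single_trial_coherence(tf: TfRepresentation) -> np.ndarray:
    """Single-trial phase coherence, defined as ``1 - jITC``."""
    return 1.0 - jitc(tf)


def autocorrelation(x, max_lag: int) -> np.ndarray:
    """Normalized autocorrelation at lags 0..max_lag (lag 0 = 1)."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    if len(x) <= max_lag:
        raise ValueError("series must be longer than max_lag")
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0.0:
        raise ValueError("autocorrelation undefined for a constant series")
    acf = np.array([np.dot(x[:len(x) - k], x[k:]) / denom
                    for k in range(max_lag + 1)])
    return acf


def band_mean(values: np.ndarray, freqs: np.ndarray, band: str | tuple,
              times: np.ndarray | None = None,
              time_window: tuple | None = None) -> np.ndarray:
    """Unweighted mean over the frequencies of a band (and optionally a
    half-open time window) of a (..., frequency, time) array."""
    lo, hi = BANDS[band] if isinstance(band, str) else band
    fmask = (freqs >= lo) & (freqs <= hi)
    if not fmask.any():
        raise ValueError("band contains no grid frequencies")
    out = values[..., fmask, :]
    with np.errstate(invalid="ignore"):
        out = np.nanmean(out, axis=-2)
        if time_window is not None:
            if times is None:
                raise ValueError("times required with time_window")
            t0, t1 = time_window
            tmask = (times >= t0) & (times < t1)
            out = np.nanmean(out[..., tmask], axis=-1)
    return out
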