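"""Seeded generators for every input of the closed-loop pipeline.

The generators emulate the statistical structure the method operates on —
not any particular recording:

* EEG background is 1/f-type colored noise (power ~ 1/f^chi).
* Cortical synchronization is a band-limited oscillation whose amplitude
  envelope fluctuates slowly (mean-reverting log-normal envelope, time
  constant ~0.5 s).  Strong oscillation = synchronized state = low
  weighted permutation entropy, so the planted envelope is the ground
  truth against which the state classifier can be scored.
* Evoked responses are additive tone-locked bursts with a controllable
  phase-locked fraction, exercising ITC/jITC.
* Pupil traces follow a slower mean-reverting process (time constant ~2 s)
  with Poisson blinks rendered as brief near-zero dips.
* Behavior is drawn from a planted logistic psychometric model and a
  linear response-speed model over the same predictor set used for
  fitting, enabling round-trip parameter recovery.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt, resample_poly
from scipy.signal.windows import hann

from .behavior import PSYCHOMETRIC_TERMS, SPEED_TERMS, recode_pitch
from .signals import EpochSet, SignalTrace, epochs_from_trace

__all__ = [
    "Oscillation",
    "SynthEegSpec",
    "SynthBehaviorSpec",
    "gen_colored_noise",
    "gen_state_modulated_eeg",
    "gen_localizer_epochs",
    "gen_evoked_epochs",
    "gen_pupil",
    "gen_behavior",
    "preprocess_pupil",
    "CleanPupil",
]


# --- specs ----------------------------------------------------------------

@dataclass
class Oscillation:
    """A band-limited oscillation with a slowly fluctuating amplitude.

    The envelope is ``amplitude * exp(OU(t))`` where OU is a zero-mean
    Ornstein-Uhlenbeck process with time constant ``env_tau`` seconds and
    stationary SD ``env_sigma`` (log scale) — positive by construction and
    self-similar on the ``env_tau`` scale.
    """

    freq: float = 10.0
    amplitude: float = 1.0
    env_tau: float = 0.5
    env_sigma: float = 0.6


@dataclass
class SynthEegSpec:
    n_channels: int = 1
    fs: float = 500.0
    duration: float = 60.0
    chi: float = 1.0                       # spectral exponent: power ~ 1/f^chi
    oscillations: List[Oscillation] = field(default_factory=lambda: [Oscillation()])
    topographies: Optional[np.ndarray] = None   # (n_sources, n_channels)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs < 250:
            raise ValueError("fs must be >= 250 Hz")
        if self.chi < 0:
            raise ValueError("spectral exponent must be >= 0")


@dataclass
class SynthBehaviorSpec:
    """Planted coefficients of the psychometric and speed models.

    ``coefs`` are on the logistic (log-odds) scale and keyed by the fit
    term names; ``speed_coefs`` are in 1/s per z-unit.  Unlisted terms are
    zero.
    """

    n_subjects: int = 20
    trials_per_subject: int = 420
    pitch_levels_hz: Sequence[float] = (925.0, 950.0, 975.0, 1000.0,
                                        1025.0, 1050.0, 1075.0)
    coefs: dict = field(default_factory=lambda: {"pitch": 2.5})
    intercept: float = 0.0
    base_speed: float = 2.0                # 1/s, i.e. mean RT ~0.5 s
    speed_coefs: dict = field(default_factory=dict)
    speed_noise_sd: float = 0.2
    seed: int = 0


# --- low-level building blocks -------------------------------------------

def _colored_noise(n: int, fs: float, chi: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise with power spectrum ~ 1/f^chi."""
    white = rng.standard_normal(n)
    if chi == 0:
        return white
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-chi / 2.0)
    if not np.all(np.isfinite(shape)):
        raise ValueError("spectral shaping produced non-finite gains")
    x = np.fft.irfft(spec * shape, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _ou(n: int, fs: float, tau: float, sigma: float,
        rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck samples: acf(k) = exp(-k/(fs*tau))."""
    from scipy.signal import lfilter
    a = np.exp(-1.0 / (fs * tau))
    innov = rng.standard_normal(n) * sigma * np.sqrt(1.0 - a * a)
    x0 = rng.standard_normal() * sigma
    innov[0] = 0.0
    x, _ = lfilter([1.0], [1.0, -a], innov, zi=np.array([a * x0]))
    return x


# --- generators -----------------------------------------------------------

def gen_colored_noise(spec: SynthEegSpec) -> SignalTrace:
    """1/f^chi background noise, one independent process per channel."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    data = np.stack([
        spec.noise_sd * _colored_noise(n, spec.fs, spec.chi, rng)
        for _ in range(spec.n_channels)
    ])
    if spec.n_channels == 1:
        data = data[0]
    return SignalTrace(data, spec.fs)


def gen_state_modulated_eeg(spec: SynthEegSpec):
    """Colored noise plus envelope-modulated oscillations.

    Returns ``(trace, envelope)`` where ``envelope`` is a SignalTrace of
    the total instantaneous oscillatory amplitude — the planted
    synchronization ground truth (high envelope = synchronized = low
    entropy).  With multichannel specs each oscillation is mixed through
    its row of ``topographies``.
    """
    if not spec.oscillations:
        raise ValueError("need at least one oscillation (use gen_colored_noise "
                         "for pure noise)")
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs

    noise = np.stack([spec.noise_sd * _colored_noise(n, spec.fs, spec.chi, rng)
                      for _ in range(spec.n_channels)])
    total_env = np.zeros(n)
    osc_sum = np.zeros((spec.n_channels, n))
    for k, osc in enumerate(spec.oscillations):
        env = osc.amplitude * np.exp(_ou(n, spec.fs, osc.env_tau,
                                         osc.env_sigma, rng))
        phase = rng.uniform(0, 2 * np.pi)
        source = env * np.sin(2 * np.pi * osc.freq * t + phase)
        if spec.topographies is not None:
            topo = np.asarray(spec.topographies, dtype=float)[k]
        else:
            topo = np.ones(spec.n_channels)
        osc_sum += topo[:, None] * source[None, :]
        total_env += env
    data = noise + osc_sum
    if spec.n_channels == 1:
        data = data[0]
    return SignalTrace(data, spec.fs), SignalTrace(total_env, spec.fs)


def gen_localizer_epochs(n_trials: int = 60, n_channels: int = 16,
                         fs: float = 500.0, snr: float = 2.0,
                         topography: Optional[np.ndarray] = None,
                         freq: float = 10.0, seed: int = 0):
    """Localizer-style epochs with one evoked source of known topography.

    Epochs span [-0.2, 0.2) s; the source (a Hann-windowed burst at
    ``freq``) is active only post-stimulus, scaled so its RMS over the
    active window is ``snr`` times the per-channel noise SD.  Returns
    ``(EpochSet, topography)`` for filter-recovery scoring.
    """
    rng = np.random.default_rng(seed)
    if topography is None:
        topography = rng.standard_normal(n_channels)
        topography /= np.linalg.norm(topography)
    topography = np.asarray(topography, dtype=float)
    n_pre = int(round(0.2 * fs))
    n_post = int(round(0.2 * fs))
    n_times = n_pre + n_post
    t_post = np.arange(n_post) / fs
    burst = hann(n_post, sym=True) * np.sin(2 * np.pi * freq * t_post)
    burst = burst / np.sqrt(np.mean(burst ** 2)) if snr > 0 else burst * 0.0

    epochs = rng.standard_normal((n_trials, n_channels, n_times))
    for i in range(n_trials):
        amp = snr * (1.0 + 0.1 * rng.standard_normal())
        epochs[i, :, n_pre:] += amp * topography[:, None] * burst[None, :]
    return EpochSet(epochs, fs, tmin=-n_pre / fs), topography


def gen_evoked_epochs(n_trials: int, phase_locked_fraction: float,
                      jitter: float = 0.0, freq: float = 10.0,
                      fs: float = 500.0, noise_sd: float = 0.1,
                      seed: int = 0) -> EpochSet:
    """Tone-evoked epochs with a controllable phase-locked fraction q.

    Each trial's response is ``q`` parts fixed-phase plus ``1 - q`` parts
    random-phase oscillation under a 0-300 ms Hann envelope, plus white
    noise; ``jitter`` (s, SD) shifts the response latency per trial.
    Epochs span [-0.5, 1.0) s.
    """
    q = phase_locked_fraction
    if not 0.0 <= q <= 1.0:
        raise ValueError("phase_locked_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    tmin, tmax = -0.5, 1.0
    n_times = int(round((tmax - tmin) * fs))
    t = tmin + np.arange(n_times) / fs
    resp_len = 0.3
    epochs = noise_sd * rng.standard_normal((n_trials, n_times))
    for i in range(n_trials):
        t0 = jitter * rng.standard_normal()
        tt = t - t0
        env = np.where((tt >= 0) & (tt < resp_len),
                       0.5 * (1 - np.cos(2 * np.pi * tt / resp_len)), 0.0)
        phi = rng.uniform(0, 2 * np.pi)
        resp = (q * np.cos(2 * np.pi * freq * tt)
                + (1 - q) * np.cos(2 * np.pi * freq * tt + phi))
        epochs[i] += env * resp
    return EpochSet(epochs, fs, tmin=tmin)


BLINK_RAMP = 0.020        # s, down/up ramps
BLINK_HOLD = 0.150        # s, near-zero plateau


def gen_pupil(duration: float, fs: float = 500.0, blink_rate: float = 0.2,
              seed: int = 0, baseline: float = 5.0, sd: float = 0.5,
              tau: float = 2.0):
    """Pupil-diameter trace: slow mean-reverting fluctuation plus blinks.

    The diameter follows ``baseline + OU(tau=2 s)`` (arbitrary units);
    blinks arrive as a Poisson process at ``blink_rate`` Hz and are
    rendered as 150 ms near-zero plateaus with 20 ms cosine ramps.
    Returns ``(trace, blink_onsets)`` with onsets in seconds.
    """
    if blink_rate < 0:
        raise ValueError("blink_rate must be >= 0")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    # smooth the mean-reverting diameter (measured pupil traces carry no
    # sample-to-sample jitter at 500 Hz) before rendering blinks
    raw = _ou(n, fs, tau, sd, rng)
    b_s, a_s = butter(2, 2.0, btype="low", fs=fs)
    x = baseline + filtfilt(b_s, a_s, raw)
    t = np.arange(n) / fs

    blinks = []
    if blink_rate > 0:
        now = rng.exponential(1.0 / blink_rate)
        total_blink = 2 * BLINK_RAMP + BLINK_HOLD
        while now < duration - total_blink:
            blinks.append(now)
            now += total_blink + rng.exponential(1.0 / blink_rate)
    for b in blinks:
        rel = t - b
        down = (rel >= 0) & (rel < BLINK_RAMP)
        hold = (rel >= BLINK_RAMP) & (rel < BLINK_RAMP + BLINK_HOLD)
        up = (rel >= BLINK_RAMP + BLINK_HOLD) & (rel < 2 * BLINK_RAMP + BLINK_HOLD)
        x[down] *= 0.5 * (1 + np.cos(np.pi * rel[down] / BLINK_RAMP))
        x[hold] *= 0.0
        x[up] *= 0.5 * (1 - np.cos(np.pi * (rel[up] - BLINK_RAMP - BLINK_HOLD)
                                   / BLINK_RAMP))
    return SignalTrace(x, fs), np.asarray(blinks)


def gen_behavior(spec: SynthBehaviorSpec,
                 state_covariates: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Draw trials from the planted psychometric and speed models.

    Covariates (pre-stimulus entropy, pupil, baseline entropy) are standard
    normal per subject unless supplied via ``state_covariates`` (columns
    ``pre_entropy``, ``pre_pupil``, ``baseline_entropy``; must be z-scored).
    Responses are Bernoulli draws from the logistic over the full fit term
    set; RTs invert the planted speed model, truncated to a plausible
    range.  Returns a trial table ready for the fitting functions.
    """
    rng = np.random.default_rng(spec.seed)
    levels = np.asarray(spec.pitch_levels_hz, dtype=float)
    pitch_norm_levels = recode_pitch(levels)
    rows = []
    for s in range(spec.n_subjects):
        npt = spec.trials_per_subject
        reps = int(np.ceil(npt / len(levels)))
        order = rng.permutation(np.tile(np.arange(len(levels)), reps))[:npt]
        if state_covariates is not None:
            cov = state_covariates.iloc[:npt]
            ent = cov["pre_entropy"].to_numpy()
            pup = cov["pre_pupil"].to_numpy()
            base_ent = cov["baseline_entropy"].to_numpy()
        else:
            ent = rng.standard_normal(npt)
            pup = rng.standard_normal(npt)
            base_ent = rng.standard_normal(npt)
        trial_number = np.arange(1, npt + 1, dtype=float)
        znum = (trial_number - trial_number.mean()) / trial_number.std(ddof=1)
        terms = {
            "pitch": pitch_norm_levels[order],
            "entropy": ent, "entropy_sq": ent ** 2,
            "pupil": pup, "pupil_sq": pup ** 2,
            "baseline_entropy": base_ent, "trial_number": znum,
        }
        terms["pitch:entropy"] = terms["pitch"] * ent
        terms["pitch:entropy_sq"] = terms["pitch"] * ent ** 2
        terms["pitch:pupil"] = terms["pitch"] * pup
        terms["pitch:pupil_sq"] = terms["pitch"] * pup ** 2

        eta = np.full(npt, spec.intercept)
        for name in PSYCHOMETRIC_TERMS:
            eta += spec.coefs.get(name, 0.0) * terms[name]
        if np.any(np.abs(eta) > 30):
            warnings.warn("logistic linear predictor clamped to +/-30")
            eta = np.clip(eta, -30, 30)
        p_high = 1.0 / (1.0 + np.exp(-eta))
        response = (rng.uniform(size=npt) < p_high).astype(int)

        speed = np.full(npt, spec.base_speed)
        for name in SPEED_TERMS:
            speed += spec.speed_coefs.get(name, 0.0) * terms[name]
        speed += spec.speed_noise_sd * rng.standard_normal(npt)
        speed = np.clip(speed, 1.0 / 1.95, 1.0 / 0.25)
        rt = 1.0 / speed

        rows.append(pd.DataFrame({
            "subject": s + 1,
            "trial_number": trial_number,
            "pitch_hz": levels[order],
            "pitch_norm": terms["pitch"],
            "pre_entropy": ent,
            "pre_pupil": pup,
            "baseline_entropy": base_ent,
            "response": response,
            "rt": rt,
        }))
    return pd.concat(rows, ignore_index=True)


# --- pupil preprocessing --------------------------------------------------

@dataclass
class CleanPupil:
    trace: SignalTrace                 # cleaned, 50 Hz
    epochs: Optional[EpochSet] = None  # peristimulus epochs when events given
    edge_blink: bool = False           # a blink span touched a trace edge


def preprocess_pupil(trace: SignalTrace, blinks,
                     events: Optional[np.ndarray] = None,
                     epoch_window: tuple = (-2.5, 3.0),
                     out_fs: float = 50.0,
                     span_pad: float = 0.03) -> CleanPupil:
    """Clean a pupil trace: spline-interpolate blinks, low-pass, resample.

    Samples within each blink span (ramps + plateau, padded by
    ``span_pad`` s on both sides) are replaced by a cubic-spline
    interpolation through the surrounding clean samples; a span touching
    a trace edge is filled with the nearest clean value and flagged.  The
    result is zero-phase low-pass filtered below 20 Hz, resampled to
    ``out_fs`` (default 50 Hz), and — when stimulus ``events`` (s) are
    given — epoched over ``epoch_window`` (default -2.5 to 3 s
    peristimulus).
    """
    if trace.data.ndim != 1:
        raise ValueError("pupil trace must be single-channel")
    x = trace.data.copy()
    t = trace.times
    fs = trace.fs
    total = 2 * BLINK_RAMP + BLINK_HOLD
    bad = np.zeros(len(x), dtype=bool)
    for b in np.atleast_1d(np.asarray(blinks, dtype=float)):
        bad |= (t >= b - span_pad) & (t < b + total + span_pad)
    edge = bool(bad[0] or bad[-1])
    if bad.any():
        good = ~bad
        if good.sum() < 4:
            raise ValueError("not enough clean samples to interpolate")
        spline = CubicSpline(t[good], x[good])
        fill = spline(t[bad])
        # nearest-value extension outside the clean support
        fill = np.where(t[bad] < t[good][0], x[good][0], fill)
        fill = np.where(t[bad] > t[good][-1], x[good][-1], fill)
        x[bad] = fill

    b_lp, a_lp = butter(4, 20.0, btype="low", fs=fs)
    x = filtfilt(b_lp, a_lp, x)

    from fractions import Fraction
    frac = Fraction(out_fs / fs).limit_denominator(1000)
    x50 = resample_poly(x, frac.numerator, frac.denominator)
    clean = SignalTrace(x50, out_fs, trace.t0)

    epochs = None
    if events is not None and len(np.atleast_1d(events)) > 0:
        epochs = epochs_from_trace(clean, np.atleast_1d(events), *epoch_window)
    return CleanPupil(trace=clean, epochs=epochs, edge_blink=edge)
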