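"""Streaming entropy and the closed-loop desynchronization classifier.

The real-time pipeline projects incoming multichannel EEG to one virtual
channel, computes sliding-window WPE, and maintains an adaptive distribution
of recent entropy values (a "forgetting window", default 30 s).  A high
(low) desynchronization state is declared when a minimum number of
consecutive entropy samples — default 10, i.e. 100 ms at the 100 Hz entropy
rate — lie strictly above the 90th (strictly below the 10th) percentile of
that distribution.  Because the criterion is relative to the recent past, it
adapts to slow drifts and samples the whole desynchronization state space
rather than splitting a fixed bimodal distribution.

Eye blinks synchronize the EEG and would masquerade as low states, so a 1 s
"mute" window after each blink removes entropy samples from both the
distribution and the run criterion.  Muted samples are invisible: they do
not reset a partially accumulated run.

On every state detection the closed-loop driver presents a tone drawn from
the remaining per-state schedule (7 pitch levels x 30 presentations per
state by default, 420 trials in total) and suspends detection for a
refractory period covering tone, response window and inter-trial pause.
"""

from __future__ import annotations

import bisect
from collections import deque
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .signals import EntropyStream, SignalTrace
from .wpe import WpeParams, wpe, wpe_series

__all__ = [
    "ClassifierParams",
    "StateEvent",
    "RollingDistribution",
    "StreamingWpe",
    "OnlineClassifier",
    "classify_stream",
    "ToneSchedule",
    "ClosedLoopResult",
    "run_closed_loop",
]


@dataclass(frozen=True)
class ClassifierParams:
    """Adaptive state-classification parameters.

    ``forgetting_window`` is the rolling span (s) of the entropy
    distribution; ``high_percentile``/``low_percentile`` set the adaptive
    thresholds; ``consecutive_required`` entropy samples must lie strictly
    beyond a threshold to declare a state; ``mute_duration`` (s) silences
    samples after a blink; ``refractory`` (s) suspends detection after a
    triggered tone (default covers 100 ms tone + 2 s response window + 6 s
    pause, reproducing the observed ~9 s tone-to-tone spacing).
    """

    forgetting_window: float = 30.0
    high_percentile: float = 90.0
    low_percentile: float = 10.0
    consecutive_required: int = 10
    mute_duration: float = 1.0
    refractory: float = 8.1

    def __post_init__(self) -> None:
        if not (0.0 < self.low_percentile < self.high_percentile < 100.0):
            raise ValueError("need 0 < low_percentile < high_percentile < 100")
        if self.consecutive_required < 1:
            raise ValueError("consecutive_required must be >= 1")


@dataclass
class StateEvent:
    """A classified high/low desynchronization onset."""

    onset_time: float
    label: str                      # "high" | "low"
    threshold_high: float
    threshold_low: float
    entropy_at_onset: float


class RollingDistribution:
    """Entropy samples within the forgetting window, with percentile queries.

    Percentiles use linear interpolation between order statistics
    (numpy's default), e.g. the 90th percentile of 1..100 is 90.1.
    """

    def __init__(self, forgetting_window: float):
        self.forgetting_window = forgetting_window
        self._times: deque = deque()
        self._values: deque = deque()
        self._sorted: list = []            # buffered values kept sorted
        self._last_time: Optional[float] = None

    def __len__(self) -> int:
        return len(self._values)

    @property
    def span(self) -> float:
        """Time covered by buffered samples (0 if fewer than two)."""
        if len(self._times) < 2:
            return 0.0
        return self._times[-1] - self._times[0]

    def push(self, value: float, time: float) -> None:
        if self._last_time is not None and time <= self._last_time:
            raise ValueError("sample times must be strictly increasing")
        self._last_time = time
        self._times.append(time)
        self._values.append(value)
        bisect.insort(self._sorted, value)
        self.evict(time)

    def evict(self, now: float) -> None:
        cutoff = now - self.forgetting_window
        while self._times and self._times[0] <= cutoff:
            self._times.popleft()
            old = self._values.popleft()
            del self._sorted[bisect.bisect_left(self._sorted, old)]

    def percentile(self, q: float) -> float:
        """Linear interpolation between order statistics (numpy default)."""
        if not self._sorted:
            raise ValueError("empty distribution")
        arr = self._sorted
        k = (len(arr) - 1) * q / 100.0
        f = int(np.floor(k))
        c = min(f + 1, len(arr) - 1)
        return float(arr[f] + (arr[c] - arr[f]) * (k - f))

    def values(self) -> np.ndarray:
        return np.fromiter(self._values, dtype=float)


class StreamingWpe:
    """Sample-by-sample WPE identical to the batch sliding-window estimate.

    Raw samples are pushed in arbitrary chunk sizes; whenever enough samples
    complete the next window placement, one entropy value is emitted stamped
    at the window's last sample.  The emitted sequence equals
    :func:`~desyncloop.wpe.wpe_series` on the concatenated signal.
    """

    def __init__(self, params: WpeParams, fs: float, t0: float = 0.0):
        self.params = params
        self.fs = fs
        self.t0 = t0
        self._buf = np.empty(0)
        self._buf_start = 0       # absolute index of _buf[0]
        self._next_start = 0      # absolute start index of the next window

    def push(self, chunk) -> List[tuple]:
        """Feed raw samples; return [(time, value), ...] newly completed."""
        chunk = np.atleast_1d(np.asarray(chunk, dtype=float))
        self._buf = np.concatenate([self._buf, chunk])
        out = []
        L, s = self.params.window_length, self.params.step
        while self._buf_start + len(self._buf) >= self._next_start + L:
            lo = self._next_start - self._buf_start
            window = self._buf[lo:lo + L]
            t = self.t0 + (self._next_start + L - 1) / self.fs
            out.append((t, wpe(window, self.params)))
            self._next_start += s
        drop = self._next_start - self._buf_start
        if drop > 0:
            self._buf = self._buf[drop:]
            self._buf_start = self._next_start
        return out


class OnlineClassifier:
    """Incremental high/low state detector over an entropy stream.

    Per entropy sample the thresholds are re-evaluated against the current
    rolling distribution (the distribution is updated constantly, including
    during candidate runs and refractory periods).  Strict inequalities are
    used, so a constant stream never triggers.  A sample failing the
    criterion resets the run counter; muted samples neither count nor
    reset.  No events are emitted until the buffered samples span at least
    half the forgetting window (cold-start warm-up).
    """

    def __init__(self, params: ClassifierParams,
                 blink_times: Optional[Sequence[float]] = None,
                 auto_refractory: bool = True):
        self.p = params
        self.auto_refractory = auto_refractory
        self.dist = RollingDistribution(params.forgetting_window)
        self.blinks = np.sort(np.asarray(blink_times if blink_times is not None
                                         else [], dtype=float))
        self._run_len = 0
        self._run_label: Optional[str] = None
        self._suspended_until = -np.inf

    def is_muted(self, t: float) -> bool:
        """True if t falls in [blink, blink + mute_duration) for any blink."""
        i = bisect.bisect_right(self.blinks, t)
        return i > 0 and t < self.blinks[i - 1] + self.p.mute_duration

    def suspend_until(self, t: float) -> None:
        self._suspended_until = t
        self._run_len = 0
        self._run_label = None

    @property
    def warmed_up(self) -> bool:
        return self.dist.span >= self.p.forgetting_window / 2.0

    def push(self, time: float, value: float) -> Optional[StateEvent]:
        if self.is_muted(time):
            return None
        self.dist.evict(time)
        event = None
        warmed = self.warmed_up
        if len(self.dist) >= 2 and time > self._suspended_until:
            thr_hi = self.dist.percentile(self.p.high_percentile)
            thr_lo = self.dist.percentile(self.p.low_percentile)
            if value > thr_hi:
                label = "high"
            elif value < thr_lo:
                label = "low"
            else:
                label = None
            if label is None:
                self._run_len, self._run_label = 0, None
            elif label == self._run_label:
                self._run_len += 1
            else:
                self._run_len, self._run_label = 1, label
            if warmed and self._run_label and self._run_len >= self.p.consecutive_required:
                event = StateEvent(onset_time=time, label=self._run_label,
                                   threshold_high=thr_hi, threshold_low=thr_lo,
                                   entropy_at_onset=value)
                self._run_len, self._run_label = 0, None
                if self.auto_refractory:
                    self._suspended_until = time + self.p.refractory
        else:
            self._run_len, self._run_label = 0, None
        self.dist.push(value, time)
        return event


def classify_stream(entropy: EntropyStream,
                    blinks: Optional[Sequence[float]] = None,
                    params: ClassifierParams = ClassifierParams()) -> List[StateEvent]:
    """Run the adaptive classifier over a complete entropy stream."""
    clf = OnlineClassifier(params, blinks)
    events = []
    for t, v in zip(entropy.times, entropy.values):
        ev = clf.push(float(t), float(v))
        if ev is not None:
            events.append(ev)
    return events


@dataclass
class ToneSchedule:
    """Balanced tone schedule: every pitch level is presented equally often
    in each state (default 7 levels x 30 per state = 210 trials per state,
    420 in total)."""

    pitch_levels_hz: Sequence[float] = (925.0, 950.0, 975.0, 1000.0,
                                        1025.0, 1050.0, 1075.0)
    per_pitch_per_state: int = 30

    def quota(self) -> dict:
        return {state: {p: self.per_pitch_per_state for p in self.pitch_levels_hz}
                for state in ("high", "low")}


@dataclass
class ClosedLoopResult:
    trials: pd.DataFrame
    events: List[StateEvent]
    entropy: EntropyStream
    complete: bool
    warning: Optional[str] = None


def run_closed_loop(eeg: SignalTrace,
                    filter_weights: Optional[np.ndarray],
                    blinks: Optional[Sequence[float]],
                    params: ClassifierParams = ClassifierParams(),
                    schedule: ToneSchedule = None,
                    wpe_params: WpeParams = WpeParams(),
                    rng: np.random.Generator | int | None = 0,
                    average_ref: bool = True) -> ClosedLoopResult:
    """Simulate one closed-loop session offline.

    Projects the EEG through the spatial-filter weights to one virtual
    channel, computes the streaming entropy series, classifies states, and
    on each detected state draws a tone pitch (uniformly among levels whose
    per-state quota remains) and records a trial.  Detection is suspended
    for the refractory period after each presented tone; events arriving for
    a state whose quota is exhausted present no tone and incur no
    refractory.  The run stops when both quotas are exhausted or the signal
    ends (then ``complete=False`` with a warning).
    """
    if schedule is None:
        schedule = ToneSchedule()
    rng = np.random.default_rng(rng)

    if eeg.data.ndim == 2:
        data = eeg.data
        if average_ref and eeg.n_channels > 1:
            data = data - data.mean(axis=0, keepdims=True)
        if filter_weights is None:
            raise ValueError("multichannel input requires filter weights")
        w = np.asarray(filter_weights, dtype=float)
        if w.shape != (data.shape[0],):
            raise ValueError("filter weights do not match channel count")
        virtual = SignalTrace(w @ data, eeg.fs, eeg.t0)
    else:
        virtual = eeg

    stream = wpe_series(virtual, wpe_params)
    clf = OnlineClassifier(params, blinks, auto_refractory=False)
    quota = schedule.quota()
    remaining = {s: sum(q.values()) for s, q in quota.items()}

    records, events = [], []
    pre_win = 0.2
    for t, v in zip(stream.times, stream.values):
        ev = clf.push(float(t), float(v))
        if ev is None:
            continue
        events.append(ev)
        if remaining[ev.label] == 0:
            continue            # quota done: no tone, no refractory
        pitches = [p for p, n in quota[ev.label].items() if n > 0]
        pitch = float(rng.choice(pitches))
        quota[ev.label][pitch] -= 1
        remaining[ev.label] -= 1
        clf.suspend_until(ev.onset_time + params.refractory)
        mask = (stream.times >= ev.onset_time - pre_win) & (stream.times < ev.onset_time)
        pre_entropy = float(stream.values[mask].mean()) if mask.any() else np.nan
        records.append({
            "trial": len(records) + 1,
            "trigger_time_s": ev.onset_time,
            "state_label": ev.label,
            "pitch_hz": pitch,
            "pre_entropy": pre_entropy,
            "entropy_at_onset": ev.entropy_at_onset,
            "threshold_high": ev.threshold_high,
            "threshold_low": ev.threshold_low,
        })
        if remaining["high"] == 0 and remaining["low"] == 0:
            break

    complete = remaining["high"] == 0 and remaining["low"] == 0
    warning = None if complete else (
        f"signal ended with quotas remaining: high={remaining['high']}, "
        f"low={remaining['low']}")
    trials = pd.DataFrame(records)
    return ClosedLoopResult(trials=trials, events=events, entropy=stream,
                            complete=complete, warning=warning)
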