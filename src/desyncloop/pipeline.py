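"""End-to-end orchestration of a simulated closed-loop session.

One call to :func:`run_experiment` performs the full stack: simulate
multichannel EEG with a planted synchronization envelope and a pupil trace
with blinks; estimate the spatial filter from simulated localizer epochs;
run the streaming entropy classifier against the virtual channel; present
tones according to the balanced per-state schedule; derive trial-wise
pre-stimulus covariates; draw behavior from the planted psychometric model;
fit the psychometric and speed models; and write all artifacts (trial
table, entropy stream, state events, fit reports, QC summary) to an output
directory.  The whole run is deterministic under its seed.

The trial table is delimited text with a fixed column order::

    subject  block  trial  pitch_hz  pitch_norm  state_label
    trigger_time_s  pre_entropy  baseline_entropy  pre_pupil  response  rt_s

Missing values are empty fields; files carry ``#`` headers documenting the
epoch convention (time 0 = tone onset, half-open windows, 0-based samples).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as bh
from . import synth
from .signals import SignalTrace
from .spatial import compute_filter
from .streaming import ClassifierParams, ToneSchedule, run_closed_loop
from .wpe import WpeParams

__all__ = ["RunConfig", "adaptive_tracking", "run_tracking", "run_experiment",
           "load_config", "save_config", "TRIAL_COLUMNS"]

TRIAL_COLUMNS = ["subject", "block", "trial", "pitch_hz", "pitch_norm",
                 "state_label", "trigger_time_s", "pre_entropy",
                 "baseline_entropy", "pre_pupil", "response", "rt_s"]

TRIALS_PER_BLOCK = 42        # 10 blocks x 42 trials = 420 trials


@dataclass
class RunConfig:
    """Everything one simulated session needs; defaults mirror the original
    closed-loop setup except where noted.

    ``refractory`` defaults to 1 s in the simulator so a complete 420-trial
    schedule fits in a few simulated minutes; the hardware-paced value
    (8.1 s: tone + response window + pause) is available through
    ``ClassifierParams``.
    """

    seed: int = 0
    subject: int = 1
    out_dir: str = "desyncloop_run"
    # --- simulated EEG
    n_channels: int = 16
    fs: float = 1000.0
    duration: float = 1500.0
    chi: float = 1.0
    osc_freq: float = 10.0
    osc_amplitude: float = 1.0
    osc_env_tau: float = 0.5
    osc_env_sigma: float = 0.6
    # --- pupil
    blink_rate: float = 0.2
    # --- entropy estimator
    wpe: WpeParams = field(default_factory=WpeParams)
    # --- classifier
    classifier: ClassifierParams = field(
        default_factory=lambda: ClassifierParams(refractory=1.0))
    # --- tone schedule
    pitch_levels_hz: tuple = (925.0, 950.0, 975.0, 1000.0, 1025.0, 1050.0, 1075.0)
    per_pitch_per_state: int = 30
    # --- planted behavior (logistic scale / 1/s per z-unit)
    behavior_coefs: dict = field(default_factory=lambda: {
        "pitch": 2.5, "entropy": 0.1, "entropy_sq": -0.3,
        "pitch:entropy": 0.15, "pupil": 0.1, "pupil_sq": -0.1,
    })
    speed_coefs: dict = field(default_factory=lambda: {"entropy_sq": -0.05})
    base_speed: float = 2.0
    speed_noise_sd: float = 0.2
    # --- analysis windows (s, half-open, 0 = tone onset)
    pre_entropy_window: tuple = (-0.2, 0.0)
    pre_pupil_window: tuple = (-0.5, 0.0)
    baseline_entropy_window: tuple = (-3.0, 0.0)


def adaptive_tracking(block_accuracy: float, current_width: float,
                      factor: float = 1.2) -> float:
    """One round of the difficulty-tracking rule for the pitch-set width:
    widen below 70% correct, narrow above 80%, otherwise keep."""
    if current_width <= 0:
        raise ValueError("width must be positive")
    if not 0.0 <= block_accuracy <= 1.0:
        raise ValueError("accuracy must lie in [0, 1]")
    if block_accuracy < 0.70:
        return current_width * factor
    if block_accuracy > 0.80:
        return current_width / factor
    return current_width


def run_tracking(accuracies, initial_width: float, factor: float = 1.2,
                 max_rounds: int = 4) -> float:
    """Apply up to four tracking rounds (50 trials each in the original
    procedure); the width after the last round defines the stimulus set."""
    width = initial_width
    for acc in list(accuracies)[:max_rounds]:
        width = adaptive_tracking(acc, width, factor)
    return width


def _window_mean(times: np.ndarray, values: np.ndarray, t_event: float,
                 window: tuple) -> float:
    mask = (times >= t_event + window[0]) & (times < t_event + window[1])
    return float(values[mask].mean()) if mask.any() else np.nan


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd if sd > 0 else x * 0.0


def run_experiment(config: RunConfig, write: bool = True) -> dict:
    """Run one full simulated session; return the report dict.

    Artifacts written to ``config.out_dir``: ``trials.tsv``,
    ``entropy.tsv``, ``events.tsv``, ``report.json``, ``config.yaml``.
    """
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, 2**31 - 1, size=8)

    # 1) spatial filter from localizer epochs with a planted topography
    topo_rng = np.random.default_rng(int(seeds[0]))
    topography = topo_rng.standard_normal(config.n_channels)
    topography /= np.linalg.norm(topography)
    locepochs, _ = synth.gen_localizer_epochs(
        n_trials=60, n_channels=config.n_channels, fs=config.fs,
        snr=2.0, topography=topography, seed=int(seeds[1]))
    sig = _slice_epochs(locepochs, 0.0, 0.2)
    noi = _slice_epochs(locepochs, -0.2, 0.0)
    weights = compute_filter(sig, noi)

    # 2) ongoing EEG: the synchronization source shares the topography
    spec = synth.SynthEegSpec(
        n_channels=config.n_channels, fs=config.fs, duration=config.duration,
        chi=config.chi,
        oscillations=[synth.Oscillation(freq=config.osc_freq,
                                        amplitude=config.osc_amplitude,
                                        env_tau=config.osc_env_tau,
                                        env_sigma=config.osc_env_sigma)],
        topographies=topography[None, :], seed=int(seeds[2]))
    eeg, envelope = synth.gen_state_modulated_eeg(spec)

    # 3) pupil with blinks
    pupil_raw, blinks = synth.gen_pupil(config.duration, fs=config.fs,
                                        blink_rate=config.blink_rate,
                                        seed=int(seeds[3]))
    pupil = synth.preprocess_pupil(pupil_raw, blinks).trace

    # 4) closed loop
    schedule = ToneSchedule(pitch_levels_hz=config.pitch_levels_hz,
                            per_pitch_per_state=config.per_pitch_per_state)
    loop = run_closed_loop(eeg, weights.weights, blinks,
                           params=config.classifier, schedule=schedule,
                           wpe_params=config.wpe, rng=int(seeds[4]))
    trials = loop.trials
    if len(trials) == 0:
        raise RuntimeError("closed loop produced no trials")

    # 5) trial covariates
    ent_t, ent_v = loop.entropy.times, loop.entropy.values
    pup_t, pup_v = pupil.times, pupil.data
    env_t, env_v = envelope.times, envelope.data
    trig = trials["trigger_time_s"].to_numpy()
    trials = trials.assign(
        baseline_entropy=[_window_mean(ent_t, ent_v, t,
                                       config.baseline_entropy_window)
                          for t in trig],
        pre_pupil=[_window_mean(pup_t, pup_v, t, config.pre_pupil_window)
                   for t in trig],
        true_envelope=[_window_mean(env_t, env_v, t,
                                    config.pre_entropy_window)
                       for t in trig],
    )

    # 6) behavior from the planted model on z-scored covariates
    cov = pd.DataFrame({
        "pre_entropy": _zscore(trials["pre_entropy"].to_numpy()),
        "pre_pupil": _zscore(trials["pre_pupil"].to_numpy()),
        "baseline_entropy": _zscore(trials["baseline_entropy"].to_numpy()),
    })
    bspec = synth.SynthBehaviorSpec(
        n_subjects=1, trials_per_subject=len(trials),
        pitch_levels_hz=config.pitch_levels_hz,
        coefs=config.behavior_coefs, speed_coefs=config.speed_coefs,
        base_speed=config.base_speed, speed_noise_sd=config.speed_noise_sd,
        seed=int(seeds[5]))
    beh = synth.gen_behavior(bspec, state_covariates=cov)
    # keep the closed-loop pitch draw, not the generator's balanced one
    beh = beh.drop(columns=["pitch_hz", "pitch_norm"])
    table = pd.concat([trials.reset_index(drop=True),
                       beh[["response", "rt"]].reset_index(drop=True)], axis=1)
    table["pitch_norm"] = bh.recode_pitch(np.asarray(config.pitch_levels_hz))[
        [list(config.pitch_levels_hz).index(p) for p in table["pitch_hz"]]]
    # responses must be regenerated for the actual pitch of each trial
    eta = np.full(len(table), bspec.intercept)
    terms = {
        "pitch": table["pitch_norm"].to_numpy(),
        "entropy": cov["pre_entropy"].to_numpy(),
        "pupil": cov["pre_pupil"].to_numpy(),
        "baseline_entropy": cov["baseline_entropy"].to_numpy(),
        "trial_number": _zscore(table["trial"].to_numpy(dtype=float)),
    }
    terms["entropy_sq"] = terms["entropy"] ** 2
    terms["pupil_sq"] = terms["pupil"] ** 2
    for name in bh.PSYCHOMETRIC_TERMS:
        if ":" in name:
            a, b = name.split(":")
            terms[name] = terms[a] * terms[b]
        eta += config.behavior_coefs.get(name, 0.0) * terms[name]
    resp_rng = np.random.default_rng(int(seeds[6]))
    table["response"] = (resp_rng.uniform(size=len(table))
                         < 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))).astype(int)

    table["subject"] = config.subject
    table["block"] = (table["trial"] - 1) // TRIALS_PER_BLOCK + 1
    table["pre_entropy_z"] = cov["pre_entropy"]
    table["pre_pupil_z"] = cov["pre_pupil"]
    table["baseline_entropy_z"] = cov["baseline_entropy"]
    table = table.rename(columns={"rt": "rt_s"})

    # 7) model fits on the session's trials
    fit_df = pd.DataFrame({
        "subject": table["subject"],
        "pitch_norm": table["pitch_norm"],
        "pre_entropy": table["pre_entropy_z"],
        "pre_pupil": table["pre_pupil_z"],
        "baseline_entropy": table["baseline_entropy_z"],
        "trial_number": _zscore(table["trial"].to_numpy(dtype=float)),
        "response": table["response"],
        "rt": table["rt_s"],
    })
    psych = bh.fit_psychometric(fit_df)
    speed = bh.fit_speed(bh.filter_rts(fit_df))
    wz = bh.wald_z(psych, "entropy_sq", "pupil_sq")
    state_terms = ["entropy", "entropy_sq", "pupil", "pupil_sq"]
    p_adj = bh.fdr_adjust(psych.table.loc[state_terms, "p"].to_numpy())

    by_state = table.groupby("state_label")["pre_entropy"].mean()
    report = {
        "seed": config.seed,
        "n_trials": int(len(table)),
        "n_blocks": int(table["block"].max()),
        "trials_per_state": {k: int(v) for k, v in
                             table["state_label"].value_counts().items()},
        "complete": bool(loop.complete),
        "warning": loop.warning,
        "qc": {
            "mean_pre_entropy_high": float(by_state.get("high", np.nan)),
            "mean_pre_entropy_low": float(by_state.get("low", np.nan)),
            "mean_true_envelope_high": float(
                table.loc[table.state_label == "high", "true_envelope"].mean()),
            "mean_true_envelope_low": float(
                table.loc[table.state_label == "low", "true_envelope"].mean()),
            "n_state_events": len(loop.events),
        },
        "psychometric": _fit_to_dict(psych),
        "speed": _fit_to_dict(speed),
        "wald_z_entropy_sq_vs_pupil_sq": float(wz),
        "fdr_adjusted_state_p": dict(zip(state_terms, map(float, p_adj))),
    }

    if write:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_trials(out / "trials.tsv", table)
        pd.DataFrame({"time_s": ent_t, "wpe": ent_v}).to_csv(
            out / "entropy.tsv", sep="\t", index=False, float_format="%.10g")
        pd.DataFrame([dataclasses.asdict(e) for e in loop.events]).to_csv(
            out / "events.tsv", sep="\t", index=False, float_format="%.10g")
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        save_config(out / "config.yaml", config)
    return report


def _slice_epochs(epochs, t0: float, t1: float):
    from .signals import EpochSet
    i0 = int(round((t0 - epochs.tmin) * epochs.fs))
    i1 = int(round((t1 - epochs.tmin) * epochs.fs))
    return EpochSet(epochs.epochs[:, :, i0:i1], epochs.fs, tmin=t0)


def _fit_to_dict(fit) -> dict:
    return {
        "link": fit.link,
        "n_obs": fit.n_obs,
        "r2": float(fit.r2),
        "bic": float(fit.bic),
        "terms": {name: {k: float(row[k]) for k in ("estimate", "se", "z", "p")}
                  for name, row in fit.table.iterrows()},
    }


def _write_trials(path, table: pd.DataFrame) -> None:
    out = table[[c for c in TRIAL_COLUMNS if c in table]]
    with open(path, "w") as fh:
        fh.write("# time 0 = tone onset; half-open windows; 0-based samples\n")
        out.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_trials(path) -> pd.DataFrame:
    """Read a trial table written by :func:`run_experiment`."""
    return pd.read_csv(path, sep="\t", comment="#")


# --- config I/O -----------------------------------------------------------

def save_config(path, config: RunConfig) -> None:
    d = dataclasses.asdict(config)
    d["wpe"] = dataclasses.asdict(config.wpe)
    d["classifier"] = dataclasses.asdict(config.classifier)
    d["pitch_levels_hz"] = list(config.pitch_levels_hz)
    for key in ("pre_entropy_window", "pre_pupil_window",
                "baseline_entropy_window"):
        d[key] = list(d[key])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["wpe"] = WpeParams(**d["wpe"])
    d["classifier"] = ClassifierParams(**d["classifier"])
    d["pitch_levels_hz"] = tuple(d["pitch_levels_hz"])
    for key in ("pre_entropy_window", "pre_pupil_window",
                "baseline_entropy_window"):
        d[key] = tuple(d[key])
    return RunConfig(**d)
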