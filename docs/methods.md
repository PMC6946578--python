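# Methods

This note documents the models implemented in `desyncloop`, the parameter
choices that matter, what the synthetic-data generators do and do not
emulate, and the numerical conventions adopted where the procedure leaves
room for choice.

## Weighted permutation entropy

WPE maps every delay sub-vector of length `m` (delay `tau` samples) to its
ordinal motif and weights each occurrence by the sub-vector's population
variance, so high-amplitude structure dominates the motif distribution and
near-flat segments contribute little.  The entropy of the weighted motif
distribution, normalized by `log(m!)`, is the desynchronization proxy:
synchronized (oscillation-dominated) activity concentrates probability on
few motifs and lowers WPE; irregular activity spreads it and raises WPE.

Parameters and defaults:

| parameter | default | meaning |
|---|---|---|
| `m` | 3 | motif length; 6 possible motifs |
| `tau` | 1 sample | delay between motif elements |
| `window_length` | 200 samples | sliding estimation window |
| `step` | 10 samples | window advance; entropy rate = `fs / step` |
| `normalize` | on | divide by `log m!` so WPE is in [0, 1] |
| `log_base` | natural | `two` gives bits |

Conventions: rank ties are broken by temporal order (the stable
Bandt–Pompe convention; the earlier sample gets the lower rank), so
constant sub-vectors map to the ascending motif.  A window whose
sub-vectors are all constant has zero total weight; it is flagged
degenerate and assigned entropy 0, the limit of a single-motif
distribution.  Each entropy value is time-stamped at its window's **last**
sample, so streaming state decisions never use future data; the streaming
estimator is tested sample-for-sample identical (1e-12) to the batch path
for arbitrary chunk sizes.  The sliding implementation computes motif codes
and weights once per sub-vector and obtains per-window motif masses from
cumulative sums, making a full session O(T·m!).

Normalization defaults to on because the classifier's percentile criterion
is scale-free either way and bounded values simplify downstream logit
transforms; the unnormalized mode is retained.

## Adaptive state classification

The classifier holds entropy samples in a rolling buffer spanning a 30 s
*forgetting window* and re-evaluates the 90th/10th percentile thresholds
against it at every sample ("updated constantly"), so the criterion adapts
to slow drifts and samples the whole desynchronization state space instead
of cutting a fixed bimodal distribution.  A high (low) state is declared
after 10 consecutive samples strictly above (below) threshold — 100 ms at
the 100 Hz entropy rate.

Numerical and procedural choices:

* **Strict inequalities** at both thresholds; "higher/lower than" is taken
  literally, and it makes a constant stream a well-defined no-event case.
* **Percentiles** use linear interpolation between order statistics
  (numpy's default); the buffer is maintained sorted so per-sample queries
  are O(log n).
* **Run bookkeeping**: a sample failing the criterion resets the run
  counter (no partial credit); a sample of the opposite label starts a new
  run of length 1.
* **Blink mute**: samples within 1 s after a blink are invisible — they
  enter neither the distribution nor the run, and they do not reset a run.
  An event can therefore be delayed by a blink but never caused or
  destroyed by one.
* **Warm-up**: no events until the buffered samples span at least half the
  forgetting window, avoiding threshold estimates from a near-empty
  distribution at cold start.
* **Refractory**: detection is suspended after each presented tone.  The
  hardware-paced default is 8.1 s (100 ms tone + 2 s response window + 6 s
  pause, matching the observed ~9 s tone-to-tone spacing).  The offline
  simulator defaults to 1 s so that a complete 420-trial session fits in a
  1500 s simulated run; pacing is a property of the experimental session,
  not of the detection rule, which is identical in both cases.

The closed-loop driver draws each tone uniformly from the pitch levels with
remaining quota for the detected state (7 levels × 30 per state); events
arriving after a state's quota is exhausted present no tone and incur no
refractory.

## Spatial filter

The filter is the unit-norm eigenvector of the largest eigenvalue of
`C_signal − C_noise`, where the covariances come from localizer epochs
(post-stimulus 0–200 ms vs pre-stimulus −200–0 ms), computed per epoch
(channels demeaned within epoch, divisor N−1) and averaged.  The symmetric
eigendecomposition is used — for a symmetric difference matrix this
coincides with an SVD up to sign — and the sign is fixed by orienting the
largest-magnitude weight positive.  Projection is a per-sample dot product;
a common-average reference is applied to multichannel data first, after
which every sample's channel mean is zero by construction.

## Spectral metrics

Time–frequency coefficients are obtained by convolving virtual-channel
epochs with frequency-adaptive Hann-tapered complex exponentials (4 cycles
per frequency), evaluated on a 100 Hz output grid.  The analysis grids are
1–40 Hz in 0.5 Hz steps (79 frequencies) and 14 log-spaced frequencies
from 40 to 70 Hz inclusive.  Edge points lacking full taper support are
masked invalid rather than zero-padded, and all downstream statistics skip
them.  Kernels are scaled to unit gain at their center frequency; all
reported quantities (dB change, ITC) are scale-free.

Power is `10·log10` of the ratio to the per-trial, per-frequency mean over
the baseline window (default −1 to 1.5 s, i.e. the whole trial).  ITC is
the magnitude of the trial average of unit-normalized coefficients;
zero-magnitude coefficients are excluded.  The jackknife jITC assigns each
trial the ITC of the remaining trials, computed via the leave-one-out
identity on the summed unit phasors and verified against literal
drop-one-recompute to 1e-12; `1 − jITC` is exposed as single-trial phase
coherence (note the inverted reading: a trial coherent with the rest gets
a *low* jITC).  Band summaries (1–8, 8–12, 14–30, 40–70 Hz) are unweighted
means over band frequencies and the stated time window.

## Behavioral models

Binary pitch judgments are fit with a maximum-likelihood logistic GLM of
response on normalized pitch, pre-stimulus entropy and pupil size (linear
and quadratic, alone and × pitch), plus baseline entropy (3 s pre-stimulus)
and trial number as covariates of no interest.  A state main effect is a
criterion shift; a state × pitch interaction is a sensitivity change.
Response speed (1/RT, trials with RT < 0.2 s or > 2 s excluded, strict
bounds) is fit with the analogous linear model without pitch interactions.

Design choices: fixed-effects GLMs with optional per-subject intercept
dummies stand in for mixed models — the random-effects selection of the
original analysis is interactive, and the fixed-effect estimates are the
quantity of interest here.  Continuous predictors are z-scored within
subject; quadratic terms are squares of the z-scored predictors, not
re-standardized.  Pitch is recoded by subtracting the median level and
dividing by the new maximum (median → 0, extremes of a symmetric set →
±1).  Wald p-values use the normal approximation with the conventional
±1.96 significance rule; coefficient differences are tested with
Wald Z = (b₁−b₂)/SE(b₁−b₂) from the fit covariance; p-value families are
adjusted with Benjamini–Hochberg FDR; Bayes factors are approximated from
likelihood-based BIC differences, `BF = exp((BIC_b − BIC_a)/2)`.  Rank
deficiency raises an error naming the collinear terms; perfect separation
raises a diagnostic error.

## Synthetic data

The generators emulate the statistical structure the method consumes, not
any particular recording:

* **Background EEG**: Gaussian noise spectrally shaped to `1/f^chi`
  (default χ=1), unit variance, independent per channel.
* **Synchronization**: a 10 Hz oscillation whose amplitude envelope is
  `exp(OU)` — a mean-reverting log-normal process with time constant 0.5 s
  (the scale on which synchronization states are self-similar) and log-SD
  0.6.  The envelope is returned as ground truth so classifier output can
  be scored against it.  Multichannel mixtures place sources through fixed
  topographies.
* **Evoked responses**: 0–300 ms Hann-windowed bursts that are `q` parts
  fixed-phase and `1−q` parts random-phase per trial, exercising the
  ITC/jITC monotonicity in the phase-locked fraction `q`.
* **Pupil**: baseline + mean-reverting fluctuation with time constant 2 s
  (slower than the entropy dynamics, reproducing the autocorrelation
  contrast between the two state variables), smoothed below 2 Hz because
  measured pupil traces carry no sample-to-sample jitter; Poisson blinks
  are rendered as 150 ms near-zero plateaus with 20 ms cosine ramps.
  Preprocessing spline-interpolates blink spans (padded 30 ms), low-passes
  at 20 Hz zero-phase, resamples to 50 Hz and epochs −2.5 to 3 s; a blink
  at a trace edge is filled with the nearest clean value and flagged.
* **Behavior**: Bernoulli draws from the logistic over the full fit term
  set with planted coefficients, and RTs from the inverted planted speed
  model (base speed 2 s⁻¹, Gaussian noise, truncated to a plausible
  range), enabling round-trip parameter recovery tests.

All generators are bit-reproducible under a fixed seed.

What passing tests on these data do **not** show: robustness to real EEG
artifacts (muscle, electrode drift, line noise), to non-stationary 1/f
exponents, to volume-conduction correlations between channel noise, or to
the phase-reset-vs-additive nature of real evoked responses (the additive
model is a deliberate non-commitment).  Mixed-effects shrinkage across
subjects is likewise out of scope.

## Problem sizes

The default simulated session is 1500 s of 16-channel EEG at 1000 Hz with
1 s simulator refractory, which completes the full 420-trial schedule with
margin; validity and drift properties are checked on 100–300 s
single-channel runs across 10 seeds; psychometric recovery uses 20
simulated subjects × 10,000 trials (~200,000 trials) for the logistic
model and 8,400 trials for the speed model.  `scripts/acceptance.py`
recomputes all of these from scratch at a given seed.

## Known limitations

* The classifier loop is pure Python (with a sorted rolling buffer); it
  processes a 1500 s session in a few seconds but is not tuned for
  hardware-rate online use.
* `adaptive_tracking` implements the accuracy-dependent widening/narrowing
  rule with a configurable factor (default 1.2); the original procedure's
  exact step size is not specified.
* EDF input is not implemented; continuous signals use the documented
  columnar text format or in-memory arrays.
* With asymmetric pitch-level sets, dividing by the new maximum yields an
  asymmetric normalized range (only the upper extreme reaches +1); the
  default level set is symmetric.
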