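"""Psychometric and response-speed models of state-dependent behavior.

Binary pitch judgments ("high" vs "low") are modelled with a logistic
regression whose predictors are the normalized tone pitch, pre-stimulus
entropy and pupil size (each entered linearly and quadratically, alone and
in interaction with pitch), plus baseline entropy and trial number as
covariates of no interest.  In this parameterization a main effect of a
state predictor is a shift of the response criterion (bias), and its
interaction with pitch is a change in the slope of the psychometric
function (perceptual sensitivity).

Response speed (1/RT, in 1/s) is modelled with the analogous linear model.
Coefficient differences are compared with a Wald Z statistic, and families
of p-values are adjusted with the Benjamini-Hochberg FDR procedure.

Fitting uses fixed-effects GLMs (statsmodels) with optional per-subject
intercept dummies; continuous predictors are expected to be z-scored within
subject (see :func:`standardize_trials`), with quadratic terms computed on
the z-scored predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "FitReport",
    "recode_pitch",
    "filter_rts",
    "standardize_trials",
    "fit_psychometric",
    "fit_speed",
    "wald_z",
    "fdr_adjust",
    "compare_models",
]

RT_MIN, RT_MAX = 0.2, 2.0        # strict exclusion bounds, seconds

PSYCHOMETRIC_TERMS = [
    "pitch", "entropy", "entropy_sq", "pupil", "pupil_sq",
    "pitch:entropy", "pitch:entropy_sq", "pitch:pupil", "pitch:pupil_sq",
    "baseline_entropy", "trial_number",
]
SPEED_TERMS = [
    "pitch", "entropy", "entropy_sq", "pupil", "pupil_sq",
    "baseline_entropy", "trial_number",
]


@dataclass
class FitReport:
    """Coefficient table and metadata of one fitted model."""

    table: pd.DataFrame              # index: term; columns: estimate, se, z, p
    vcov: pd.DataFrame
    link: str                        # "logit" | "identity"
    n_obs: int
    llf: float
    bic: float
    r2: float                        # pseudo-R2 (McFadden) or OLS R2
    meta: dict = field(default_factory=dict)

    def estimate(self, term: str) -> float:
        return float(self.table.loc[term, "estimate"])


def recode_pitch(levels_hz) -> np.ndarray:
    """Normalize pitch levels: subtract the median, divide by the new
    maximum, so the median maps to 0 and the extremes of a symmetric set to
    -1 and +1."""
    levels = np.asarray(levels_hz, dtype=float)
    if len(np.unique(levels)) != len(levels):
        raise ValueError("pitch levels must be distinct")
    if len(levels) % 2 == 0:
        raise ValueError("an odd number of pitch levels is required")
    centered = levels - np.median(levels)
    return centered / centered.max()


def filter_rts(trials: pd.DataFrame) -> pd.DataFrame:
    """Drop trials with RT below 0.2 s or above 2 s (strict bounds; boundary
    values are retained) and add ``speed`` = 1/RT in 1/s."""
    out = trials[(trials["rt"] >= RT_MIN) & (trials["rt"] <= RT_MAX)].copy()
    out["speed"] = 1.0 / out["rt"]
    return out


def standardize_trials(trials: pd.DataFrame,
                       cols=("pre_entropy", "pre_pupil", "baseline_entropy",
                             "trial_number")) -> pd.DataFrame:
    """Z-score continuous predictors within each subject."""
    out = trials.copy()
    for col in cols:
        grp = out.groupby("subject")[col]
        out[col] = (out[col] - grp.transform("mean")) / grp.transform("std", ddof=1)
    return out


def _design(trials: pd.DataFrame, terms, subject_dummies: bool) -> pd.DataFrame:
    cols = {"intercept": np.ones(len(trials))}
    base = {
        "pitch": trials["pitch_norm"].to_numpy(),
        "entropy": trials["pre_entropy"].to_numpy(),
        "pupil": trials["pre_pupil"].to_numpy(),
        "baseline_entropy": trials["baseline_entropy"].to_numpy(),
        "trial_number": trials["trial_number"].to_numpy(),
    }
    base["entropy_sq"] = base["entropy"] ** 2
    base["pupil_sq"] = base["pupil"] ** 2
    for term in terms:
        if ":" in term:
            a, b = term.split(":")
            cols[term] = base[a] * base[b]
        else:
            cols[term] = base[term]
    X = pd.DataFrame(cols, index=trials.index)
    if subject_dummies:
        subjects = pd.unique(trials["subject"])
        for s in subjects[1:]:                       # first subject absorbed
            X[f"subject[{s}]"] = (trials["subject"] == s).astype(float)
    return X


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy()
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        _, r = np.linalg.qr(arr)
        bad = X.columns[np.abs(np.diag(r)) < 1e-8 * np.abs(np.diag(r)).max()]
        raise ValueError(f"design matrix is rank deficient; collinear terms: "
                         f"{list(bad)}")


def _report(result, X: pd.DataFrame, link: str, r2: float, meta: dict) -> FitReport:
    table = pd.DataFrame({
        "estimate": result.params,
        "se": result.bse,
        "z": result.params / result.bse,
        "p": result.pvalues,
    })
    table.index = X.columns
    vcov = pd.DataFrame(np.asarray(result.cov_params()),
                        index=X.columns, columns=X.columns)
    # likelihood-based BIC for both model families (GLM's default is
    # deviance-based, which is unusable for Bayes-factor approximation)
    bic = -2.0 * float(result.llf) + X.shape[1] * np.log(result.nobs)
    return FitReport(table=table, vcov=vcov, link=link, n_obs=int(result.nobs),
                     llf=float(result.llf), bic=bic, r2=r2,
                     meta=meta)


def fit_psychometric(trials: pd.DataFrame,
                     subject_dummies: bool = False) -> FitReport:
    """Maximum-likelihood logistic fit of response on pitch, linear and
    quadratic state terms, their pitch interactions, and covariates.

    Raises a diagnostic error on perfect separation and names collinear
    terms on rank deficiency.
    """
    y = trials["response"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("responses contain a single class")
    X = _design(trials, PSYCHOMETRIC_TERMS, subject_dummies)
    _check_rank(X)
    model = sm.GLM(y, X.to_numpy(), family=sm.families.Binomial())
    try:
        result = model.fit()
    except PerfectSeparationError as err:
        raise ValueError("perfect separation detected in the logistic fit") from err
    null = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Binomial()).fit()
    pseudo_r2 = 1.0 - result.llf / null.llf
    return _report(result, X, "logit", pseudo_r2,
                   meta={"model": "psychometric"})


def fit_speed(trials: pd.DataFrame, subject_dummies: bool = False) -> FitReport:
    """Least-squares fit of response speed (1/RT) on the state predictor
    set (no pitch interactions)."""
    if "speed" not in trials:
        raise ValueError("run filter_rts first (no 'speed' column)")
    y = trials["speed"].to_numpy(dtype=float)
    X = _design(trials, SPEED_TERMS, subject_dummies)
    _check_rank(X)
    result = sm.OLS(y, X.to_numpy()).fit()
    return _report(result, X, "identity", float(result.rsquared),
                   meta={"model": "speed"})


def wald_z(fit: FitReport, term_a: str, term_b: str) -> float:
    """Wald Z for the difference of two coefficients from the same model:
    ``(b_a - b_b) / SE(b_a - b_b)``; |Z| > 1.96 is the conventional
    significance rule."""
    for t in (term_a, term_b):
        if t not in fit.table.index:
            raise KeyError(f"term {t!r} not in fit")
    if fit.vcov is None:
        raise ValueError("fit has no coefficient covariance")
    ba, bb = fit.estimate(term_a), fit.estimate(term_b)
    va = float(fit.vcov.loc[term_a, term_a])
    vb = float(fit.vcov.loc[term_b, term_b])
    cab = float(fit.vcov.loc[term_a, term_b])
    se_diff = np.sqrt(max(va + vb - 2.0 * cab, 0.0))
    if se_diff == 0.0:
        if ba == bb:                 # identical terms: no difference to test
            return 0.0
        raise ValueError("zero standard error for a non-zero difference")
    return (ba - bb) / se_diff


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def compare_models(fit_a: FitReport, fit_b: FitReport) -> float:
    """Approximate Bayes factor in favor of model a over model b from the
    BIC difference: ``BF = exp((BIC_b - BIC_a) / 2)``.  Models must be fit
    on the same observations."""
    if fit_a.n_obs != fit_b.n_obs:
        raise ValueError("models were fit on different numbers of observations")
    return float(np.exp((fit_b.bic - fit_a.bic) / 2.0))
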