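"""Localizer-based spatial filtering of multichannel EEG.

To emphasize activity from a cortical region of interest (auditory cortex
in the original setup), a spatial filter is estimated from localizer
epochs: the channel covariance of a post-stimulus "signal" window (0 to
200 ms) minus the covariance of a pre-stimulus "noise" window (-200 to
0 ms) is eigendecomposed, and the eigenvector of the largest eigenvalue
supplies one weight per channel.  Multiplying incoming EEG with these
weights yields a single virtual channel dominated by the evoked source.

Covariances are estimated per epoch (channels demeaned within the epoch,
divisor N-1) and averaged over epochs.  The difference matrix is symmetric,
so the symmetric eigendecomposition is used; the eigenvector sign is fixed
by orienting the largest-magnitude element positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signals import EpochSet, SignalTrace

__all__ = ["FilterWeights", "covariance_of", "compute_filter", "project"]


@dataclass
class FilterWeights:
    """Unit-norm spatial-filter weights (one per channel)."""

    weights: np.ndarray
    eigenvalue: float
    sign_convention: str = "largest_abs_positive"


def covariance_of(epochs: EpochSet) -> np.ndarray:
    """Average per-epoch channel covariance (channels demeaned per epoch).

    Returns a symmetric positive-semidefinite channel x channel matrix.
    """
    if epochs.n_channels < 2:
        raise ValueError("covariance requires >= 2 channels")
    if epochs.n_trials < 2 or epochs.n_times < 2:
        raise ValueError("need >= 2 epochs of >= 2 samples")
    x = epochs.epochs - epochs.epochs.mean(axis=2, keepdims=True)
    covs = np.einsum("eit,ejt->eij", x, x) / (epochs.n_times - 1)
    cov = covs.mean(axis=0)
    return 0.5 * (cov + cov.T)      # exact symmetry


def compute_filter(signal: EpochSet, noise: EpochSet) -> FilterWeights:
    """Spatial filter from the signal-minus-noise covariance difference.

    The weights are the unit-norm eigenvector of the largest (most
    positive) eigenvalue of ``C_signal - C_noise`` — the channel
    combination whose variance increases most from the pre- to the
    post-stimulus window.
    """
    if signal.n_channels != noise.n_channels:
        raise ValueError("signal and noise epochs have different channel counts")
    diff = covariance_of(signal) - covariance_of(noise)
    eigvals, eigvecs = np.linalg.eigh(diff)
    w = eigvecs[:, -1]
    w = w / np.linalg.norm(w)
    if w[np.argmax(np.abs(w))] < 0:
        w = -w
    return FilterWeights(weights=w, eigenvalue=float(eigvals[-1]))


def project(eeg: SignalTrace, w: FilterWeights | np.ndarray) -> SignalTrace:
    """Project multichannel EEG through the filter to one virtual channel."""
    weights = w.weights if isinstance(w, FilterWeights) else np.asarray(w, dtype=float)
    if eeg.data.ndim != 2:
        raise ValueError("project expects a multichannel trace")
    if weights.shape != (eeg.n_channels,):
        raise ValueError("weight length does not match channel count")
    return SignalTrace(weights @ eeg.data, eeg.fs, eeg.t0)
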