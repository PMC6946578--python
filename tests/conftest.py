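"""Shared fixtures and independent oracle implementations.

The brute-force weighted-permutation-entropy oracle here deliberately
mirrors the definition sub-vector by sub-vector, independently of the
package's vectorized path, so equivalence tests are meaningful.
"""

import math

import numpy as np
import pytest


def brute_force_wpe(x, m, tau, normalize=True, log_base="natural"):
    """Naive WPE: materialize every sub-vector, rank it (ties by temporal
    order), weight by population variance, and take the Shannon entropy of
    the weighted motif relative frequencies."""
    x = np.asarray(x, dtype=float)
    n_sub = len(x) - (m - 1) * tau
    assert n_sub >= 1
    table = {}
    total = 0.0
    for j in range(n_sub):
        sub = x[j:j + (m - 1) * tau + 1:tau]
        order = sorted(range(m), key=lambda k: (sub[k], k))
        ranks = [0] * m
        for r, k in enumerate(order):
            ranks[k] = r
        w = float(np.mean((sub - sub.mean()) ** 2))
        table[tuple(ranks)] = table.get(tuple(ranks), 0.0) + w
        total += w
    if total == 0.0:
        return 0.0
    log = np.log2 if log_base == "two" else np.log
    h = -sum((w / total) * log(w / total) for w in table.values() if w > 0)
    if normalize:
        h /= log(math.factorial(m))
    return float(h)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
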