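"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive — enumeration, hand-rolled partial
likelihoods, staged grid search — and shares no code path with the package
implementation it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom


def efron_partial_loglik(beta: float, t, e, z) -> float:
    """Efron-tie-corrected Cox partial log-likelihood, one binary covariate."""
    t = np.asarray(t, float)
    e = np.asarray(e, bool)
    z = np.asarray(z, float)
    ll = 0.0
    for tau in np.unique(t[e]):
        d_idx = (t == tau) & e
        r_idx = t >= tau
        d = int(d_idx.sum())
        s_r = float(np.exp(beta * z[r_idx]).sum())
        s_d = float(np.exp(beta * z[d_idx]).sum())
        ll += beta * float(z[d_idx].sum())
        for j in range(d):
            ll -= np.log(s_r - (j / d) * s_d)
    return ll


def grid_cox_mle(t, e, z, lo: float = -4.0, hi: float = 4.0) -> float:
    """Staged grid search for the partial-likelihood maximizer."""
    best = 0.0
    width = hi - lo
    center = (lo + hi) / 2.0
    for _ in range(5):
        grid = np.linspace(center - width / 2, center + width / 2, 81)
        vals = [efron_partial_loglik(b, t, e, z) for b in grid]
        best = float(grid[int(np.argmax(vals))])
        center = best
        width = width / 20.0
    return best


def product_limit(durations, events):
    """Hand product-limit estimator: list of (time, survival) steps."""
    durations = np.asarray(durations, float)
    events = np.asarray(events, bool)
    steps = []
    s = 1.0
    for tau in np.unique(durations[events]):
        n_risk = int((durations >= tau).sum())
        d = int(((durations == tau) & events).sum())
        s *= 1.0 - d / n_risk
        steps.append((float(tau), s))
    return steps


def pl_median(durations, events) -> float:
    """First time the hand product-limit curve drops to <= 0.5."""
    for tau, s in product_limit(durations, events):
        if s <= 0.5:
            return tau
    return float("inf")


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration."""
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    dist = hypergeom(n, row1, col1)
    p_obs = dist.pmf(a)
    ks = np.arange(max(0, col1 - (n - row1)), min(row1, col1) + 1)
    pk = dist.pmf(ks)
    return float(pk[pk <= p_obs * (1 + 1e-9)].sum())
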