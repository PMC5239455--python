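"""Independent brute-force oracles used by unit and acceptance tests.

Deliberately written in plain loops / closed forms, sharing no code with the
package implementation paths they check.
"""

import numpy as np
from scipy.stats import hypergeom


def youden_scan_oracle(scores, labels):
    """Brute-force Youden maximizer: plain loops over midpoint cutpoints."""
    uniq = sorted(set(scores))
    best_j, best_t = -np.inf, None
    for lo, hi in zip(uniq[:-1], uniq[1:]):
        t = (lo + hi) / 2.0
        tp = sum(1 for s, y in zip(scores, labels) if s > t and y == 1)
        fn = sum(1 for s, y in zip(scores, labels) if s <= t and y == 1)
        tn = sum(1 for s, y in zip(scores, labels) if s <= t and y == 0)
        fp = sum(1 for s, y in zip(scores, labels) if s > t and y == 0)
        j = tp / (tp + fn) + tn / (tn + fp) - 1.0
        if j > best_j:  # strict: keeps the lowest threshold on ties
            best_j, best_t = j, t
    return best_t, best_j


def km_hand_oracle(times, events):
    """Product-limit estimator computed directly from its definition."""
    order = np.argsort(times)
    times, events = np.asarray(times)[order], np.asarray(events)[order]
    s, out = 1.0, {}
    for t in np.unique(times):
        at_risk = np.sum(times >= t)
        d = np.sum((times == t) & (events == 1))
        if d > 0:
            s *= 1.0 - d / at_risk
        out[float(t)] = s
    return out


def cox_partial_loglik_no_ties(beta, x, times, events):
    """Exact partial log-likelihood for one covariate without tied event times."""
    ll = 0.0
    for i in range(len(times)):
        if events[i] == 1:
            risk = [j for j in range(len(times)) if times[j] >= times[i]]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * np.array(x)[risk])))
    return ll


def fisher_enumeration_oracle(table):
    """Two-sided Fisher p by full hypergeometric enumeration."""
    a, b = table[0]
    c, d = table[1]
    n = a + b + c + d
    row1, col1 = a + b, a + c
    rv = hypergeom(n, col1, row1)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    probs = rv.pmf(support)
    p_obs = rv.pmf(a)
    return float(probs[probs <= p_obs * (1 + 1e-9)].sum())


def mono_fisher_info_sd(tau, n_photons, n_bins, time_window):
    """Cramer-Rao SD bound from numerically differentiated bin probabilities."""
    edges = np.linspace(0.0, time_window, n_bins + 1)

    def probs(t):
        e = np.exp(-edges / t)
        return (e[:-1] - e[1:]) / (1.0 - np.exp(-time_window / t))

    h = tau * 1e-6
    p = probs(tau)
    dp = (probs(tau + h) - probs(tau - h)) / (2.0 * h)
    info = n_photons * np.sum(dp**2 / p)
    return float(1.0 / np.sqrt(info))
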