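"""Slow, independent reference implementations used only to cross-check.

Everything here is written as plain loops over the definitions, deliberately
avoiding the vectorized code paths of the package.
"""

import numpy as np


def brute_cindex(times, status, risk):
    """Harrell's c by an O(n^2) double loop over all pairs."""
    n = len(times)
    num = den = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            # pair usable if the shorter time is an observed event
            if times[i] < times[j] and status[i] == 1:
                den += 1
                if risk[i] > risk[j]:
                    num += 1
                elif risk[i] == risk[j]:
                    num += 0.5
    return num / den


def brute_cpe(lp):
    """Gönen-Heller CPE by explicit double summation over unordered pairs."""
    n = len(lp)
    total = 0.0
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            d = abs(lp[i] - lp[j])
            total += 1.0 / (1.0 + np.exp(-d))
            count += 1
    return total / count


def direct_partial_loglik(X, time, status, beta):
    """Breslow partial log-likelihood by explicit risk-set loops."""
    X = np.atleast_2d(X)
    if X.shape[0] != len(time):
        X = X.T
    lp = X @ np.asarray(beta, dtype=float)
    ll = 0.0
    for i in range(len(time)):
        if status[i] == 1:
            risk = [j for j in range(len(time)) if time[j] >= time[i]]
            ll += lp[i] - np.log(np.sum(np.exp(lp[risk])))
    return ll


def nelson_aalen_at(time, status, t):
    """Nelson-Aalen cumulative hazard at t by explicit loops."""
    out = 0.0
    for tau in sorted(set(time[status == 1])):
        if tau <= t:
            d = np.sum((time == tau) & (status == 1))
            n_at = np.sum(time >= tau)
            out += d / n_at
    return out


def brute_max_logrank_split(time, status, x, window=(0.10, 0.90)):
    """Maximally selected log-rank rank statistic, split by split.

    Scores a_i = d_i - NA(t_i); for each admissible split the linear rank
    statistic over {x <= c} is standardized by its permutational moments.
    Returns (best_cut, best_|Z|).
    """
    n = len(time)
    a = np.array([status[i] - nelson_aalen_at(time, status, time[i]) for i in range(n)])
    abar = a.mean()
    va = np.sum((a - abar) ** 2)
    lo, hi = np.percentile(x, [100 * window[0], 100 * window[1]])
    cands = sorted(set(x[(x >= lo) & (x <= hi)]))
    cands = [c for c in cands if c < x.max()]
    best_c, best_z = None, -1.0
    for c in cands:
        g = x <= c
        m = int(g.sum())
        S = a[g].sum()
        V = m * (n - m) / (n * (n - 1.0)) * va
        z = abs(S - m * abar) / np.sqrt(V)
        if z > best_z:
            best_c, best_z = c, z
    return best_c, best_z


def deboor_bspline(x, knots, degree, i):
    """Cox-de Boor recursion for the i-th B-spline basis function."""
    if degree == 0:
        return 1.0 if knots[i] <= x < knots[i + 1] else 0.0
    left = 0.0
    if knots[i + degree] > knots[i]:
        left = (x - knots[i]) / (knots[i + degree] - knots[i]) * deboor_bspline(
            x, knots, degree - 1, i
        )
    right = 0.0
    if knots[i + degree + 1] > knots[i + 1]:
        right = (knots[i + degree + 1] - x) / (
            knots[i + degree + 1] - knots[i + 1]
        ) * deboor_bspline(x, knots, degree - 1, i + 1)
    return left + right
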