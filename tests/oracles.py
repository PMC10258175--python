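"""Independent brute-force reference implementations used only by tests.

Everything here is written with explicit loops straight from the defining
formulas, with no suffix-sum or vectorisation tricks, so it shares no code
path with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import optimize


def brute_risk_sets(t, r):
    """Distinct event times with tie counts and at-risk memberships by loops."""
    t = np.asarray(t, float)
    r = np.asarray(r, float)
    u = sorted(set(t.tolist()))
    d = [sum(1 for ti in t if ti == uj) for uj in u]
    at_risk = [[i for i in range(len(t)) if t[i] <= uj <= r[i]] for uj in u]
    return u, d, at_risk


def brute_vhat(t, r, z, beta):
    """Baseline odds estimate evaluated by literal double loops."""
    t = np.asarray(t, float)
    z = np.atleast_2d(np.asarray(z, float))
    beta = np.atleast_1d(np.asarray(beta, float))
    u, d, at_risk = brute_risk_sets(t, r)
    m = len(u)
    y = [len(a) for a in at_risk]
    # log P(u_j) = - sum_{k >= j} d_k / y_k  (N steps down in forward time)
    log_p = [-sum(d[k] / y[k] for k in range(j, m)) for j in range(m)]
    q = [
        sum(math.exp(float(z[i] @ beta)) for i in range(len(t)) if t[i] == u[j]) / y[j]
        for j in range(m)
    ]
    vhat = []
    for j in range(m):
        denom = sum(math.exp(log_p[k]) * q[k] for k in range(j, m))
        vhat.append(math.exp(log_p[j]) / denom)
    return u, np.array(vhat)


def brute_score(t, r, z, beta, weights=None):
    """Estimating function by a double loop over subjects and risk sets."""
    t = np.asarray(t, float)
    r = np.asarray(r, float)
    z = np.atleast_2d(np.asarray(z, float))
    beta = np.atleast_1d(np.asarray(beta, float))
    n, p = z.shape
    u, _, at_risk = brute_risk_sets(t, r)
    uvhat = dict(zip(u, brute_vhat(t, r, z, beta)[1]))
    zbar = {}
    for uj, members in zip(u, at_risk):
        zbar[uj] = sum(z[i] for i in members) / len(members)
    w = dict(zip(u, weights)) if weights is not None else {uj: 1.0 for uj in u}
    total = np.zeros(p)
    for i in range(n):
        uj = t[i]
        term = math.exp(float(z[i] @ beta)) * uvhat[uj] + 1.0
        total += w[uj] * (z[i] - zbar[uj]) * term
    return total / n


def finite_diff_jacobian(fun, x, eps=1e-6):
    """Central finite differences of a vector-valued function."""
    x = np.asarray(x, float)
    cols = []
    for k in range(x.size):
        h = np.zeros_like(x)
        h[k] = eps
        cols.append((fun(x + h) - fun(x - h)) / (2 * eps))
    return np.column_stack(cols)


def npmle_truncated_cdf(t, r, n_starts=3, seed=0):
    """Conditional NPMLE of F for right-truncated data by direct likelihood
    maximisation over point masses at the distinct event times.

    Maximises ``prod_i f(t_i) / F(r_i)`` over the probability simplex with
    multiple random restarts; returns F at the distinct event times
    (normalised so F equals 1 at the largest).
    """
    t = np.asarray(t, float)
    r = np.asarray(r, float)
    u = np.array(sorted(set(t.tolist())))
    m = u.size

    def neg_loglik(f):
        f = np.clip(f, 1e-12, None)
        f = f / f.sum()
        ll = 0.0
        for ti, ri in zip(t, r):
            fi = f[np.flatnonzero(u == ti)[0]]
            big_f = f[u <= ri].sum()
            ll += math.log(fi) - math.log(big_f)
        return -ll

    rng = np.random.default_rng(seed)
    best, best_val = None, np.inf
    starts = [np.full(m, 1.0 / m)] + [rng.dirichlet(np.ones(m)) for _ in range(n_starts)]
    for x0 in starts:
        res = optimize.minimize(
            neg_loglik,
            x0,
            method="SLSQP",
            bounds=[(0.0, 1.0)] * m,
            constraints=[{"type": "eq", "fun": lambda f: f.sum() - 1.0}],
            options={"maxiter": 500, "ftol": 1e-14},
        )
        if res.fun < best_val:
            best, best_val = res.x, res.fun
    f = np.clip(best, 0.0, None)
    f = f / f.sum()
    return np.cumsum(f)


def enumerate_truncated_configs(max_n=4, times=(1.0, 2.0, 3.0)):
    """All subject multisets of (t, r) pairs with t <= r drawn from ``times``."""
    pairs = [(ti, rj) for ti in times for rj in times if ti <= rj]
    for n in range(2, max_n + 1):
        for combo in itertools.combinations_with_replacement(pairs, n):
            t = [c[0] for c in combo]
            r = [c[1] for c in combo]
            yield np.array(t), np.array(r)
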