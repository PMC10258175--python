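"""Closed-form estimation of the baseline odds function v(t) = exp(alpha(t)).

Under the proportional odds model
``log{F(t|Z)/S(t|Z)} = alpha(t) + Z'beta`` the reverse-time (retro) hazard has
a log-linear relationship with the forward hazard, which yields an explicit
plug-in estimator of the baseline odds ``v(t) = exp(alpha(t))`` at any fixed
beta:

    vhat(t, beta) = P_n(t) / int_t^tau P_n(s) Q_n(ds, beta),

where ``P_n(t) = exp( int_t^tau dNbar / Ybar ) = exp( - sum_{u_k >= t} d_k / y_k )``
is the exponential of a reverse-cumulative Nelson-Aalen-type sum (it does
not depend on beta) and ``Q_n`` places mass
``q_j = sum_{i: t_i = u_j} exp(Z_i'beta) / y_j`` at each distinct event
time.  Both are suffix sums over the event grid, accumulated from the
largest event time downward in one O(m) pass.

Note the sign: in forward time the counting process ``N_i(t) = I(t <= T_i)``
steps *down*, so the suffix integral of dN is minus the suffix sum of tie
counts.  With this sign the continuous-time limit of vhat solves
``v'/v = p(t) + q(t) v`` -- exactly the identity the model imposes on the
reverse hazard -- and vhat is consistent for v (checked against the known
v(t) = t^3 in the test suite).  The exponential-of-cumulative-sum form is
kept as displayed rather than replaced by the product-limit
``prod (1 - d/y)``; the two differ in finite samples.

vhat and its beta-gradient are homogeneous of degree zero in P_n, so P_n is
shifted in log space before exponentiation and overflow or underflow can
never contaminate them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sample import EventGrid, RightTruncatedSample

__all__ = [
    "NumericalOverflowError",
    "BaselineOdds",
    "compute_P",
    "compute_Q_mass",
    "compute_vhat",
    "compute_vhat_grad",
]


class NumericalOverflowError(FloatingPointError):
    """exp(Z'beta) overflowed; consider rescaling covariates."""


@dataclass(frozen=True)
class BaselineOdds:
    """Step-function estimate of the baseline odds on the event grid.

    ``vhat[j]`` estimates v(u_j) at the stored ``beta``; ``dvhat[j, k]`` is
    its partial derivative in beta_k.  Between grid points the estimate is the
    right-continuous step taking the value at the smallest grid point >= t.
    """

    u: np.ndarray
    p_vals: np.ndarray
    q_mass: np.ndarray
    vhat: np.ndarray
    dvhat: np.ndarray | None
    beta: np.ndarray


def _log_P(grid: EventGrid) -> np.ndarray:
    # minus the suffix sum of d_k / y_k (N has downward jumps in forward time)
    ratio = grid.d / grid.y
    return -np.cumsum(ratio[::-1])[::-1]


def compute_P(grid: EventGrid) -> np.ndarray:
    """P_n at each grid point: ``P_j = exp( - sum_{k >= j} d_k / y_k )``.

    Nondecreasing in j, with ``P_m = exp(-d_m / y_m) < 1``; free of beta.
    """
    with np.errstate(over="ignore"):
        return np.exp(_log_P(grid))


def _exp_lp(sample: RightTruncatedSample, beta: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        e = np.exp(sample.z @ beta)
    if not np.all(np.isfinite(e)):
        raise NumericalOverflowError(
            "exp(Z'beta) is not finite; rescale covariates or restart closer to 0"
        )
    return e


def compute_Q_mass(
    grid: EventGrid, beta: np.ndarray, sample: RightTruncatedSample
) -> np.ndarray:
    """Point masses of Q_n: ``q_j = sum_{i: t_i = u_j} exp(Z_i'beta) / y_j``.

    ``Q_n(t, beta) = sum_{u_k >= t} q_k``; at beta = 0 this reduces to d/y.
    """
    beta = np.asarray(beta, dtype=float)
    e = _exp_lp(sample, beta)
    num = np.bincount(grid.event_index, weights=e, minlength=grid.m)
    return num / grid.y


def _q_grad(
    grid: EventGrid, beta: np.ndarray, sample: RightTruncatedSample
) -> np.ndarray:
    """(m, p) matrix with ``q_j^(k) = sum_{i: t_i = u_j} Z_ik exp(Z_i'beta) / y_j``."""
    e = _exp_lp(sample, np.asarray(beta, dtype=float))
    out = np.zeros((grid.m, sample.p))
    np.add.at(out, grid.event_index, sample.z * e[:, None])
    return out / grid.y[:, None]


def compute_vhat(
    grid: EventGrid,
    beta: np.ndarray,
    sample: RightTruncatedSample,
    with_grad: bool = True,
) -> BaselineOdds:
    """Evaluate vhat(., beta) (and, optionally, its beta-gradient) on the grid.

    ``vhat_j = P_j / D_j`` with ``D_j = sum_{k >= j} P_k q_k`` and

    ``d vhat_j / d beta_k = - P_j ( sum_{l >= j} P_l q_l^(k) ) / D_j^2``

    (P does not depend on beta).  All suffix sums use the log-shifted P, under
    which both ratios are exactly invariant.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    log_p = _log_P(grid)
    p_shift = np.exp(log_p - log_p.max())
    q = compute_Q_mass(grid, beta, sample)
    d_suffix = np.cumsum((p_shift * q)[::-1])[::-1]
    assert np.all(d_suffix > 0), "denominator of vhat vanished"
    vhat = p_shift / d_suffix
    dvhat = None
    if with_grad:
        qk = _q_grad(grid, beta, sample)
        g_suffix = np.cumsum((p_shift[:, None] * qk)[::-1], axis=0)[::-1]
        dvhat = -(p_shift / d_suffix**2)[:, None] * g_suffix
    with np.errstate(over="ignore"):
        p_vals = np.exp(log_p)
    return BaselineOdds(
        u=grid.u, p_vals=p_vals, q_mass=q, vhat=vhat, dvhat=dvhat, beta=beta
    )


def compute_vhat_grad(
    grid: EventGrid, beta: np.ndarray, sample: RightTruncatedSample
) -> np.ndarray:
    """(m, p) gradient of vhat in beta; see :func:`compute_vhat`."""
    return compute_vhat(grid, beta, sample, with_grad=True).dvhat
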