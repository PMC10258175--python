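"""Lynden-Bell product-limit estimation under right truncation, and the
weight functions it supplies to the weighted estimating equations.

The nonparametric product-limit estimator of the baseline distribution for
right-truncated data (Lynden-Bell's estimator, familiar from astronomy and
from AIDS incubation studies) reuses the truncation-adjusted risk sets
``y_j = #{i : t_i <= u_j <= r_i}`` already built for the regression:

    Fhat(u_j) = prod_{k > j} (1 - d_k / y_k),

with the empty product equal to 1 at the largest event time, so Fhat is a
distribution function normalised to reach 1 there (under right truncation F
is only identified up to its value at the end of observation).  Covariates
are ignored: this is the pooled baseline estimate.

Two weight functions for the weighted estimating equation are derived from
it, both evaluated at the *left limit* ``Shat(u_j-)`` (the value at the
previous grid point; 1 before the first event) so the weight process is
predictable with respect to the canonical filtration:

- Prentice-Wilcoxon:  W(u_j) = Shat_LB(u_j-)
- optimal:            W(u_j) = Shat_LB(u_j-) (1 - Shat_LB(u_j-)),

the plug-in of the variance-minimising limit w(t) = S(t){1 - S(t)}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .sample import EventGrid

__all__ = ["StepDistribution", "fit_lynden_bell", "make_weights", "WEIGHT_SCHEMES"]

WEIGHT_SCHEMES = ("unweighted", "prentice_wilcoxon", "optimal")


@dataclass(frozen=True)
class StepDistribution:
    """Right-continuous step estimate of the baseline distribution."""

    u: np.ndarray
    F_hat: np.ndarray
    S_hat: np.ndarray


def fit_lynden_bell(grid: EventGrid) -> StepDistribution:
    """Product-limit estimate of the baseline F under right truncation."""
    frac = 1.0 - grid.d / grid.y
    if np.any(frac[1:] == 0.0):
        warnings.warn(
            "an interior risk set is exhausted (y_k = d_k); the estimate "
            "is identically zero before that point",
            stacklevel=2,
        )
    # Fhat[j] = prod_{k > j} frac[k]; build from the right
    rev = np.cumprod(frac[::-1])[::-1]
    f_hat = np.concatenate((rev[1:], [1.0]))
    return StepDistribution(u=grid.u, F_hat=f_hat, S_hat=1.0 - f_hat)


def make_weights(dist: StepDistribution, scheme: str) -> np.ndarray:
    """Predictable weights over the event grid for a fitted step distribution."""
    s_left = np.concatenate(([1.0], dist.S_hat[:-1]))
    if scheme == "prentice_wilcoxon":
        return s_left
    if scheme == "optimal":
        return s_left * (1.0 - s_left)
    raise ValueError(f"unknown weight scheme: {scheme!r}")
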