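"""Right-truncated survival samples: validation, CSV I/O, risk-set summaries.

A subject enters a right-truncated sample only if its event time ``T`` does
not exceed its truncation time ``R`` (for example, an AIDS case is recorded
only if diagnosis happens before the end of the surveillance window).  Short
event times are therefore over-represented and any analysis ignoring the
selection is biased.

This module holds the observed triples ``(T_i, R_i, Z_i)`` and builds the
aggregated counting-process summaries every estimator consumes: the distinct
event times, tie counts, at-risk counts ``Y(u) = #{i : T_i <= u <= R_i}``
(note the risk set grows and then shrinks -- it is *not* monotone under
truncation), and the risk-set covariate means ``Zbar(u)``.

Everything is expressed in forward time.  The reverse-time sample
``(tau - T, tau - R)`` that makes the theory adapted is never materialised:
all estimating quantities are suffix sums over event times, which depend on
the data only through the forward-time risk sets built here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DataFormatError",
    "DataValidationError",
    "RightTruncatedSample",
    "EventGrid",
    "load_sample",
    "write_sample",
    "build_event_grid",
]


class DataFormatError(ValueError):
    """The input file does not have the expected columns/layout."""


class DataValidationError(ValueError):
    """The data violate an observability or positivity constraint."""


@dataclass(frozen=True)
class RightTruncatedSample:
    """Observed right-truncated data ``(T_i, R_i, Z_i)``, ``i = 1..n``.

    Parameters
    ----------
    t : array of event times, strictly positive.
    r : array of right-truncation times; observability requires ``t <= r``.
    z : (n, p) covariate matrix, one row per subject.
    tau : study duration; defaults to ``max(t)``.  Every estimating quantity
        is a sum over event times, so any ``tau >= max(t)`` yields identical
        estimates -- the field only matters for reporting.
    covariate_names : optional column labels, kept through CSV round trips.
    """

    t: np.ndarray
    r: np.ndarray
    z: np.ndarray
    tau: float | None = None
    covariate_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        r = np.asarray(self.r, dtype=float)
        z = np.atleast_2d(np.asarray(self.z, dtype=float))
        if z.shape[0] != t.size and z.shape[1] == t.size:
            z = z.T
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "z", z)
        if t.ndim != 1 or r.ndim != 1 or t.size != r.size or z.shape[0] != t.size:
            raise DataValidationError(
                "t, r and the rows of z must have a common length"
            )
        if t.size < 2:
            raise DataValidationError("need at least two subjects")
        if not (np.isfinite(t).all() and np.isfinite(r).all() and np.isfinite(z).all()):
            raise DataValidationError("non-finite entries in the data")
        bad = np.flatnonzero(t <= 0)
        if bad.size:
            raise DataValidationError(
                f"event time must be positive; first offending row: {bad[0]}"
            )
        bad = np.flatnonzero(t > r)
        if bad.size:
            raise DataValidationError(
                f"observability requires t <= r; first offending row: {bad[0]}"
            )
        tau = float(t.max()) if self.tau is None else float(self.tau)
        if tau < t.max():
            raise DataValidationError("tau must be at least max(t)")
        object.__setattr__(self, "tau", tau)
        names = self.covariate_names
        if names is not None:
            names = tuple(names)
            if len(names) != z.shape[1]:
                raise DataValidationError(
                    "covariate_names length does not match columns of z"
                )
        object.__setattr__(self, "covariate_names", names)

    @property
    def n(self) -> int:
        return self.t.size

    @property
    def p(self) -> int:
        return self.z.shape[1]

    def names(self) -> tuple[str, ...]:
        if self.covariate_names is not None:
            return self.covariate_names
        return tuple(f"z{k + 1}" for k in range(self.p))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.t, "trunc": self.r})
        for k, name in enumerate(self.names()):
            df[name] = self.z[:, k]
        return df

    def without_truncation(self) -> "RightTruncatedSample":
        """Discard the truncation structure: set every R_i to tau.

        This is the sample a naive analysis pretends to have observed; risk
        sets become ``Y_i(t) = I(T_i <= t)``.
        """
        return replace(self, r=np.full(self.n, self.tau))


@dataclass(frozen=True)
class EventGrid:
    """Tie-aggregated counting-process summaries on the distinct event times.

    ``u`` is strictly increasing; ``d[j]`` counts events tied at ``u[j]``;
    ``y[j] = #{i: t_i <= u[j] <= r_i}`` (closed risk interval on both ends);
    ``zbar[j]`` is the mean covariate among subjects at risk at ``u[j]``;
    ``event_index[i]`` is the grid row of subject ``i``'s event time.
    """

    u: np.ndarray
    d: np.ndarray
    y: np.ndarray
    zbar: np.ndarray
    event_index: np.ndarray
    n: int

    @property
    def m(self) -> int:
        return self.u.size

    def members(self, j: int) -> np.ndarray:
        """Subject indices whose event time is ``u[j]``."""
        return np.flatnonzero(self.event_index == j)


def load_sample(
    path: str | Path, covariate_names: list[str] | tuple[str, ...]
) -> RightTruncatedSample:
    """Read a right-truncated sample from CSV.

    The file must have a header with columns ``time``, ``trunc`` and each
    requested covariate; extra columns are ignored.  ``tau`` is set to
    ``max(time)``.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    needed = ["time", "trunc", *covariate_names]
    for col in needed:
        if col not in df.columns:
            raise DataFormatError(f"missing required column: {col!r}")
    sub = df[needed]
    numeric = sub.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~sub.isna()
    if bad.to_numpy().any() or numeric.isna().to_numpy().any():
        row = int(np.flatnonzero(numeric.isna().any(axis=1).to_numpy())[0])
        raise DataValidationError(f"non-numeric or missing cell in row {row}")
    return RightTruncatedSample(
        t=numeric["time"].to_numpy(),
        r=numeric["trunc"].to_numpy(),
        z=numeric[list(covariate_names)].to_numpy(),
        covariate_names=tuple(covariate_names),
    )


def write_sample(sample: RightTruncatedSample, path: str | Path) -> None:
    """Write ``time, trunc, <covariates>`` CSV that :func:`load_sample` reads back."""
    # 17 significant digits make the write/read round trip bit-exact
    sample.to_frame().to_csv(path, index=False, float_format="%.17g")


def _canonical_order(primary: np.ndarray, z: np.ndarray) -> np.ndarray:
    # lexsort with covariates as tie-breakers makes the summation order (and
    # hence the floating-point result) invariant to row permutation of the input
    keys = tuple(z[:, k] for k in reversed(range(z.shape[1]))) + (primary,)
    return np.lexsort(keys)


def risk_set_sums(
    sample: RightTruncatedSample,
    times: np.ndarray,
    subject_weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted risk-set sums at arbitrary times.

    Returns ``(sw, swz)`` where ``sw[j] = sum_{i at risk at times[j]} w_i`` and
    ``swz[j] = sum_{i at risk} w_i Z_i``.  Runs in O(n log n + m p) via
    cumulative sums over the times sorted by entry (``t``) and exit (``r``).
    """
    times = np.asarray(times, dtype=float)
    w = np.ones(sample.n) if subject_weights is None else np.asarray(subject_weights)
    z = sample.z
    ot = _canonical_order(sample.t, z)
    orr = _canonical_order(sample.r, z)
    ts, rs = sample.t[ot], sample.r[orr]
    cw_t = np.concatenate(([0.0], np.cumsum(w[ot])))
    cw_r = np.concatenate(([0.0], np.cumsum(w[orr])))
    cwz_t = np.vstack([np.zeros(sample.p), np.cumsum(w[ot, None] * z[ot], axis=0)])
    cwz_r = np.vstack([np.zeros(sample.p), np.cumsum(w[orr, None] * z[orr], axis=0)])
    i_t = np.searchsorted(ts, times, side="right")
    i_r = np.searchsorted(rs, times, side="left")
    sw = cw_t[i_t] - cw_r[i_r]
    swz = cwz_t[i_t] - cwz_r[i_r]
    return sw, swz


def build_event_grid(sample: RightTruncatedSample) -> EventGrid:
    """Aggregate the sample onto its distinct event times.

    For each distinct event time ``u_j``: the tie count ``d_j``, the at-risk
    count ``y_j`` and the risk-set covariate mean ``Zbar(u_j)``.  Counting
    integrals ``int phi dN_i`` are realised as ``phi(T_i)``; suffix integrals
    ``int_t^tau`` are sums over grid points ``u_k >= t`` (closed lower limit).
    """
    u, event_index, d = np.unique(sample.t, return_inverse=True, return_counts=True)
    y_float, sz = risk_set_sums(sample, u)
    y = np.rint(y_float).astype(int)
    if np.any(y < d):
        raise AssertionError("at-risk count below tie count; invalid risk sets")
    zbar = sz / y[:, None]
    return EventGrid(
        u=u, d=d, y=y, zbar=zbar, event_index=event_index, n=sample.n
    )
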