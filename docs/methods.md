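# Methods

## The problem

Right truncation is a retrospective sampling defect: a subject with event
time `T` and truncation time `R` enters the sample only if `T <= R`.  The
canonical example is AIDS surveillance of transfusion-infected cases, where
only incubation periods ending in a diagnosis before the close of the study
window are recorded.  Short event times are over-sampled, and any regression
that treats the observed `T` as an ordinary sample is biased toward shorter
times.

`truncpo` estimates the semiparametric proportional odds model

    log{ F(t|Z) / S(t|Z) } = alpha(t) + Z' beta,

with `F = 1 - S` the conditional distribution function, `alpha` an
unspecified nondecreasing baseline log-odds function and `beta` the log
odds-ratio coefficients.  Under this model the reverse-time (retro) hazard
`f(t|Z)/F(t|Z)` — the natural hazard for right-truncated data, because in
reverse time the sample is left-truncated and risk sets are adapted — has a
simple relationship with the baseline odds `v(t) = exp(alpha(t))`:

    lambda^B(t|Z) = v'(t) / [ v(t) {1 + v(t) exp(Z'beta)} ].

## The estimator

Work on the grid of distinct event times `u_1 < ... < u_m` with tie counts
`d_j`, truncation-adjusted risk sets `y_j = #{i : t_i <= u_j <= r_i}` (note
these grow and then shrink) and risk-set covariate means `Zbar(u_j)`.

**Baseline odds.**  For fixed `beta` the reverse-hazard identity
`v'/v = p(t) + q(t) v` — with `p` the pooled retro-hazard increment and `q`
its `exp(Z'beta)`-tilted version — integrates in closed form to

    vhat(u_j, beta) = P_j / sum_{k >= j} P_k q_k,
    P_j = exp( - sum_{k >= j} d_k / y_k ),
    q_k = sum_{i: t_i = u_k} exp(Z_i'beta) / y_k.

The minus sign in `P` comes from the counting process `N_i(t) = I(t <= T_i)`
stepping *down* in forward time, so the suffix integral of `dN` is minus the
suffix sum of tie counts; with this sign `vhat` is consistent (on n = 5000
draws from the default design its median relative error against the known
`v(t) = t^3` is about 1%).  `vhat` and its `beta`-gradient (also closed
form) are invariant to rescaling `P`, so `P` is shifted in log space and
cannot over- or underflow.  The exponential-of-sum form is kept rather than
the product-limit `prod(1 - d/y)`, which collapses to zero whenever a late
risk set is exhausted.

**Coefficients.**  `vhat` is plugged into the martingale score

    S_{n,W}(beta) = (1/n) sum_i W(T_i) {Z_i - Zbar(T_i)}
                          {exp(Z_i'beta) vhat(T_i, beta) + 1},

whose root is found by damped Newton-Raphson (closed-form Jacobian;
start at `beta = 0`; step halved up to 10 times whenever the score norm
fails to decrease; a derivative-free hybrid root search as final fallback;
convergence at max-abs score `<= 1e-8`; non-convergence is flagged, never
silent).  `Zbar(t)` is the plain risk-set mean in the weighted equation as
well — the weight multiplies the whole score term.

**Weights.**  `W` is 1 (unweighted), the Lynden-Bell survival estimate
`S_LB(t-)` (Prentice-Wilcoxon), or `S_LB(t-){1 - S_LB(t-)}` (the
variance-minimising choice, derived at `beta = 0`).  The Lynden-Bell
product-limit `F_LB(u_j) = prod_{k>j}(1 - d_k/y_k)` reuses the same risk
sets and normalises to 1 at the last event time, where identification under
right truncation ends.  Weights are evaluated at left limits (value at the
previous event time, 1 before the first) so the weight process is
predictable; at the sample sizes studied the difference from evaluation at
`t` is O(1/n).  The optimal weight's zero at the first event is kept — it
merely removes that one score term.

**Variance.**  Sandwich `U^{-1} Vhat U^{-T} / n` with `U` the closed-form
Jacobian at the root and `Vhat` the empirical second moment of the
per-subject score terms (they sum to ~0 at the root).  The asymptotic
theory defines the middle matrix only as the limiting covariance of the
normalised score; the empirical outer product is the natural plug-in and is
validated by the SEE-vs-SSE calibration test (mean estimated SE within 20%
of the Monte-Carlo SD at n = 300).  A nonparametric bootstrap over subjects
(default 200 resamples) is available as an alternative.  A constant
covariate raises a rank-deficiency error; other numerical singularity falls
back to a pseudo-inverse with a recorded warning.

**Alternative parametrisation.**  `fit_logit_link` solves the analogous
equation for the model with the logit placed on survival
(`log{S/F} = alpha + Z'beta`), which requires the `exp(Z'beta)`-tilted
risk-set mean and has no closed-form Jacobian; it is solved by a hybrid
root search with finite differences and reported in its own
parametrisation.  No numerical relation to the main fit is asserted.

## Synthetic data

The generator draws from the design used throughout the package's studies:
`alpha(t) = 3 log t` (baseline odds `t^3`), `beta0 = (1, 0.5)`,
`Z1 ~ Uniform(0, 2)`, `Z2 ~ Bernoulli(0.5)`, and `R ~ Uniform(0, c)`
independent of everything.  Failure times invert the model CDF:
`T = exp{(logit(U) - Z'beta0)/3}` for `U ~ Uniform(0,1)`.  Truncation is
realised as the selection it is — proposals with `T > R` are rejected — so
the realised rejection fraction is reported and directly comparable with
the nominal rates: P(T > R) is 20.1% for `c = 4` (mild), 38.6% for `c = 2`
(moderate) and 66.6% for `c = 1` (heavy), by adaptive quadrature of
`E_Z[(1/c) int_0^c dr / (1 + r^3 e^{Z'beta})]`.  One root seed spawns
independent per-replication streams (`numpy` `SeedSequence`), so every
study is bitwise reproducible.

What the generator does **not** emulate: covariate-dependent truncation,
censoring, ties (event times are continuous), measurement error, or the
discrete month-scale times of real surveillance data.  Passing tests
therefore demonstrate correctness of the estimating machinery under the
stated design, not robustness to those features.

## Study harness and replication layout

`run_study` reports, per coefficient component: bias, SSE (Monte-Carlo SD
of the estimates), SEE (defined here as the *mean* of the estimated
sandwich SEs — the convention is not standard and medians differ little),
and empirical coverage of 95% Wald intervals (normal quantile 1.959964),
all scaled x1000 / percent.  Replications whose fit fails to converge are
dropped and counted in the metadata; above 5% drops the table carries a
warning flag.  Default studies use 1000 replications at n in
{300, 400, 500, 600}; the acceptance checks run n in {300, 600} with 1000
replications (500 for the truncation-ignoring comparison), which keeps the
full suite under a minute on one CPU.

`run_table2` fits the *naive* estimator — identical machinery with every
`R_i` replaced by `tau`, so risk sets become `I(T_i <= t)` and the
truncation structure is discarded — across mild/moderate/heavy truncation.
It uses the Prentice-Wilcoxon weight by default: the attenuation pattern
(bias toward zero, growing with the truncation rate, variance falling in
n) is the systematic consequence of ignoring truncation, and the weighted
equation exhibits it cleanly, whereas the unweighted naive fit superimposes
the tail instability described next.

## Numerical choices and known limitations

- **Right-edge sensitivity of the unweighted equation.**  Near the end of
  observation the suffix integrals behind `vhat` average over very few
  events (under right truncation, risk sets *shrink* as `t` grows), so the
  unweighted score gives full weight to terms whose `vhat` factor is
  noisiest.  At n = 300 under mild truncation this produces a heavy right
  tail in the root's sampling distribution: Monte-Carlo bias on the order
  of 6/sqrt(n) and roughly twice the dispersion of the weighted fits, with
  slightly conservative coverage (the blown-up replications also carry huge
  standard errors, so their intervals cover).  The effect is a property of
  the estimating equation at these sample sizes, is absent from the
  weighted fits (their weights vanish exactly where the instability lives),
  and shrinks as n grows.  `fit(..., trim_upper_frac=0.05)` optionally
  zeroes the score contributions of the largest 5% of event times, which
  removes the tail (bias and SD drop roughly to the weighted fits' level);
  the default is 0 so that the default fit is the estimating equation
  exactly as defined.  Practitioners using the unweighted fit on real data
  should prefer a weighted scheme or a small trim.
- **Integration conventions.**  Suffix sums use the closed lower limit
  (`u_k >= t`); `vhat` between grid points is the right-continuous step
  from above.  The open-limit alternative changes results negligibly.
- **tau.**  Defaults to `max(t)`; every estimating quantity is a sum over
  event times, so any `tau >= max(t)` yields identical estimates.
- **Ties** are grouped on the event grid; risk intervals are closed on both
  ends (`t_i <= t <= r_i`), so a subject with `t_i = r_i` is at risk at its
  own event.
- **Overflow.**  `exp(Z'beta)` overflowing raises an explicit error
  suggesting covariate rescaling; `P` is computed in log space.
- **Exhausted interior risk sets** (`y_k = d_k`) zero the Lynden-Bell
  estimate before that point; this is permitted with a warning.
- The Lynden-Bell estimate carries no variance, and no smoothing or
  extrapolation of `alpha_hat = log vhat` below the first event time is
  provided; the estimator is only ever evaluated at event times.
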