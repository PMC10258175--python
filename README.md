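# truncpo

Proportional odds regression for **right-truncated** time-to-event data.

Right truncation arises in retrospective designs: a case enters the sample
only if its event time `T` does not exceed its truncation time `R` — for
example, an incubation period is recorded only if diagnosis happens before
the end of a surveillance window.  Short times are over-sampled, and naive
regression is biased.  `truncpo` is for biostatisticians and
epidemiologists who want covariate effects on such data with an
interpretable parameter: under the proportional odds model

    log{ F(t|Z) / S(t|Z) } = alpha(t) + Z' beta,

`exp(beta_k)` multiplies the odds of failure by any time `t` per unit of
covariate `k`, at every `t`.

The estimator exploits the reverse-time (retro) hazard, which for
right-truncated data plays the role the ordinary hazard plays for
left-truncated data.  Under the model it factorises through the baseline
odds `v(t) = exp(alpha(t))`, which has a closed-form plug-in estimate

    vhat(t, beta) = P_n(t) / int_t^tau P_n dQ_n(., beta),

built from suffix sums over truncation-adjusted risk sets; plugging it into
the martingale score

    S_n(beta) = (1/n) sum_i W(T_i) {Z_i - Zbar(T_i)} {e^{Z_i'beta} vhat(T_i, beta) + 1}

gives an estimating equation solved by damped Newton-Raphson, with sandwich
(or bootstrap) standard errors.  `W` is 1, the Lynden-Bell survival
estimate (Prentice-Wilcoxon), or `S(1-S)` — the variance-minimising weight.
A simulator and a replication harness (bias / SSE / SEE / coverage tables)
round out the package.  See `docs/methods.md` for the full account.

## Worked example

```python
from truncpo import SimConfig, fit, generate

sample, rate = generate(SimConfig(n=300, seed=42))   # ~20% truncation design
res = fit(sample)                                    # unweighted fit
```

Running `python examples/01_simulate_and_fit.py` prints:

```
n = 300, realized truncation rate = 23.9%
z1: beta = +1.073  (SE 0.451, 95% CI [+0.189, +1.956])
z2: beta = +0.733  (SE 0.478, 95% CI [-0.204, +1.671])
converged = True after 4 Newton iterations
```

The data were generated with `beta = (1.0, 0.5)`: each estimate sits well
inside its interval, and `exp(1.073) ~ 2.9` says a unit increase of `z1`
nearly triples the odds of failure by any given time.  The other examples
cover weighted estimation (`02`), the Lynden-Bell baseline distribution
(`03`), truncation rates (`04`) and the cost of ignoring truncation (`05`).

A thin CLI wraps the same functions:

```sh
trunc-po simulate --n 300 --c 4 --seed 7 --out sim.csv
trunc-po fit sim.csv --covariates z1,z2 --weight pw --out fit.json
trunc-po lyndenbell sim.csv --out lb.csv
trunc-po table1 --n 300 --reps 1000 --seed 11 --out table1.csv
```

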