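"""Generate one right-truncated dataset and fit the proportional odds model.

Draws n = 300 subjects from the default design (baseline odds v(t) = t^3,
coefficients (1, 0.5), truncation R ~ Uniform(0, 4), ~20% of the latent
population truncated away) and fits the unweighted estimating equation.
The printed coefficients are log odds ratios: exp(beta) multiplies the odds
of failure by any time t per unit of covariate.
"""

import numpy as np

from truncpo import SimConfig, fit, generate

sample, rate = generate(SimConfig(n=300, seed=42))
print(f"n = {sample.n}, realized truncation rate = {rate:.1%}")

res = fit(sample)
for name, b, se, lo, hi in zip(
    sample.names(), res.beta_hat, res.se, res.ci_low, res.ci_high
):
    print(f"{name}: beta = {b:+.3f}  (SE {se:.3f}, 95% CI [{lo:+.3f}, {hi:+.3f}])")
print(f"converged = {res.converged} after {res.n_iter} Newton iterations")
print("Generating values were (1.0, 0.5); estimates should sit within a few SEs.")
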