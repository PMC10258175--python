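"""What happens when the truncation structure is ignored.

Runs a small replication study fitting both the truncation-adjusted and the
truncation-ignoring (naive) Prentice-Wilcoxon estimator on identical
datasets at each truncation intensity.  The naive fit attenuates the
covariate effect, increasingly so as truncation gets heavier.
"""

import numpy as np

from truncpo import SimConfig, fit, fit_naive, generate

beta0 = np.array([1.0, 0.5])
reps = 60
for c, label in ((4.0, "mild"), (2.0, "moderate"), (1.0, "heavy")):
    adj, naive = [], []
    for child in np.random.SeedSequence(5).spawn(reps):
        rng = np.random.default_rng(child)
        sample, _ = generate(SimConfig(n=300, seed=5, c=c), rng=rng)
        a = fit(sample, weight_scheme="prentice_wilcoxon")
        b = fit_naive(sample, weight_scheme="prentice_wilcoxon")
        if a.converged and b.converged:
            adj.append(a.beta_hat)
            naive.append(b.beta_hat)
    adj_bias = np.mean(adj, axis=0) - beta0
    naive_bias = np.mean(naive, axis=0) - beta0
    print(
        f"{label:9s} (c={c}): adjusted bias {adj_bias.round(3)}, "
        f"naive bias {naive_bias.round(3)}"
    )
print("Naive bias is toward zero and grows with the truncation rate; the")
print("adjusted estimator tracks the truth much more closely at every level")
print("(under heavy truncation both degrade, the naive fit far more).")
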