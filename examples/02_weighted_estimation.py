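"""Compare the unweighted, Prentice-Wilcoxon and optimally weighted fits.

The weighted estimating equations multiply each event's score term by a
predictable function of the Lynden-Bell survival estimate; the weight
S(t){1 - S(t)} minimises the asymptotic variance.  On a single dataset the
weighted standard errors are visibly smaller.
"""

from truncpo import SimConfig, fit, generate

sample, _ = generate(SimConfig(n=400, seed=7))
print(f"{'scheme':20s} {'beta1':>8s} {'beta2':>8s} {'SE1':>7s} {'SE2':>7s}")
for scheme in ("unweighted", "prentice_wilcoxon", "optimal"):
    res = fit(sample, weight_scheme=scheme)
    print(
        f"{scheme:20s} {res.beta_hat[0]:8.3f} {res.beta_hat[1]:8.3f} "
        f"{res.se[0]:7.3f} {res.se[1]:7.3f}"
    )
print("Weighted fits downweight late events, where truncated risk sets are")
print("thin, and should show the smallest standard errors for 'optimal'.")
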