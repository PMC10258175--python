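"""Estimating equations, Newton solver, sandwich variance, naive and
logit-link fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from truncpo import (
    RankDeficiencyError,
    RightTruncatedSample,
    SimConfig,
    build_event_grid,
    fit,
    fit_logit_link,
    fit_lynden_bell,
    fit_naive,
    generate,
    jacobian,
    make_weights,
    sandwich_variance,
    score,
)
from truncpo.estimator import _score_logit_link

from oracles import brute_score, finite_diff_jacobian


def test_score_zero_for_constant_covariate():
    s = RightTruncatedSample(t=[1.0, 2.0, 3.0], r=[2.0, 3.0, 3.0], z=np.ones((3, 1)))
    g = build_event_grid(s)
    for beta in ([0.0], [1.3], [-2.0]):
        np.testing.assert_allclose(score(np.array(beta), g, s), 0.0, atol=1e-15)


@pytest.mark.parametrize(
    "beta", [np.zeros(2), np.array([0.5, -0.2]), np.array([1.0, 0.5])]
)
def test_score_matches_brute_force(five_sample, beta):
    g = build_event_grid(five_sample)
    expected = brute_score(five_sample.t, five_sample.r, five_sample.z, beta)
    np.testing.assert_allclose(score(beta, g, five_sample), expected, rtol=1e-12)


def test_weighted_score_matches_brute_force(five_sample):
    g = build_event_grid(five_sample)
    w = make_weights(fit_lynden_bell(g), "prentice_wilcoxon")
    beta = np.array([0.3, 0.1])
    expected = brute_score(five_sample.t, five_sample.r, five_sample.z, beta, w)
    np.testing.assert_allclose(score(beta, g, five_sample, w), expected, rtol=1e-12)


def test_jacobian_matches_finite_differences(five_sample):
    g = build_event_grid(five_sample)
    for beta in (np.zeros(2), np.array([0.4, -0.6])):
        fd = finite_diff_jacobian(lambda b: score(b, g, five_sample), beta)
        an = jacobian(beta, g, five_sample)
        np.testing.assert_allclose(an, fd, rtol=1e-5, atol=1e-9)


def test_jacobian_fd_weighted_simulated(grid_300, sim_sample_300):
    w = make_weights(fit_lynden_bell(grid_300), "optimal")
    beta = np.array([0.8, 0.3])
    fd = finite_diff_jacobian(
        lambda b: score(b, grid_300, sim_sample_300, w), beta
    )
    an = jacobian(beta, grid_300, sim_sample_300, w)
    np.testing.assert_allclose(an, fd, rtol=1e-5, atol=1e-9)


def test_jacobian_linear_in_weights(five_sample):
    g = build_event_grid(five_sample)
    beta = np.array([0.2, 0.2])
    u1 = jacobian(beta, g, five_sample)
    u3 = jacobian(beta, g, five_sample, np.full(g.m, 3.0))
    np.testing.assert_allclose(u3, 3.0 * u1, rtol=1e-12)


@given(st.integers(0, 10_000))
@settings(max_examples=20, deadline=None, derandomize=True)
def test_score_brute_force_property(seed):
    """Vectorised score equals the double-loop oracle on random small samples."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 9))
    t = rng.integers(1, 5, n).astype(float)
    r = t + rng.integers(0, 3, n)
    z = rng.integers(-1, 2, (n, 2)).astype(float)
    s = RightTruncatedSample(t=t, r=r, z=z)
    beta = rng.normal(scale=0.5, size=2)
    g = build_event_grid(s)
    np.testing.assert_allclose(
        score(beta, g, s), brute_score(t, r, z, beta), rtol=1e-10, atol=1e-12
    )


@pytest.mark.parametrize("scheme", ["unweighted", "prentice_wilcoxon", "optimal"])
def test_fit_converges_with_small_score(sim_sample_300, scheme):
    res = fit(sim_sample_300, weight_scheme=scheme)
    assert res.converged
    assert res.score_norm <= 1e-8
    assert res.cov.shape == (2, 2)
    np.testing.assert_allclose(res.se, np.sqrt(np.diag(res.cov)))
    np.testing.assert_allclose(res.cov, res.cov.T)
    assert np.all(np.linalg.eigvalsh(res.cov) >= -1e-15)


def test_parameter_recovery_large_sample():
    """At n=2000 the estimate lands within 3 SEs of the generating (1, 0.5)."""
    s, _ = generate(SimConfig(n=2000, seed=8))
    res = fit(s, weight_scheme="prentice_wilcoxon")
    assert res.converged
    np.testing.assert_array_less(
        np.abs(res.beta_hat - np.array([1.0, 0.5])), 3.0 * res.se
    )


def test_covariate_scale_equivariance(sim_sample_300):
    res = fit(sim_sample_300)
    c = 2.5
    z2 = sim_sample_300.z.copy()
    z2[:, 0] *= c
    s2 = RightTruncatedSample(t=sim_sample_300.t, r=sim_sample_300.r, z=z2)
    res2 = fit(s2)
    np.testing.assert_allclose(res2.beta_hat[0], res.beta_hat[0] / c, rtol=1e-6)
    np.testing.assert_allclose(res2.beta_hat[1], res.beta_hat[1], rtol=1e-6)
    # Wald z-statistics are invariant
    np.testing.assert_allclose(
        res2.beta_hat / res2.se, res.beta_hat / res.se, rtol=1e-5
    )


def test_covariate_shift_invariance(sim_sample_300):
    res = fit(sim_sample_300)
    s2 = RightTruncatedSample(
        t=sim_sample_300.t, r=sim_sample_300.r, z=sim_sample_300.z + 3.0
    )
    res2 = fit(s2)
    np.testing.assert_allclose(res2.beta_hat, res.beta_hat, rtol=1e-7)


def test_sandwich_constant_covariate_raises(sim_sample_300):
    z = sim_sample_300.z.copy()
    z[:, 1] = 1.0
    s = RightTruncatedSample(t=sim_sample_300.t, r=sim_sample_300.r, z=z)
    g = build_event_grid(s)
    with pytest.raises(RankDeficiencyError):
        sandwich_variance(np.array([0.5, 0.0]), g, s)


def test_sandwich_halves_under_duplication(sim_sample_300):
    res = fit(sim_sample_300)
    dup = RightTruncatedSample(
        t=np.concatenate([sim_sample_300.t] * 2),
        r=np.concatenate([sim_sample_300.r] * 2),
        z=np.vstack([sim_sample_300.z] * 2),
    )
    res2 = fit(dup)
    np.testing.assert_allclose(res2.beta_hat, res.beta_hat, rtol=1e-6)
    np.testing.assert_allclose(res2.cov, res.cov / 2.0, rtol=1e-5)


def test_bootstrap_variance_same_scale(sim_sample_300):
    res_s = fit(sim_sample_300, weight_scheme="prentice_wilcoxon")
    res_b = fit(
        sim_sample_300,
        weight_scheme="prentice_wilcoxon",
        variance="bootstrap",
        boot_reps=40,
        seed=0,
    )
    np.testing.assert_allclose(res_b.beta_hat, res_s.beta_hat)
    assert res_b.variance_method == "bootstrap"
    ratio = res_b.se / res_s.se
    assert np.all(ratio > 0.5) and np.all(ratio < 2.0)


def test_naive_equals_fit_without_truncation():
    rng = np.random.default_rng(17)
    t = rng.uniform(0.5, 3.0, 120)
    tau = t.max()
    z = np.column_stack([rng.uniform(0, 2, 120), rng.binomial(1, 0.5, 120)])
    s = RightTruncatedSample(t=t, r=np.full(120, tau), z=z)
    res = fit(s, weight_scheme="prentice_wilcoxon")
    res_naive = fit_naive(s, weight_scheme="prentice_wilcoxon")
    np.testing.assert_array_equal(res_naive.beta_hat, res.beta_hat)
    np.testing.assert_array_equal(res_naive.cov, res.cov)


def test_naive_more_biased_under_heavy_truncation():
    """Paired comparison on identical heavily truncated datasets."""
    err_adj, err_naive = [], []
    beta0 = np.array([1.0, 0.5])
    children = np.random.SeedSequence(31).spawn(30)
    for ch in children:
        rng = np.random.default_rng(ch)
        s, _ = generate(SimConfig(n=600, seed=31, c=1.0), rng=rng)
        a = fit(s, weight_scheme="prentice_wilcoxon")
        b = fit_naive(s, weight_scheme="prentice_wilcoxon")
        if a.converged and b.converged:
            err_adj.append(a.beta_hat - beta0)
            err_naive.append(b.beta_hat - beta0)
    bias_adj = np.abs(np.mean(err_adj, axis=0))
    bias_naive = np.abs(np.mean(err_naive, axis=0))
    assert bias_naive[0] > bias_adj[0]


def test_trim_matches_explicit_weight_mask(sim_sample_300, grid_300):
    res_trim = fit(sim_sample_300, trim_upper_frac=0.05)
    keep = np.ones(grid_300.m)
    keep[-int(np.ceil(0.05 * grid_300.m)):] = 0.0
    s_at = score(res_trim.beta_hat, grid_300, sim_sample_300, keep)
    assert np.max(np.abs(s_at)) <= 1e-8


def test_logit_link_constant_covariate_zero_score():
    s = RightTruncatedSample(t=[1.0, 2.0, 3.0], r=[2.0, 3.0, 3.0], z=np.ones((3, 1)))
    g = build_event_grid(s)
    np.testing.assert_allclose(
        _score_logit_link(np.array([0.7]), g, s), 0.0, atol=1e-15
    )


def test_logit_link_score_equals_plain_score_at_zero(five_sample):
    g = build_event_grid(five_sample)
    np.testing.assert_allclose(
        _score_logit_link(np.zeros(2), g, five_sample),
        score(np.zeros(2), g, five_sample),
        rtol=1e-12,
    )


def test_logit_link_brute_force(five_sample):
    """Tilted-mean estimating function matches a literal double loop."""
    import math

    g = build_event_grid(five_sample)
    beta = np.array([0.4, -0.2])
    t, r, z = five_sample.t, five_sample.r, five_sample.z
    from oracles import brute_risk_sets, brute_vhat

    u, _, at_risk = brute_risk_sets(t, r)
    uvhat = dict(zip(u, brute_vhat(t, r, z, beta)[1]))
    total = np.zeros(2)
    for i in range(5):
        uj = t[i]
        members = at_risk[u.index(uj)]
        wts = [math.exp(float(z[k] @ beta)) for k in members]
        zbar = sum(w * z[k] for w, k in zip(wts, members)) / sum(wts)
        term = math.exp(float(z[i] @ beta)) * uvhat[uj] + 1.0
        total += (z[i] - zbar) * term
    np.testing.assert_allclose(
        _score_logit_link(beta, g, five_sample), total / 5.0, rtol=1e-12
    )


def test_logit_link_fit_runs(sim_sample_300):
    res = fit_logit_link(sim_sample_300)
    assert res.converged
    assert np.all(res.se > 0)
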