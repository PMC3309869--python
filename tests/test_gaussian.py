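import numpy as np
import pytest
from scipy.stats import chi2, multivariate_normal

from rvjoint import (PermutationPlan, PhenotypeVector, center_columns,
                     lmm_profile_loglik, lrt_joint, rlrt, score_joint,
                     score_joint_components, score_joint_stat, ssu_stat,
                     sum_test, super_variant)
from rvjoint.gaussian_tests import (ScoreComponents, _batch_lrt_joint_stats,
                                    _batch_rlrt_stats, _MlProfile)
from conftest import make_genotypes, random_instance


# ---------------------------------------------------------------------------
# Sum-Test and SSU


def test_sum_test_matches_hand_computed_regression_score():
    y = PhenotypeVector([1.0, 2.0, 3.0, 4.0])
    G = make_genotypes([[0], [0], [0], [1]])
    res = sum_test(y, G, B=10, seed=0)
    # (s_c' y~)^2 / (sigma2 * s_c's_c) = 1.5^2 / ((5/3) * 0.75)
    assert res.statistic == pytest.approx(1.8)
    # independent least-squares oracle: squared score = r^2 (n-1) * varratio
    s = super_variant(G)
    slope, intercept = np.polyfit(s, y.values, 1)
    resid = y.values - (intercept + slope * s)
    s_c = s - s.mean()
    assert res.statistic == pytest.approx(
        slope ** 2 * (s_c @ s_c) / y.values.var(ddof=1))


def test_sum_test_zero_when_outcome_orthogonal_to_super_variant():
    y = PhenotypeVector([1.0, 3.0, 2.0, 2.0])    # y~ orthogonal to s_c
    G = make_genotypes([[0], [0], [0], [1]])
    assert sum_test(y, G, B=10).statistic == pytest.approx(0.0, abs=1e-12)


def test_sum_test_invariant_under_location_scale():
    rng = np.random.default_rng(0)
    y, G = random_instance(rng, 30, 3)
    y2 = PhenotypeVector(2.0 * y.values + 7.0)
    plan = PermutationPlan(30, 50, seed=4)
    r1 = sum_test(y, G, plan=plan)
    r2 = sum_test(y2, G, plan=plan)
    assert r1.statistic == pytest.approx(r2.statistic)
    assert r1.p_value == r2.p_value


def test_sum_test_rejects_constant_super_variant():
    y = PhenotypeVector([1.0, 2.0, 3.0])
    with pytest.raises(ValueError, match="super variant"):
        sum_test(y, make_genotypes(np.zeros((3, 2), dtype=int)), B=10)


def test_ssu_statistic_examples():
    y = PhenotypeVector([1.0, 2.0, 3.0, 4.0])
    G = make_genotypes([[0, 1], [0, 0], [0, 0], [1, 0]])
    assert ssu_stat(y, G, B=10).statistic == pytest.approx(4.5)
    # appending an all-zero variant changes nothing
    G2 = make_genotypes([[0, 1, 0], [0, 0, 0], [0, 0, 0], [1, 0, 0]])
    assert ssu_stat(y, G2, B=10).statistic == pytest.approx(4.5)


# ---------------------------------------------------------------------------
# joint score test


def _joint_loglik(beta, tau, y, G):
    """Dense Gaussian log-likelihood of N(alpha 1 + beta s, tau K_c + s2 I)
    with alpha = ybar and s2 the sample variance — the finite-difference
    reference for the score components."""
    yv = y.values
    s2 = yv.var(ddof=1)
    K = center_columns(G.counts) @ center_columns(G.counts).T
    mean = yv.mean() + beta * super_variant(G)
    cov = tau * K + s2 * np.eye(len(yv))
    return multivariate_normal.logpdf(yv, mean, cov)


def test_score_components_match_finite_difference_derivatives(rng):
    y, G = random_instance(rng, 20, 4)
    c = score_joint_components(y, G)
    h = 1e-6
    fd_beta = (_joint_loglik(h, 0, y, G) - _joint_loglik(-h, 0, y, G)) / (2 * h)
    fd_tau = (_joint_loglik(0, h, y, G) - _joint_loglik(0, -h, y, G)) / (2 * h)
    assert c.u_beta == pytest.approx(fd_beta, rel=1e-5)
    assert c.u_tau == pytest.approx(fd_tau, rel=1e-5)


def test_u_tau_null_moments_match_monte_carlo():
    """Under y ~ N(0, 1) independent of G, u_tau has mean ~0 and variance
    ~var_tau (both within 3 Monte-Carlo standard errors)."""
    rng = np.random.default_rng(99)
    n, m, N = 200, 4, 10000
    counts = rng.binomial(2, rng.uniform(0.05, 0.3, m), size=(n, m))
    G_c = center_columns(counts)
    tr_K = np.sum(G_c * G_c)
    GtG = G_c.T @ G_c
    var_tau = np.sum(GtG * GtG) / 2.0          # at the true sigma^2 = 1
    Y = rng.standard_normal((N, n))
    Yc = Y - Y.mean(axis=1, keepdims=True)
    s2 = Y.var(axis=1, ddof=1)
    quad = np.einsum("bj,bj->b", Yc @ G_c, Yc @ G_c)
    u = quad / (2 * s2 ** 2) - tr_K / (2 * s2)
    se_mean = u.std(ddof=1) / np.sqrt(N)
    assert abs(u.mean()) < 3 * se_mean
    m2 = u.var(ddof=1)
    m4 = np.mean((u - u.mean()) ** 4)
    se_var = np.sqrt((m4 - (N - 3) / (N - 1) * m2 ** 2) / N)
    assert abs(m2 - var_tau) < 3 * se_var


def test_u_tau_negative_when_quadratic_term_vanishes():
    # y~ orthogonal to the column space of G_c -> u_tau = -tr(K_c)/(2 s2) < 0
    G = make_genotypes([[0, 0], [1, 1], [2, 2], [1, 1]])
    y = PhenotypeVector([0.0, 1.0, 0.0, -1.0])  # orthogonal to centred column
    c = score_joint_components(y, G)
    assert c.u_tau < 0
    s2 = y.values.var(ddof=1)
    tr_K = np.sum(center_columns(G.counts) ** 2)
    assert c.u_tau == pytest.approx(-tr_K / (2 * s2))


def test_score_joint_stat_arithmetic():
    assert score_joint_stat(ScoreComponents(0.0, 0.0, 1.0, 1.0, 1.0)).statistic == 0
    c = ScoreComponents(u_beta=2.0, u_tau=3.0, var_beta=4.0, var_tau=9.0,
                        sigma2_hat=1.0)
    assert score_joint_stat(c).statistic == pytest.approx(2.0)
    with pytest.raises(ValueError):
        ScoreComponents(1.0, 1.0, 0.0, 1.0, 1.0)


def test_score_joint_single_variant_reduces_coherently():
    rng = np.random.default_rng(1)
    y, G = random_instance(rng, 40, 1)
    res = score_joint(y, G, B=30, seed=2)
    assert np.isfinite(res.statistic) and res.statistic >= 0
    # u_beta proportional to the Sum-Test score
    assert res.components.u_beta * res.components.sigma2_hat == pytest.approx(
        float(center_columns(super_variant(G)) @ center_columns(y.values)))


@pytest.mark.parametrize("method", [sum_test, ssu_stat, score_joint,
                                    lrt_joint, rlrt])
def test_statistics_invariant_under_joint_relabeling(method, rng):
    y, G = random_instance(rng, 25, 3)
    perm = rng.permutation(25)
    y2 = PhenotypeVector(y.values[perm])
    G2 = make_genotypes(G.counts[perm])
    r1 = method(y, G, B=5, seed=0)
    r2 = method(y2, G2, B=5, seed=0)
    assert r1.statistic == pytest.approx(r2.statistic, rel=1e-9, abs=1e-12)


# ---------------------------------------------------------------------------
# linear mixed model fits


def test_ml_fit_matches_dense_multivariate_normal_density(rng):
    y, G = random_instance(rng, 30, 5)
    fit = lmm_profile_loglik(y, G, with_burden=True)
    X = np.column_stack([np.ones(30), super_variant(G)])
    mean = X @ [fit.alpha_hat, fit.beta_hat]
    Gf = G.counts.astype(float)
    cov = fit.tau_hat * Gf @ Gf.T + fit.sigma2_hat * np.eye(30)
    dense = multivariate_normal.logpdf(y.values, mean, cov)
    assert fit.loglik == pytest.approx(dense, abs=1e-8)


def test_all_zero_genotypes_recover_ordinary_regression():
    y = PhenotypeVector(np.r_[1.0, 2.0, 0.5, -1.0, 3.0])
    G = make_genotypes(np.zeros((5, 2), dtype=int))
    fit = lmm_profile_loglik(y, G, with_burden=False)
    assert fit.tau_hat == 0.0
    ss = np.sum((y.values - y.values.mean()) ** 2)
    ols = -0.5 * 5 * (np.log(2 * np.pi * ss / 5) + 1)
    assert fit.loglik == pytest.approx(ols, abs=1e-10)


def test_profile_at_lambda_zero_equals_fixed_effects_loglik(rng):
    y, G = random_instance(rng, 25, 3)
    X = np.column_stack([np.ones(25), super_variant(G)])
    prof = _MlProfile(X, G.counts.astype(float))
    ll0 = prof.loglik(0.0, prof.prepare(y.values[None, :]))[0]
    # closed-form OLS maximum log-likelihood
    beta = np.linalg.lstsq(X, y.values, rcond=None)[0]
    rss = np.sum((y.values - X @ beta) ** 2)
    assert ll0 == pytest.approx(-0.5 * 25 * (np.log(2 * np.pi * rss / 25) + 1),
                                abs=1e-10)


def test_lrt_statistic_nonnegative_on_fuzz_suite():
    rng = np.random.default_rng(7)
    for _ in range(150):
        n = rng.integers(12, 30)
        m = rng.integers(1, 5)
        y, G = random_instance(rng, n, m)
        if super_variant(G).max() == super_variant(G).min():
            continue
        stats = _batch_lrt_joint_stats(y.values[None, :], G, super_variant(G))
        assert stats[0] >= 0


def test_lrt_null_statistics_are_modest():
    """Under the null, the LRT statistic is stochastically far below the
    chi-square(2) far tail (sanity against runaway optimisation)."""
    rng = np.random.default_rng(12)
    counts = rng.binomial(2, 0.15, size=(60, 4))
    G = make_genotypes(counts)
    Y = rng.standard_normal((300, 60))
    stats = _batch_lrt_joint_stats(Y, G, super_variant(G))
    assert np.median(stats) < chi2.isf(0.05, 2)
    assert stats.min() >= 0
    assert (stats < 0.1).mean() > 0.05       # positive mass near zero


def test_degenerate_design_raises():
    y = PhenotypeVector([1.0, 2.0, 3.0])
    G = make_genotypes(np.zeros((3, 1), dtype=int))
    with pytest.raises(ValueError):
        lrt_joint(y, G, B=5)


# ---------------------------------------------------------------------------
# RLRT


def _reml_dense(lam, yv, Gf):
    """Independent dense REML criterion (profiled sigma^2), for the grid oracle."""
    n = len(yv)
    X = np.ones((n, 1))
    V = np.eye(n) + lam * Gf @ Gf.T
    Vi = np.linalg.inv(V)
    XVX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XVX) @ X.T @ Vi
    ss = yv @ P @ yv
    return -0.5 * (np.linalg.slogdet(V)[1] + np.log(XVX[0, 0])
                   + (n - 1) * np.log(ss))


def test_rlrt_matches_grid_search_reml_oracle():
    rng = np.random.default_rng(21)
    counts = rng.binomial(2, 0.25, size=(30, 5))
    G = make_genotypes(counts)
    # induce signal so the optimum is interior
    y = PhenotypeVector(counts @ rng.normal(0.8, 0.3, 5) + rng.standard_normal(30))
    res = rlrt(y, G, B=5, seed=3)
    Gf = G.counts.astype(float)
    grid = np.concatenate([[0.0], np.logspace(-4, 4, 2000)])
    vals = np.array([_reml_dense(l, y.values, Gf) for l in grid])
    oracle = 2 * (vals.max() - vals[0])
    assert oracle > 0.1                      # the case genuinely is interior
    assert res.statistic == pytest.approx(oracle, abs=1e-4)


def test_rlrt_boundary_solutions_are_exact_zeros_with_positive_probability():
    rng = np.random.default_rng(31)
    counts = rng.binomial(2, 0.2, size=(40, 5))
    G = make_genotypes(counts)
    Y = rng.standard_normal((300, 40))
    stats = _batch_rlrt_stats(Y, G)
    frac_zero = (stats == 0.0).mean()
    assert 0.0 < frac_zero < 1.0
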