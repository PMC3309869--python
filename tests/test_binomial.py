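import numpy as np
import pytest
from scipy.special import expit

from rvjoint import (BINARY, PermutationPlan, PhenotypeVector,
                     glmm_laplace_loglik, lrt_joint_binary, rlrt_binary,
                     score_joint_binary, score_joint_components_binary,
                     super_variant)
from rvjoint.binomial_tests import LogisticNullFit, _batch_glmm_lrt_stats
from conftest import make_genotypes, random_instance


def _logistic_loglik(beta, y, G):
    """Null-intercept logistic log-likelihood as a function of the burden
    coefficient — the finite-difference reference for u_beta."""
    p0 = y.values.mean()
    eta = np.log(p0 / (1 - p0)) + beta * super_variant(G)
    return float(np.sum(y.values * eta - np.logaddexp(0.0, eta)))


def test_u_beta_matches_finite_difference_of_logistic_loglik(rng):
    y, G = random_instance(rng, 20, 4, trait=BINARY)
    c = score_joint_components_binary(y, G)
    h = 1e-5
    fd = (_logistic_loglik(h, y, G) - _logistic_loglik(-h, y, G)) / (2 * h)
    assert c.u_beta == pytest.approx(fd, rel=1e-5)


def test_complementing_a_balanced_outcome_flips_u_beta():
    G = make_genotypes([[0], [1], [2], [0], [1], [0]])
    y = PhenotypeVector([1, 0, 1, 0, 1, 0], BINARY)       # p0 = 0.5
    c1 = score_joint_components_binary(y, G)
    c2 = score_joint_components_binary(
        PhenotypeVector(1 - y.values, BINARY), G)
    assert c2.u_beta == pytest.approx(-c1.u_beta)


def test_all_zero_genotypes_give_zero_scores():
    y = PhenotypeVector([0, 1, 0, 1], BINARY)
    G = make_genotypes(np.zeros((4, 2), dtype=int))
    c = score_joint_components_binary(y, G)
    assert c.u_beta == 0.0 and c.u_tau == 0.0


def test_components_invariant_under_joint_relabeling(rng):
    y, G = random_instance(rng, 30, 3, trait=BINARY)
    perm = rng.permutation(30)
    c1 = score_joint_components_binary(y, G)
    c2 = score_joint_components_binary(
        PhenotypeVector(y.values[perm], BINARY), make_genotypes(G.counts[perm]))
    assert c2.u_beta == pytest.approx(c1.u_beta)
    assert c2.u_tau == pytest.approx(c1.u_tau)


def test_score_joint_binary_pvalue_on_discrete_grid(rng):
    y, G = random_instance(rng, 40, 3, trait=BINARY)
    B = 150
    res = score_joint_binary(y, G, B=B, seed=5)
    k = res.p_value * (B + 1)
    assert k == pytest.approx(round(k))
    assert 1 <= round(k) <= B + 1
    with pytest.raises(ValueError):
        score_joint_binary(y, G, B=50)        # too few to estimate variances


def test_single_class_outcome_rejected():
    G = make_genotypes([[0], [1], [2]])
    with pytest.raises(ValueError):
        PhenotypeVector([1, 1, 1], BINARY)
    with pytest.raises(ValueError):
        LogisticNullFit(1.0)


def test_laplace_at_tau_zero_equals_logistic_regression_ml(rng):
    import statsmodels.api as sm

    y, G = random_instance(rng, 60, 3, trait=BINARY)
    ll = glmm_laplace_loglik(y, G, with_burden=True, tau=0.0)
    X = sm.add_constant(super_variant(G))
    oracle = sm.Logit(y.values, X).fit(disp=0).llf
    assert ll == pytest.approx(oracle, abs=1e-6)


def test_laplace_close_to_gauss_hermite_quadrature_m1():
    """With one variant the integral over the single random effect can be
    computed by adaptive Gauss-Hermite quadrature; Laplace agrees to 0.05."""
    rng = np.random.default_rng(8)
    counts = rng.binomial(2, 0.4, size=(12, 1))
    G = make_genotypes(counts)
    y = PhenotypeVector(rng.binomial(1, 0.5, 12).astype(float), BINARY)
    tau = 0.6
    ll, theta = glmm_laplace_loglik(y, G, with_burden=False, tau=tau,
                                    return_fit=True)
    alpha, b_hat = theta[0], theta[1]
    g = counts[:, 0].astype(float)

    def joint(b):
        eta = alpha + b * g
        return (np.sum(y.values * eta - np.logaddexp(0.0, eta))
                - b ** 2 / (2 * tau))

    # adaptive GH: center on the conditional mode, scale by the curvature
    h = 1e-4
    curv = -(joint(b_hat + h) - 2 * joint(b_hat) + joint(b_hat - h)) / h ** 2
    scale = 1.0 / np.sqrt(curv)
    nodes, weights = np.polynomial.hermite_e.hermegauss(41)
    vals = (np.array([joint(b_hat + scale * x) for x in nodes])
            + nodes ** 2 / 2.0)     # divide out the e^{-x^2/2} GH weight
    log_integral = (np.log(np.sum(weights * np.exp(vals - vals.max())))
                    + vals.max() + np.log(scale) - 0.5 * np.log(2 * np.pi * tau))
    assert ll == pytest.approx(log_integral, abs=0.05)


def test_glmm_lrt_statistics_nonnegative_on_fuzz_suite():
    rng = np.random.default_rng(17)
    for _ in range(15):
        y, G = random_instance(rng, 30, 2, trait=BINARY)
        if super_variant(G).max() == super_variant(G).min():
            continue
        for burden in (True, False):
            stats = _batch_glmm_lrt_stats(y.values[None, :], G, burden)
            assert stats[0] >= 0


def test_all_zero_genotypes_give_zero_lrt_statistic():
    y = PhenotypeVector([0, 1, 1, 0, 1, 0], BINARY)
    G = make_genotypes(np.zeros((6, 3), dtype=int))
    stats = _batch_glmm_lrt_stats(y.values[None, :], G, with_burden=False)
    assert stats[0] == 0.0


def test_binary_lrt_and_rlrt_run_end_to_end(rng):
    y, G = random_instance(rng, 50, 3, trait=BINARY)
    r1 = lrt_joint_binary(y, G, B=60, seed=1)
    r2 = rlrt_binary(y, G, B=60, seed=1)
    for r in (r1, r2):
        assert r.statistic >= 0
        assert 0 < r.p_value <= 1
        assert r.n_permutations == 60
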