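"""Association tests for a continuous trait in one variant region.

Six statistics are provided.  Three are classical comparators:

* **Sum-Test** (burden): the squared score of regressing y on the collapsed
  "super variant" s_i = sum_j G_ij — one degree of freedom, optimal when all
  variant effects are equal and same-signed.
* **SSU**: U'U with U = G'(y - ybar), the sum of squared marginal scores;
  under permutation calibration it is equivalent to Goeman's score test of a
  variance component with zero-mean random effects.
* **SKAT** (delegated to :mod:`rvjoint.quadform`).

Three test a *common* burden effect beta together with *individual* random
deviations b_j ~ (0, sigma_b^2) around it, in the working model

    y = alpha 1 + beta s + G b + eps,     eps ~ N(0, sigma^2 I),

with null hypothesis beta = 0 and sigma_b^2 = 0:

* **Score-Joint**: each score component standardised by its null variance and
  summed with equal weight, T = u_beta^2/var_beta + u_tau^2/var_tau;
* **LRT-Joint**: the maximum-likelihood ratio against the intercept-only
  regression, with Gaussian b;
* **RLRT**: the restricted (REML) likelihood-ratio test of sigma_b^2 = 0 in
  the model without the burden term (random deviations only) — its null
  statistic has a point mass at exactly zero.

Because sigma_b^2 sits on the boundary of its parameter space under the null,
the usual chi-square (mixture) asymptotics are unreliable; all five
non-SKAT statistics are calibrated by outcome permutation.

The mixed-model fits use one thin SVD of G per dataset: rotating onto the
kernel's eigenvectors reduces each likelihood evaluation to O(rank) work, so
the profiled ratio lambda = sigma_b^2/sigma^2 can be optimised for thousands
of permuted outcomes at once.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import CONTINUOUS, GenotypeMatrix, PhenotypeVector, center_columns, super_variant
from .permutation import PermutationPlan, add_one_pvalue
from .results import TestResult

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreComponents", "LmmFit",
    "sum_test", "ssu_stat",
    "score_joint_components", "score_joint_stat", "score_joint",
    "lmm_profile_loglik", "lrt_joint", "rlrt",
]

#: singular values below this (relative to the largest) are treated as zero
_RANK_RTOL = 1e-12
#: profiled variance-ratio search grid for lambda = sigma_b^2 / sigma^2
_LAMBDA_GRID = np.concatenate([[0.0], np.logspace(-8.0, 8.0, 81)])
_GOLDEN_ITERS = 36


@dataclass
class ScoreComponents:
    """Two-part score for (beta, sigma_b^2) at the null, with null variances.

    ``u_beta`` is the burden score, ``u_tau`` the variance-component score;
    ``sigma2_hat`` is the null residual variance (sample variance of y).
    """

    u_beta: float
    u_tau: float
    var_beta: float
    var_tau: float
    sigma2_hat: float

    def __post_init__(self):
        if not (self.var_beta > 0 and self.var_tau > 0):
            raise ValueError("score-component variances must be positive")
        if not self.sigma2_hat > 0:
            raise ValueError("null residual variance must be positive")


@dataclass
class LmmFit:
    """A profiled linear-mixed-model fit; b is integrated out, never estimated."""

    loglik: float
    tau_hat: float
    sigma2_hat: float
    alpha_hat: float
    beta_hat: float | None = None

    def __post_init__(self):
        if self.tau_hat < 0 or not np.isfinite(self.loglik):
            raise ValueError("invalid mixed-model fit")


# ---------------------------------------------------------------------------
# permutation plumbing


def _resolve_plan(n: int, B: int, seed: int, plan: PermutationPlan | None):
    return plan if plan is not None else PermutationPlan(n, B, seed)


def _perm_outcomes(y: np.ndarray, plan: PermutationPlan) -> np.ndarray:
    """(B+1, n) outcome matrix: row 0 observed, rows 1..B permuted."""
    Y = np.empty((plan.B + 1, y.size))
    Y[0] = y
    Y[1:] = y[plan.indices()]
    return Y


def _finish(method: str, stats: np.ndarray, plan: PermutationPlan,
            **extras) -> TestResult:
    p = add_one_pvalue(stats[0], stats[1:])
    return TestResult(method=method, statistic=float(stats[0]), p_value=p,
                      n_permutations=plan.B, seed=plan.seed, **extras)


def _check_continuous(y: PhenotypeVector):
    if y.trait_type != CONTINUOUS:
        raise ValueError("this statistic expects a continuous trait")


# ---------------------------------------------------------------------------
# Sum-Test and SSU


def _batch_sum_stats(Y: np.ndarray, s: np.ndarray) -> np.ndarray:
    s_c = s - s.mean()
    ss = float(s_c @ s_c)
    if ss == 0.0:
        raise ValueError("degenerate super variant (constant)")
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sigma2 = Y.var(axis=1, ddof=1)
    return (Yc @ s_c) ** 2 / (sigma2 * ss)


def sum_test(y: PhenotypeVector, G: GenotypeMatrix, *, B: int = 2000,
             seed: int = 0, plan: PermutationPlan | None = None) -> TestResult:
    """Burden test: squared score of the simple regression of y on the
    super variant, permutation-calibrated.

    Accepts a binary trait as well: with the intercept-only logistic null the
    score residual y - p0 equals y - ybar, so the same centred formula applies
    and the scaling constant is irrelevant under permutation.
    """
    plan = _resolve_plan(y.n, B, seed, plan)
    stats = _batch_sum_stats(_perm_outcomes(y.values, plan), super_variant(G))
    return _finish("sum", stats, plan)


def _batch_ssu_stats(Y: np.ndarray, G: GenotypeMatrix) -> np.ndarray:
    Yc = Y - Y.mean(axis=1, keepdims=True)
    U = Yc @ G.counts.astype(float)
    return np.einsum("bj,bj->b", U, U)


def ssu_stat(y: PhenotypeVector, G: GenotypeMatrix, *, B: int = 2000,
             seed: int = 0, plan: PermutationPlan | None = None) -> TestResult:
    """Sum of squared marginal scores U'U, U = G'(y - ybar), permutation
    p-value.  Binary traits are accepted (see :func:`sum_test`)."""
    plan = _resolve_plan(y.n, B, seed, plan)
    stats = _batch_ssu_stats(_perm_outcomes(y.values, plan), G)
    return _finish("ssu", stats, plan)


# ---------------------------------------------------------------------------
# joint score test


def score_joint_components(y: PhenotypeVector, G: GenotypeMatrix) -> ScoreComponents:
    """Gaussian score and information for (beta, sigma_b^2) at (0, 0).

    With ytilde = y - ybar, sigma2 the sample variance of y, s_c the centred
    super variant and K_c = G_c G_c' the intercept-projected kernel:

        u_beta  = s_c' ytilde / sigma2         var_beta = s_c' s_c / sigma2
        u_tau   = ytilde' K_c ytilde / (2 sigma2^2) - tr(K_c) / (2 sigma2)
        var_tau = tr(K_c K_c) / (2 sigma2^2)

    The projected kernel appears in both the quadratic and trace terms so
    that u_tau has mean zero under the null with the intercept estimated.
    """
    _check_continuous(y)
    yv = y.values
    yt = yv - yv.mean()
    sigma2 = yv.var(ddof=1)
    s_c = center_columns(super_variant(G))
    ss = float(s_c @ s_c)
    if ss == 0.0:
        raise ValueError("degenerate super variant (constant)")
    G_c = center_columns(G.counts)
    tr_K = float(np.sum(G_c * G_c))           # tr(G_c G_c')
    if tr_K == 0.0:
        raise ValueError("null kernel: all variants constant")
    GtG = G_c.T @ G_c
    tr_KK = float(np.sum(GtG * GtG))          # tr(K_c K_c) = ||G_c'G_c||_F^2
    quad = float(np.sum((G_c.T @ yt) ** 2))   # ytilde' K_c ytilde
    return ScoreComponents(
        u_beta=float(s_c @ yt) / sigma2,
        u_tau=quad / (2 * sigma2 ** 2) - tr_K / (2 * sigma2),
        var_beta=ss / sigma2,
        var_tau=tr_KK / (2 * sigma2 ** 2),
        sigma2_hat=sigma2,
    )


def score_joint_stat(c: ScoreComponents) -> TestResult:
    """Equal-weight standardised sum T = u_beta^2/var_beta + u_tau^2/var_tau."""
    stat = c.u_beta ** 2 / c.var_beta + c.u_tau ** 2 / c.var_tau
    return TestResult(method="score_joint", statistic=float(stat), components=c)


def _batch_score_joint_stats(Y: np.ndarray, G: GenotypeMatrix,
                             s: np.ndarray) -> tuple:
    sigma2 = Y.var(axis=1, ddof=1)   # invariant when rows are permutations
    s_c = s - s.mean()
    ss = float(s_c @ s_c)
    if ss == 0.0:
        raise ValueError("degenerate super variant (constant)")
    G_c = center_columns(G.counts)
    tr_K = float(np.sum(G_c * G_c))
    if tr_K == 0.0:
        raise ValueError("null kernel: all variants constant")
    GtG = G_c.T @ G_c
    tr_KK = float(np.sum(GtG * GtG))
    Yc = Y - Y.mean(axis=1, keepdims=True)
    u_beta = (Yc @ s_c) / sigma2
    P = Yc @ G_c                                   # (B+1, m)
    u_tau = (np.einsum("bj,bj->b", P, P) / (2 * sigma2 ** 2)
             - tr_K / (2 * sigma2))
    var_beta = ss / sigma2
    var_tau = tr_KK / (2 * sigma2 ** 2)
    stats = u_beta ** 2 / var_beta + u_tau ** 2 / var_tau
    comp = ScoreComponents(u_beta=float(u_beta[0]), u_tau=float(u_tau[0]),
                           var_beta=float(var_beta[0]), var_tau=float(var_tau[0]),
                           sigma2_hat=float(sigma2[0]))
    return stats, comp


def score_joint(y: PhenotypeVector, G: GenotypeMatrix, *, B: int = 2000,
                seed: int = 0, plan: PermutationPlan | None = None) -> TestResult:
    """Joint score test of the common and individual effects, permutation
    p-value on the shared stream."""
    _check_continuous(y)
    plan = _resolve_plan(y.n, B, seed, plan)
    Y = _perm_outcomes(y.values, plan)
    stats, comp = _batch_score_joint_stats(Y, G, super_variant(G))
    return _finish("score_joint", stats, plan, components=comp)


# ---------------------------------------------------------------------------
# profiled linear mixed model via eigen-rotation


class _MlProfile:
    """Exact profiled ML of y ~ N(X gamma, sigma^2 (I + lambda G G')).

    One thin SVD of G reduces every (lambda, outcome) evaluation to
    O(rank * p) work; gamma and sigma^2 are profiled in closed form via GLS
    identities in the rotated basis.
    """

    def __init__(self, X: np.ndarray, G: np.ndarray):
        self.n, self.p = X.shape
        if self.n <= self.p:
            raise ValueError("need n > number of fixed effects")
        if np.linalg.matrix_rank(X) < self.p:
            raise ValueError("rank-deficient fixed-effect design")
        self.X = X
        U, d, _ = np.linalg.svd(np.asarray(G, dtype=float), full_matrices=False)
        keep = d > _RANK_RTOL * d[0] if d.size and d[0] > 0 else np.zeros_like(d, bool)
        self.U, self.d2 = U[:, keep], d[keep] ** 2
        self.r = self.U.shape[1]
        self.A = self.U.T @ X                      # (r, p)
        self.XtX = X.T @ X

    def prepare(self, Y: np.ndarray) -> dict:
        """Per-outcome projections; Y is (B, n)."""
        return {
            "u": Y @ self.U,                       # (B, r)
            "t": Y @ self.X,                       # (B, p)
            "yty": np.einsum("bi,bi->b", Y, Y),
        }

    def loglik(self, lam, pre: dict, want_coef: bool = False):
        """Profiled log-likelihood at lambda (scalar or per-outcome vector)."""
        u, t, yty = pre["u"], pre["t"], pre["yty"]
        B = u.shape[0]
        lam = np.broadcast_to(np.asarray(lam, dtype=float), (B,))
        if self.r:
            S = lam[:, None] * self.d2 / (1.0 + lam[:, None] * self.d2)  # (B, r)
            logdet = np.sum(np.log1p(lam[:, None] * self.d2), axis=1)
            Su = S * u
            v = t - Su @ self.A                    # (B, p)
            M = self.XtX[None] - np.einsum("ri,br,rj->bij", self.A, S, self.A)
            ytVy = yty - np.einsum("br,br->b", Su, u)
        else:
            logdet = np.zeros(B)
            v, M = t, np.broadcast_to(self.XtX, (B, self.p, self.p))
            ytVy = yty
        gamma = np.linalg.solve(M, v[..., None])[..., 0]
        rss = ytVy - np.einsum("bp,bp->b", v, gamma)
        rss = np.maximum(rss, 1e-300)
        sigma2 = rss / self.n
        ll = -0.5 * (self.n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet)
        if want_coef:
            return ll, gamma, sigma2
        return ll


class _RemlProfile:
    """Profiled REML of the same model, via the (n - p) residual contrasts.

    The rotation onto eigenvectors of the residual-projected kernel Q G G' Q
    makes the contrasts independent with variances sigma^2 (1 + lambda mu_j),
    so the restricted likelihood is an exact function of rank-many components.
    """

    def __init__(self, X: np.ndarray, G: np.ndarray):
        self.n, self.p = X.shape
        if self.n <= self.p:
            raise ValueError("need n > number of fixed effects")
        self.X = X
        self.XtX_inv = np.linalg.inv(X.T @ X)
        Gq = G - X @ (self.XtX_inv @ (X.T @ G))
        U, d, _ = np.linalg.svd(np.asarray(Gq, dtype=float), full_matrices=False)
        keep = d > _RANK_RTOL * d[0] if d.size and d[0] > 0 else np.zeros_like(d, bool)
        self.U, self.mu = U[:, keep], d[keep] ** 2
        self.r = self.U.shape[1]

    def prepare(self, Y: np.ndarray) -> dict:
        Yq = Y - (Y @ self.X) @ (self.XtX_inv @ self.X.T)
        c = Yq @ self.U
        ss_tot = np.einsum("bi,bi->b", Yq, Yq)
        return {"c2": c ** 2, "rest": ss_tot - np.einsum("br,br->b", c, c)}

    def loglik(self, lam, pre: dict):
        c2, rest = pre["c2"], pre["rest"]
        B = c2.shape[0]
        lam = np.broadcast_to(np.asarray(lam, dtype=float), (B,))
        if self.r:
            denom = 1.0 + lam[:, None] * self.mu
            ss = np.sum(c2 / denom, axis=1) + rest
            logdet = np.sum(np.log(denom), axis=1)
        else:
            ss, logdet = c2.sum(axis=1) + rest, np.zeros(B)
        ss = np.maximum(ss, 1e-300)
        df = self.n - self.p
        sigma2 = ss / df
        return -0.5 * (df * (np.log(2 * np.pi * sigma2) + 1.0) + logdet)


def _maximize_lambda(profile, pre: dict,
                     grid: np.ndarray = _LAMBDA_GRID) -> tuple:
    """Vectorised grid + golden-section maximisation of the profiled loglik.

    Returns (lambda_hat, loglik_hat) arrays, one entry per outcome row.
    lambda = 0 is always on the grid, so boundary solutions are exact zeros.
    """
    lls = np.stack([profile.loglik(lam, pre) for lam in grid])   # (L, B)
    k = np.argmax(lls, axis=0)
    best_lam = grid[k]
    best_ll = np.take_along_axis(lls, k[None], axis=0)[0]
    interior = k > 0
    if profile.r == 0 or not interior.any():
        return best_lam, best_ll
    lo = np.log(grid[np.maximum(k - 1, 1)])
    hi = np.log(grid[np.minimum(k + 1, grid.size - 1)])
    lo = np.where(k == 1, np.log(grid[1]) - 2.0, lo)   # below the first point
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo.copy(), hi.copy()
    x1 = b - invphi * (b - a)
    x2 = a + invphi * (b - a)
    f1 = profile.loglik(np.exp(x1), pre)
    f2 = profile.loglik(np.exp(x2), pre)
    for _ in range(_GOLDEN_ITERS):
        take1 = f1 > f2                  # maximum lies in [a, x2]
        b = np.where(take1, x2, b)
        a = np.where(take1, a, x1)
        new_x1 = b - invphi * (b - a)
        new_x2 = a + invphi * (b - a)
        x_eval = np.where(take1, new_x1, new_x2)
        f_eval = profile.loglik(np.exp(x_eval), pre)
        x1, x2, f1, f2 = (np.where(take1, new_x1, x2),
                          np.where(take1, x1, new_x2),
                          np.where(take1, f_eval, f2),
                          np.where(take1, f1, f_eval))
    x_best = np.where(f1 >= f2, x1, x2)
    f_best = np.maximum(f1, f2)
    improved = f_best > best_ll
    best_lam = np.where(improved & interior, np.exp(x_best), best_lam)
    best_ll = np.where(improved & interior, f_best, best_ll)
    return best_lam, best_ll


def lmm_profile_loglik(y: PhenotypeVector, G: GenotypeMatrix,
                       with_burden: bool, reml: bool = False) -> LmmFit:
    """Fit y ~ N(X gamma, sigma_b^2 G G' + sigma^2 I) by profiled ML or REML.

    X is [1, s] when ``with_burden`` (the joint model) or [1] (random
    deviations only).  The variance ratio lambda = sigma_b^2/sigma^2 is
    optimised by vectorised grid + golden section after eigen-rotation;
    tau_hat = 0 (the boundary) is returned exactly when it maximises the
    profile.
    """
    _check_continuous(y)
    n = y.n
    X = np.column_stack([np.ones(n), super_variant(G)]) if with_burden \
        else np.ones((n, 1))
    Gf = G.counts.astype(float)
    Y = y.values[None, :]
    if reml:
        profile = _RemlProfile(X, Gf)
        lam, ll = _maximize_lambda(profile, profile.prepare(Y))
        # coefficients at the optimum via the ML machinery (GLS identities)
        ml = _MlProfile(X, Gf)
        _, gamma, _ = ml.loglik(lam, ml.prepare(Y), want_coef=True)
        pre = profile.prepare(Y)
        denom = 1.0 + lam[0] * profile.mu
        ss = float(np.sum(pre["c2"][0] / denom) + pre["rest"][0])
        sigma2 = ss / (n - X.shape[1])
    else:
        profile = _MlProfile(X, Gf)
        pre = profile.prepare(Y)
        lam, ll = _maximize_lambda(profile, pre)
        _, gamma, sigma2v = profile.loglik(lam, pre, want_coef=True)
        sigma2 = float(sigma2v[0])
    if not np.isfinite(ll[0]):
        raise ValueError("non-finite mixed-model likelihood")
    return LmmFit(loglik=float(ll[0]), tau_hat=float(lam[0] * sigma2),
                  sigma2_hat=float(sigma2), alpha_hat=float(gamma[0][0]),
                  beta_hat=float(gamma[0][1]) if with_burden else None)


def _clamp(stats: np.ndarray) -> np.ndarray:
    neg = stats < 0
    if neg.any():
        worst = stats.min()
        if worst < -1e-8:
            logger.warning("clamped likelihood-ratio statistics as low as %g", worst)
        stats = np.where(neg, 0.0, stats)
    return stats


def _batch_lrt_joint_stats(Y: np.ndarray, G: GenotypeMatrix,
                           s: np.ndarray) -> np.ndarray:
    n = Y.shape[1]
    if s.max() == s.min():
        raise ValueError("degenerate super variant (constant)")
    X = np.column_stack([np.ones(n), s])
    profile = _MlProfile(X, G.counts.astype(float))
    _, ll_alt = _maximize_lambda(profile, profile.prepare(Y))
    # per-row intercept-only ML log-likelihood (invariant when rows are
    # permutations of one outcome, but computed per row for generality)
    ss0 = n * Y.var(axis=1)
    ll_null = -0.5 * n * (np.log(2 * np.pi * ss0 / n) + 1.0)
    return _clamp(2.0 * (ll_alt - ll_null))


def lrt_joint(y: PhenotypeVector, G: GenotypeMatrix, *, B: int = 2000,
              seed: int = 0, plan: PermutationPlan | None = None) -> TestResult:
    """ML likelihood-ratio test of (beta, sigma_b^2) = (0, 0) against the
    joint burden + random-deviation model, permutation-calibrated."""
    _check_continuous(y)
    plan = _resolve_plan(y.n, B, seed, plan)
    Y = _perm_outcomes(y.values, plan)
    stats = _batch_lrt_joint_stats(Y, G, super_variant(G))
    return _finish("lrt_joint", stats, plan)


def _batch_rlrt_stats(Y: np.ndarray, G: GenotypeMatrix) -> np.ndarray:
    n = Y.shape[1]
    X = np.ones((n, 1))
    profile = _RemlProfile(X, G.counts.astype(float))
    if profile.r == 0:
        raise ValueError("null kernel: all variants constant")
    pre = profile.prepare(Y)
    lam, ll_hat = _maximize_lambda(profile, pre)
    ll0 = profile.loglik(0.0, pre)
    stats = 2.0 * (ll_hat - ll0)
    stats[lam == 0.0] = 0.0          # boundary solutions are exact zeros
    return _clamp(stats)


def rlrt(y: PhenotypeVector, G: GenotypeMatrix, *, B: int = 2000,
         seed: int = 0, plan: PermutationPlan | None = None) -> TestResult:
    """REML likelihood-ratio test of sigma_b^2 = 0 with intercept-only fixed
    effects: the restricted-likelihood analogue of the SSU/Goeman test.

    Under the null a positive fraction of statistics is exactly zero (the
    profiled variance ratio sits on the boundary), which is why calibration
    is by permutation and why the p-value distribution has a point mass at
    its maximum attainable value."""
    _check_continuous(y)
    plan = _resolve_plan(y.n, B, seed, plan)
    Y = _perm_outcomes(y.values, plan)
    stats = _batch_rlrt_stats(Y, G)
    return _finish("rlrt", stats, plan)
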