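"""Binary-trait versions of the association tests under a logistic model.

The working model mirrors the continuous case on the logit scale:

    logit P(y_i = 1) = alpha + beta s_i + G_i b,    b_j ~ (0, tau I),

with s the collapsed super variant.  The intercept-only null is closed form
(alpha0 = logit(ybar)), so the score residual is r = y - p0 with null weight
w0 = p0 (1 - p0).

The joint score components are the efficient-score analogues of the Gaussian
case, u_beta = s_c' r and u_tau = (r' K_c r - w0 tr K_c) / 2; their null
variances are estimated empirically from the permutation stream itself (a
symmetric function of the stream, so exchangeability — and hence permutation
validity — is preserved) and applied identically to the observed and every
permuted statistic.

The likelihood-ratio tests integrate the random deviations out with a Laplace
approximation: an inner Newton optimisation of the joint log-density over
(fixed effects, b) plus the half log-determinant curvature correction,
profiled over tau >= 0.  Because the tau boundary again breaks the standard
chi-square asymptotics, every binary test is permutation-calibrated.

The burden (Sum) and SSU statistics need no binary-specific code: with the
intercept-only logistic null, y - p0 equals y - ybar, so the functions in
:mod:`rvjoint.gaussian_tests` apply verbatim (their scaling constants cancel
under permutation).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .core import BINARY, GenotypeMatrix, PhenotypeVector, center_columns, super_variant
from .gaussian_tests import ScoreComponents, _clamp, _finish, _perm_outcomes, _resolve_plan
from .permutation import PermutationPlan
from .results import TestResult

logger = logging.getLogger(__name__)

__all__ = [
    "LogisticNullFit", "score_joint_components_binary", "score_joint_binary",
    "glmm_laplace_loglik", "lrt_joint_binary", "rlrt_binary",
]

_NEWTON_MAX_ITER = 100
_NEWTON_GTOL = 1e-4
_STEP_CLIP = 5.0
#: search grid for the random-effect variance tau in the Laplace profile
_TAU_GRID = np.concatenate([[0.0], np.logspace(-2.0, 1.0, 4)])
_TAU_GOLDEN_ITERS = 8


@dataclass
class LogisticNullFit:
    """Closed-form intercept-only logistic null: p0 = ybar, w0 = p0 (1 - p0)."""

    p0: float

    def __post_init__(self):
        if not 0.0 < self.p0 < 1.0:
            raise ValueError("null probability must lie strictly in (0, 1)")

    @property
    def w0(self) -> float:
        return self.p0 * (1.0 - self.p0)


def _check_binary(y: PhenotypeVector):
    if y.trait_type != BINARY:
        raise ValueError("this statistic expects a binary trait")


def score_joint_components_binary(y: PhenotypeVector, G: GenotypeMatrix,
                                  plan: PermutationPlan | None = None
                                  ) -> ScoreComponents:
    """Joint score components at the logistic null.

    With r = y - p0 and the intercept-projected kernel K_c = G_c G_c':

        u_beta = s_c' r,    u_tau = (r' K_c r - w0 tr K_c) / 2.

    When a permutation ``plan`` is supplied the component variances are the
    sample variances over the permuted stream; without one the components are
    returned unstandardised (variances set to 1), which is how
    :func:`score_joint_binary` consumes them before standardising against its
    own stream.  ``sigma2_hat`` carries w0.
    """
    _check_binary(y)
    yv = y.values
    null = LogisticNullFit(float(yv.mean()))
    r = yv - null.p0
    # a constant super variant (e.g. all-zero G) gives u_beta = u_tau = 0;
    # degeneracy is only an error where standardisation is required
    s_c = center_columns(super_variant(G))
    G_c = center_columns(G.counts)
    tr_K = float(np.sum(G_c * G_c))
    u_beta = float(s_c @ r)
    u_tau = (float(np.sum((G_c.T @ r) ** 2)) - null.w0 * tr_K) / 2.0
    var_beta = var_tau = 1.0
    if plan is not None:
        R = _perm_outcomes(r, plan)[1:]
        ub = R @ s_c
        P = R @ G_c
        ut = (np.einsum("bj,bj->b", P, P) - null.w0 * tr_K) / 2.0
        var_beta = float(np.var(ub, ddof=1))
        var_tau = float(np.var(ut, ddof=1))
        if var_beta <= 0 or var_tau <= 0:
            raise ValueError("zero empirical score variance (degenerate genotypes)")
    return ScoreComponents(u_beta=u_beta, u_tau=u_tau, var_beta=var_beta,
                           var_tau=var_tau, sigma2_hat=null.w0)


def _batch_score_joint_binary(Y: np.ndarray, G: GenotypeMatrix) -> tuple:
    p0 = Y[0].mean()
    if not 0.0 < p0 < 1.0:
        raise ValueError("binary trait needs both classes present")
    w0 = p0 * (1 - p0)
    R = Y - p0
    s_c = center_columns(super_variant(G))
    if float(s_c @ s_c) == 0.0:
        raise ValueError("degenerate super variant (constant)")
    G_c = center_columns(G.counts)
    tr_K = float(np.sum(G_c * G_c))
    u_beta = R @ s_c
    P = R @ G_c
    u_tau = (np.einsum("bj,bj->b", P, P) - w0 * tr_K) / 2.0
    var_beta = float(np.var(u_beta[1:], ddof=1))
    var_tau = float(np.var(u_tau[1:], ddof=1))
    if var_beta <= 0 or var_tau <= 0:
        raise ValueError("zero empirical score variance (degenerate genotypes)")
    stats = u_beta ** 2 / var_beta + u_tau ** 2 / var_tau
    comp = ScoreComponents(u_beta=float(u_beta[0]), u_tau=float(u_tau[0]),
                           var_beta=var_beta, var_tau=var_tau, sigma2_hat=w0)
    return stats, comp


def score_joint_binary(y: PhenotypeVector, G: GenotypeMatrix, *, B: int = 2000,
                       seed: int = 0, plan: PermutationPlan | None = None
                       ) -> TestResult:
    """Joint score test for a binary trait, standardised by permutation-stream
    variances shared between the observed and permuted statistics."""
    _check_binary(y)
    plan = _resolve_plan(y.n, B, seed, plan)
    if plan.B < 100:
        raise ValueError("need at least 100 permutations to estimate the "
                         "score-component variances")
    Y = _perm_outcomes(y.values, plan)
    stats, comp = _batch_score_joint_binary(Y, G)
    return _finish("score_joint", stats, plan, components=comp)


# ---------------------------------------------------------------------------
# Laplace-approximate logistic mixed model


class _LaplaceEngine:
    """Batched Laplace approximation to the logistic mixed-model likelihood.

    Works on a (B, n) block of outcome vectors at once.  For each outcome and
    a given tau, an inner Newton ascent maximises the penalised joint
    log-density over (fixed effects, b); the approximate integrated
    log-likelihood is the maximum plus the Gaussian curvature correction
    -1/2 log det(I + tau G' W G).  All heavy steps are (B x n) matrix
    products, so profiling tau across thousands of permuted outcomes is
    feasible.
    """

    def __init__(self, Y: np.ndarray, G: np.ndarray, with_burden: bool):
        self.Y = Y
        self.Bn, self.n = Y.shape
        self.m = G.shape[1]
        cols = [np.ones(self.n)]
        if with_burden:
            cols.append(G.sum(axis=1))
        self.p = len(cols)
        self.Xf = np.column_stack(cols + [G])          # (n, p + m)
        q = self.p + self.m
        self.q = q
        self.KR = (self.Xf[:, :, None] * self.Xf[:, None, :]).reshape(self.n, q * q)
        self.GG = (G[:, :, None] * G[:, None, :]).reshape(self.n, self.m * self.m)
        p0 = np.clip(Y.mean(axis=1), 1e-12, 1 - 1e-12)
        self.theta = np.zeros((self.Bn, q))
        self.theta[:, 0] = np.log(p0 / (1 - p0))

    def _objective(self, eta: np.ndarray, tau: np.ndarray) -> np.ndarray:
        ll = np.einsum("bi,bi->b", self.Y, eta) - np.logaddexp(0.0, eta).sum(axis=1)
        b = self.theta[:, self.p:]
        with np.errstate(divide="ignore", invalid="ignore"):
            pen = np.where(tau > 0, np.einsum("bj,bj->b", b, b) / (2 * tau), 0.0)
        return ll - pen

    def loglik(self, tau) -> np.ndarray:
        """Laplace log-likelihood at tau (scalar or per-outcome vector).

        tau = 0 reduces exactly to ordinary logistic regression on the fixed
        effects (b pinned at zero).  The inner Newton warm-starts from the
        previous call, so ascending tau schedules converge in a few steps.
        """
        tau = np.broadcast_to(np.asarray(tau, dtype=float), (self.Bn,)).copy()
        free_b = tau > 0
        inv_tau = np.where(free_b, 1.0 / np.where(free_b, tau, 1.0), 0.0)
        self.theta[:, self.p:] *= free_b[:, None]
        diag_idx = np.arange(self.p, self.q)
        # active-set Newton: converged outcome rows drop out of the batch and
        # their linear predictor is cached for the final likelihood pass
        eta_full = np.empty_like(self.Y)
        mu_full = np.empty_like(self.Y)
        active = np.arange(self.Bn)
        for it in range(_NEWTON_MAX_ITER):
            th = self.theta[active]
            eta = th @ self.Xf.T
            mu = expit(eta)
            grad = (self.Y[active] - mu) @ self.Xf
            grad[:, self.p:] -= th[:, self.p:] * inv_tau[active, None]
            # where tau == 0, b stays pinned at zero
            grad[:, self.p:] *= free_b[active, None]
            gmax = np.abs(grad).max(axis=1)
            keep = gmax >= _NEWTON_GTOL
            if not keep.all():
                done = active[~keep]
                eta_full[done] = eta[~keep]
                mu_full[done] = mu[~keep]
                active = active[keep]
                if active.size == 0:
                    break
                mu, grad = mu[keep], grad[keep]
            w = np.clip(mu * (1 - mu), 1e-10, None)
            H = (w @ self.KR).reshape(-1, self.q, self.q)
            H[:, diag_idx, diag_idx] += (inv_tau[active, None]
                                         + (~free_b[active, None]) * 1e8)
            delta = np.linalg.solve(H, grad[..., None])[..., 0]
            np.clip(delta, -_STEP_CLIP, _STEP_CLIP, out=delta)
            self.theta[active] += delta
        else:
            raise RuntimeError(
                f"inner Newton failed to converge after {_NEWTON_MAX_ITER} "
                f"iterations (max |grad| = {gmax.max():.3g})")
        obj = self._objective(eta_full, tau)
        if not free_b.any():
            return obj
        w = np.clip(mu_full * (1 - mu_full), 1e-10, None)
        GtWG = (w @ self.GG).reshape(self.Bn, self.m, self.m)
        M = np.broadcast_to(np.eye(self.m), GtWG.shape).copy()
        M += tau[:, None, None] * GtWG
        _, logdet = np.linalg.slogdet(M)
        return obj - 0.5 * np.where(free_b, logdet, 0.0)

    def _subset(self, idx: np.ndarray) -> "_LaplaceEngine":
        """A view-engine on a subset of outcome rows (shares design matrices)."""
        sub = object.__new__(_LaplaceEngine)
        sub.__dict__.update(self.__dict__)
        sub.Y = self.Y[idx]
        sub.theta = self.theta[idx].copy()
        sub.Bn = idx.size
        return sub

    def profile_tau(self) -> tuple:
        """Maximise over tau >= 0: coarse grid (warm-started, ascending) plus
        a vectorised golden-section refinement on the rows whose grid optimum
        is interior (boundary rows keep their exact tau = 0 value)."""
        lls = np.stack([self.loglik(t) for t in _TAU_GRID])     # (L, B)
        k = np.argmax(lls, axis=0)
        best_tau = _TAU_GRID[k]
        best_ll = np.take_along_axis(lls, k[None], axis=0)[0]
        interior = np.flatnonzero(k > 0)
        if interior.size:
            sub = self._subset(interior)
            ks = k[interior]
            lo = np.log(_TAU_GRID[np.maximum(ks - 1, 1)])
            hi = np.log(_TAU_GRID[np.minimum(ks + 1, _TAU_GRID.size - 1)])
            lo = np.where(ks == 1, np.log(_TAU_GRID[1]) - 2.0, lo)
            invphi = (np.sqrt(5.0) - 1.0) / 2.0
            a, b = lo, hi
            x1 = b - invphi * (b - a)
            x2 = a + invphi * (b - a)
            f1 = sub.loglik(np.exp(x1))
            f2 = sub.loglik(np.exp(x2))
            for _ in range(_TAU_GOLDEN_ITERS):
                take1 = f1 > f2
                b = np.where(take1, x2, b)
                a = np.where(take1, a, x1)
                new_x1 = b - invphi * (b - a)
                new_x2 = a + invphi * (b - a)
                f_eval = sub.loglik(np.exp(np.where(take1, new_x1, new_x2)))
                x1, x2, f1, f2 = (np.where(take1, new_x1, x2),
                                  np.where(take1, x1, new_x2),
                                  np.where(take1, f_eval, f2),
                                  np.where(take1, f1, f_eval))
            x_best = np.where(f1 >= f2, x1, x2)
            f_best = np.maximum(f1, f2)
            improve = f_best > best_ll[interior]
            best_tau[interior] = np.where(improve, np.exp(x_best), best_tau[interior])
            best_ll[interior] = np.where(improve, f_best, best_ll[interior])
        return best_tau, best_ll


def glmm_laplace_loglik(y: PhenotypeVector, G: GenotypeMatrix,
                        with_burden: bool, tau: float,
                        return_fit: bool = False):
    """Laplace-approximate integrated log-likelihood of the logistic mixed
    model at a candidate random-effect variance tau >= 0.

    Deterministic given inputs; tau = 0 equals the ordinary logistic-regression
    maximum log-likelihood on the fixed effects.  With ``return_fit`` the
    maximising (fixed effects, b) vector is also returned.
    """
    _check_binary(y)
    if tau < 0:
        raise ValueError("tau must be >= 0")
    eng = _LaplaceEngine(y.values[None, :], G.counts.astype(float), with_burden)
    ll = float(eng.loglik(tau)[0])
    if return_fit:
        return ll, eng.theta[0].copy()
    return ll


def _batch_glmm_lrt_stats(Y: np.ndarray, G: GenotypeMatrix,
                          with_burden: bool) -> np.ndarray:
    p0 = Y.mean(axis=1)      # invariant when rows are permutations
    null_ll = Y.shape[1] * (p0 * np.log(p0) + (1 - p0) * np.log(1 - p0))
    if not G.counts.any():
        # no genetic variation at all: the alternative collapses to the null
        return np.zeros(Y.shape[0])
    s = super_variant(G)
    if with_burden and s.max() == s.min():
        raise ValueError("degenerate super variant (constant)")
    eng = _LaplaceEngine(Y, G.counts.astype(float), with_burden)
    _, ll = eng.profile_tau()
    return _clamp(2.0 * (ll - null_ll))


def lrt_joint_binary(y: PhenotypeVector, G: GenotypeMatrix, *, B: int = 2000,
                     seed: int = 0, plan: PermutationPlan | None = None
                     ) -> TestResult:
    """Laplace-ML likelihood-ratio test of the joint burden + random-deviation
    logistic model against the intercept-only null, permutation-calibrated."""
    _check_binary(y)
    plan = _resolve_plan(y.n, B, seed, plan)
    Y = _perm_outcomes(y.values, plan)
    stats = _batch_glmm_lrt_stats(Y, G, with_burden=True)
    return _finish("lrt_joint", stats, plan)


def rlrt_binary(y: PhenotypeVector, G: GenotypeMatrix, *, B: int = 2000,
                seed: int = 0, plan: PermutationPlan | None = None
                ) -> TestResult:
    """Likelihood-ratio test of the random-deviation variance alone (no burden
    term) for a binary trait, on the tau boundary, permutation-calibrated."""
    _check_binary(y)
    plan = _resolve_plan(y.n, B, seed, plan)
    Y = _perm_outcomes(y.values, plan)
    stats = _batch_glmm_lrt_stats(Y, G, with_burden=False)
    return _finish("rlrt", stats, plan)
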