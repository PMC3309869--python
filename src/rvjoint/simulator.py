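"""Genotype and trait simulator for the rare-variant study design.

Genotypes for a region of m = n_causal + n_neutral variants are generated by
dichotomising a latent multivariate normal vector with AR(1) correlation
(corr(i, j) = rho^|i-j|): each subject receives two independent latent draws
(two haplotypes), each latent coordinate is thresholded so the haplotype
allele frequency hits a per-variant target drawn from Uniform(maf_low,
maf_high), and the genotype is the haplotype sum in {0, 1, 2}.  This yields
correlated rare variants with realistic in-sample monomorphism at rare MAFs.

Traits: continuous y = G beta + eps with standard normal errors, or binary
y ~ Bernoulli(expit(beta0 + G beta)) with beta0 = logit(prevalence)
(prospective sampling; prevalence 0.5 by default).

Five effect-vector settings span the space of association patterns on the
causal slots (scale c = effect_scale, the mean absolute effect):

1. all equal +c (favours burden-style tests);
2. half +c, half -c — zero average effect;
3. same-signed linear ramp from 0.25c to 1.75c (mean c);
4. the setting-3 ramp with alternating signs, centred to mean exactly 0;
5. all +c except two at -c.

Neutral slots are always exactly zero.  Defaults follow the study design this
package reproduces: n = 1000 subjects, 10 causal rare variants, MAF targets in
(0.001, 0.01), effect scale 0.4 trait units per allele for continuous traits
and log(2) (average odds ratio 2) for binary traits.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .core import BINARY, CONTINUOUS, GenotypeMatrix, PhenotypeVector

__all__ = ["SimulationConfig", "EffectVector", "ar1_correlation",
           "maf_threshold", "simulate_genotypes", "effect_vector",
           "simulate_trait", "simulate_dataset"]

SETTINGS = (1, 2, 3, 4, 5, "null")


@dataclass
class SimulationConfig:
    """One simulation scenario; defaults are the study's stated conditions."""

    n: int = 1000
    n_causal: int = 10
    n_neutral: int = 0
    rho: float = 0.0
    maf_low: float = 0.001
    maf_high: float = 0.01
    setting: object = "null"
    trait_type: str = CONTINUOUS
    effect_scale: float | None = None
    prevalence: float = 0.5
    #: when True (default) all variants share one AR(1) latent vector; when
    #: False the neutral variants are generated independently of the causal
    #: block (and of each other).
    neutral_correlated: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("need n >= 2 subjects")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("need 0 <= rho < 1")
        if not 0.0 < self.maf_low <= self.maf_high < 0.5:
            raise ValueError("need 0 < maf_low <= maf_high < 0.5")
        if self.setting not in SETTINGS:
            raise ValueError(f"setting must be one of {SETTINGS}")
        if self.trait_type not in (CONTINUOUS, BINARY):
            raise ValueError("trait_type must be continuous or binary")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.setting in (2, 4) and self.n_causal % 2:
            raise ValueError("settings 2 and 4 need an even number of causal variants")
        if self.effect_scale is None:
            self.effect_scale = 0.4 if self.trait_type == CONTINUOUS else float(np.log(2.0))

    @property
    def m(self) -> int:
        return self.n_causal + self.n_neutral


@dataclass
class EffectVector:
    """Per-variant coefficients; zeros on the neutral slots."""

    betas: np.ndarray
    n_causal: int

    def __post_init__(self):
        self.betas = np.asarray(self.betas, dtype=float)
        if np.any(self.betas[self.n_causal:] != 0.0):
            raise ValueError("neutral slots must be exactly zero")


def ar1_correlation(m: int, rho: float) -> np.ndarray:
    """AR(1) correlation matrix, entry (i, j) = rho^|i-j|."""
    if not 0.0 <= rho < 1.0:
        raise ValueError("need 0 <= rho < 1")
    idx = np.arange(m)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def maf_threshold(p: float) -> float:
    """Latent normal threshold t with P(Z > t) = p; allele = 1{latent > t}."""
    if not 0.0 < p <= 0.5:
        raise ValueError("target MAF must lie in (0, 0.5]")
    return float(norm.isf(p))


def _latent_cholesky(cfg: SimulationConfig) -> np.ndarray:
    if cfg.neutral_correlated:
        return np.linalg.cholesky(ar1_correlation(cfg.m, cfg.rho))
    L = np.eye(cfg.m)
    L[:cfg.n_causal, :cfg.n_causal] = np.linalg.cholesky(
        ar1_correlation(cfg.n_causal, cfg.rho))
    return L


def simulate_genotypes(cfg: SimulationConfig,
                       rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Draw one genotype matrix: two thresholded latent haplotypes per subject.

    Per-variant target MAFs are redrawn from Uniform(maf_low, maf_high) each
    call; causal variants occupy the first ``n_causal`` columns.  In-sample
    monomorphic columns are possible (and expected) at rare MAFs — downstream
    statistics tolerate all-zero columns.
    """
    if rng is None:
        rng = np.random.Generator(np.random.Philox(cfg.seed))
    mafs = rng.uniform(cfg.maf_low, cfg.maf_high, size=cfg.m)
    thresholds = norm.isf(mafs)
    L = _latent_cholesky(cfg)
    Z = rng.standard_normal(size=(2, cfg.n, cfg.m)) @ L.T
    counts = (Z > thresholds[None, None, :]).sum(axis=0).astype(np.int16)
    samples = [f"S{i:05d}" for i in range(cfg.n)]
    variants = ([f"RV{j + 1}" for j in range(cfg.n_causal)]
                + [f"NV{j + 1}" for j in range(cfg.n_neutral)])
    return GenotypeMatrix(samples, variants, counts)


def effect_vector(cfg: SimulationConfig) -> EffectVector:
    """Coefficient vector for the scenario's setting (see module docstring)."""
    c = cfg.effect_scale
    k = cfg.n_causal
    if cfg.setting == "null":
        causal = np.zeros(k)
    elif cfg.setting == 1:
        causal = np.full(k, c)
    elif cfg.setting == 2:
        # alternate the signs so adjacent (AR-correlated) variants oppose
        # each other; half +c, half -c, mean exactly zero
        causal = c * np.where(np.arange(k) % 2, -1.0, 1.0)
    elif cfg.setting == 3:
        causal = c * np.linspace(0.25, 1.75, k)
    elif cfg.setting == 4:
        ramp = c * np.linspace(0.25, 1.75, k) * np.where(np.arange(k) % 2, -1.0, 1.0)
        causal = ramp - ramp.mean()
    elif cfg.setting == 5:
        causal = np.full(k, c)
        causal[-2:] = -c
    betas = np.concatenate([causal, np.zeros(cfg.n_neutral)])
    return EffectVector(betas, n_causal=k)


def simulate_trait(G: GenotypeMatrix, betas: np.ndarray, cfg: SimulationConfig,
                   rng: np.random.Generator | None = None) -> PhenotypeVector:
    """Draw the trait given genotypes and coefficients."""
    if rng is None:
        rng = np.random.Generator(np.random.Philox(cfg.seed))
    eta = G.counts @ np.asarray(betas, dtype=float)
    if cfg.trait_type == CONTINUOUS:
        y = eta + rng.standard_normal(G.n)
        return PhenotypeVector(y, CONTINUOUS)
    beta0 = float(np.log(cfg.prevalence / (1 - cfg.prevalence)))
    y = rng.binomial(1, expit(beta0 + eta)).astype(float)
    return PhenotypeVector(y, BINARY)


def simulate_dataset(cfg: SimulationConfig,
                     rng: np.random.Generator | None = None):
    """One (genotypes, phenotype, effects) replicate from a single seed."""
    if rng is None:
        rng = np.random.Generator(np.random.Philox(cfg.seed))
    G = simulate_genotypes(cfg, rng)
    ev = effect_vector(cfg)
    y = simulate_trait(G, ev.betas, cfg, rng)
    return G, y, ev
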