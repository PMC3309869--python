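# rvjoint

Region-based association tests for **rare variants** that jointly examine a
common (burden) effect and individual per-variant deviations from it, with
permutation calibration throughout — plus the classical Sum-Test, SSU and
SKAT comparators, a genotype/trait simulator, and a study driver that
estimates type I error and power over a scenario grid.

## The problem and the tests

Single-variant association tests have essentially no power for variants with
minor-allele frequency below 1%, so sequencing studies test a *set* of rare
variants (a gene or region) jointly. The two classical strategies sit at
opposite extremes. Burden (collapsing) tests regress the trait on the
per-subject total minor-allele count `s_i = Σ_j G_ij` (the "super variant"):
one degree of freedom, optimal when every variant pushes the trait the same
way, powerless when effects oppose each other. Variance-component tests (SSU,
Goeman's test, SKAT) treat the per-variant coefficients as zero-mean random
effects and test their variance: robust to mixed signs, but they pool all
effects toward zero and ignore any shared average effect.

`rvjoint` implements tests built on the working model

    y_i = α + β s_i + Σ_j G_ij b_j + ε_i,        b_j ~ (0, σ_b²),

(logit scale for a binary trait), where β is the *average* effect across
variants and the random `b_j` are individual deviations from it. The null of
no association is H₀: β = 0, σ_b² = 0. Three tests of this structure are
provided:

* **Score-Joint** — `T = u_β²/v_β + u_τ²/v_τ`, the two score components
  (burden score and variance-component score) each standardised by its null
  variance and given equal weight. For a continuous trait, with
  `ỹ = y − ȳ`, `σ̂²` the sample variance of `y` and `K_c = G_c G_c'` the
  column-centred kernel:
  `u_β = s_c'ỹ/σ̂²`, `u_τ = ỹ'K_c ỹ/(2σ̂⁴) − tr(K_c)/(2σ̂²)`.
* **LRT-Joint** — the maximum-likelihood ratio of the joint model (Gaussian
  `b`) against the intercept-only fit.
* **RLRT** — the restricted (REML) likelihood-ratio test of σ_b² = 0 in the
  model *without* the burden term: the likelihood-ratio analogue of SSU /
  Goeman. Its null statistic has a point mass at exactly zero.

Because σ_b² lies on the boundary of its parameter space under the null, the
usual 50:50 chi-square mixture is unreliable; all of these tests (and the
Sum-Test and SSU comparators) are calibrated by permuting the outcome across
subjects, with the add-one rule `p = (1 + #{T_b ≥ T_obs})/(B + 1)`. SKAT
keeps its analytic p-value: the tail of a positive mixture of χ²₁ variables
computed by characteristic-function inversion (Davies-style), with a
three-moment fallback.

The mixed-model machinery is fast: one thin SVD of `G` per dataset reduces
each profiled (restricted) likelihood evaluation to O(rank) work, so a
likelihood-ratio statistic can be re-maximised for thousands of permuted
outcomes at once; the binary-trait mixed model uses a batched Laplace
approximation with an inner Newton ascent.

## Worked example

```python
import numpy as np
from rvjoint import SimulationConfig, simulate_dataset, replicate_pvalues
from rvjoint.permutation import PermutationPlan

# 1000 subjects, 10 correlated rare variants (MAF ~ U(0.001, 0.01)),
# all ten variants sharing a +0.4 effect on a continuous trait
cfg = SimulationConfig(n=1000, n_causal=10, rho=0.5, setting=1, seed=7)
G, y, effects = simulate_dataset(cfg)

plan = PermutationPlan(n=cfg.n, B=2000, seed=1)
pvals = replicate_pvalues(G, y, ["sum", "score_joint", "rlrt", "skat"], plan)
for method, p in pvals.items():
    print(f"{method:12s} p = {p:.4g}")
```

Output from this exact script:

```
sum          p = 0.0004998
score_joint  p = 0.0004998
rlrt         p = 0.003498
skat         p = 0.002738
```

All four tests detect the shared effect. The burden-aware tests (Sum-Test
and Score-Joint) are the most sensitive here — their permutation p-values hit
the smallest value attainable with B = 2000 permutations, 1/2001 ≈ 0.0005 —
exactly the regime (equal, same-signed effects) where pooling toward a
common β pays off. Under a sign-balanced alternative (`setting=2`) the
burden test's p-value collapses toward uniformity while the
variance-component tests retain power.

The same tests run from the shell on VCF/TSV inputs:

```bash
rvjoint simulate --config sim.yaml --out data/
rvjoint test --geno data/genotypes.tsv --pheno data/phenotypes.tsv \
        --sets data/sets.tsv --tests sum,ssu,score_joint,lrt_joint,rlrt,skat \
        --perms 2000 --seed 1 --out results/
rvjoint study --config study.yaml --out study_out/
```

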