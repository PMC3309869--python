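# Methods

## Models and statistics

All tests operate on one variant set at a time: an `n × m` matrix `G` of
minor-allele counts (entries in {0, 1, 2}) and an outcome `y`, continuous or
binary. The package's working model adds the collapsed "super variant"
`s = G·1` as a fixed effect alongside zero-mean random per-variant
deviations:

    continuous:  y = α1 + βs + Gb + ε,   ε ~ N(0, σ²I),  b ~ (0, σ_b²I)
    binary:      logit P(y=1) = α1 + βs + Gb

with the null hypothesis β = 0 and σ_b² = 0. β carries the average effect
across the set's variants; b the individual deviations from it.

**Score-Joint (continuous).** With `ỹ = y − ȳ`, `σ̂²` the sample variance of
`y` (denominator n − 1), `s_c` the centred super variant, `G_c` the
column-centred counts and `K_c = G_c G_c'`:

    u_β = s_c'ỹ / σ̂²                    v_β = s_c's_c / σ̂²
    u_τ = ỹ'K_c ỹ/(2σ̂⁴) − tr K_c/(2σ̂²)  v_τ = tr(K_c K_c)/(2σ̂⁴)
    T   = u_β²/v_β + u_τ²/v_τ

The intercept-projected (centred) kernel appears in both the quadratic and
the trace term, which makes E[u_τ] = 0 under the null with the intercept
estimated; a Monte-Carlo moment test in the suite verifies both null moments.
`v_τ` omits the O(1/n) correction for estimating σ̂²: the null distribution
comes from permutation, not from a χ² approximation, so the standardisation
constants only have to be permutation-invariant — which they are.

**Score-Joint (binary).** The intercept-only logistic null is closed form
(p₀ = ȳ), giving the residual r = y − p₀ and weight w₀ = p₀(1 − p₀):

    u_β = s_c'r          u_τ = (r'K_c r − w₀ tr K_c) / 2.

The component variances are estimated as the sample variances of (u_β, u_τ)
across the permutation stream itself and applied identically to the observed
and every permuted statistic. Because this variance estimate is a symmetric
function of the stream, exchangeability under the null is preserved; the
calibration tests confirm nominal level. This replaces an analytic null
covariance for the binary score, which would in any case only shift the
(permutation-invariant) standardisation.

**LRT-Joint and RLRT (continuous).** The Gaussian marginal likelihood of
y ~ N(Xγ, σ²(I + λGG')) with λ = σ_b²/σ² is profiled exactly: one thin SVD
of `G` (or of the residual-projected `QG` for REML) rotates the data onto the
kernel's eigenvectors, after which γ and σ² have closed GLS forms and each
likelihood evaluation costs O(rank). λ is maximised over {0} ∪ a 81-point
log-grid on [1e−8, 1e8] followed by 36 vectorised golden-section iterations;
λ = 0 is always evaluated explicitly so boundary solutions give *exactly*
zero statistics (the RLRT's null point mass). Negative statistics from
round-off below ~1e−10 are clamped to zero and logged. The LRT-Joint
statistic is 2(ML of the joint model − ML of the intercept-only regression);
the RLRT statistic is 2(REML at λ̂ − REML at 0) in the model without the
burden term, using the (n − p)-contrast form of the restricted likelihood
(the `log|X'V⁻¹X|` term is implicit in the contrast rotation, and all
conventions cancel in the difference). Oracles: dense multivariate-normal
density agreement to 1e−8; a 2000-point grid-search REML reference to 1e−4.

**LRT-Joint and RLRT (binary).** The random effects are integrated out by a
Laplace approximation: an inner Newton ascent maximises the penalised joint
log-density over (fixed effects, b) — globally concave, step-clipped, with
converged permutation streams dropped from the batch — and the integrated
log-likelihood is the maximum plus the curvature correction
−½ log det(I + τG'WG). τ ≥ 0 is profiled over {0} ∪ a 4-point log-grid on
[1e−2, 10] with 8 golden-section refinements for streams whose grid optimum
is interior; boundary streams keep the exact τ = 0 (ordinary logistic) value.
The same procedure is applied to the observed and every permuted outcome, so
the approximation's small bias cannot distort the permutation p-value. A
41-point adaptive Gauss–Hermite quadrature oracle bounds the Laplace error
at 0.05 log-likelihood units on an m = 1 instance. (A pseudo-likelihood
REML fit, as SAS GLIMMIX defaults to, would be an alternative likelihood
definition; Laplace was chosen as the better-defined integrated likelihood,
and permutation calibration makes the choice immaterial to type I error.)

**Comparators.** Sum-Test: the squared score of the simple regression of y
on s (binary traits reuse the same centred formula since y − p₀ = y − ȳ).
SSU: U'U with U = G'ỹ, equivalent under permutation to Goeman's
variance-component score test with Σ₀ ∝ I. SKAT: Q = r'GW²G'r with
W = diag Beta(1, 25) density weights of the MAFs; its p-value is analytic —
the upper tail of Σλ_j χ²₁ with λ_j the nonzero eigenvalues of
φ̂·WG'P₀GW (P₀ the centering projection, φ̂ = σ̂² or w₀).

**Mixture tails.** The characteristic-function inversion uses the real
(Imhof) form of the Gil–Pelaez integral evaluated by a midpoint rule — the
discretisation underlying Davies' algorithm — with the step chosen so the
aliasing error (a tail probability beyond q + 2π/Δ) is ~1e−9 and the
truncation point from an explicit envelope bound at 1e−7. Single-eigenvalue
mixtures are returned as exact scaled-χ²₁ tails. If the term budget
(4·10⁶) would be exceeded (possible for two widely-unequal eigenvalues,
whose integrand decays slowly), the three-moment (Liu-style) chi-square
match is used instead; it is exact for equal eigenvalues. Eigenvalues below
1e−10 of the largest are truncated: the kernel's rank is at most m ≪ n and
round-off eigenvalues must not enter the tail.

**Permutation engine.** Outcome permutations only; stream generated by the
counter-based Philox generator, so (n, B, seed) reproduces bit-identical
p-values across platforms. Add-one p-values, ties counted as exceedances:
always in (0, 1], exactly valid under exchangeability, and within 5e−4 of
the raw proportion at B = 2000. Default B = 2000, configurable.

## Simulator

Each dataset draws per-variant target MAFs from Uniform(0.001, 0.01)
(redrawn every replicate), builds an AR(1) latent correlation ρ^|i−j|
(ρ ∈ {0, 0.5, 0.8} in the study grid), and dichotomises two independent
latent Gaussian draws per subject at the normal upper-quantile of each
target MAF; the genotype is the haplotype sum. By default all
m = n_causal + n_neutral variants share one latent vector
(`neutral_correlated=False` makes the neutral block independent).
Continuous traits add standard normal noise to `G·β`; binary traits are
Bernoulli(expit(β₀ + G·β)) with β₀ = logit(prevalence), prevalence 0.5 —
prospective sampling with a balanced null.

Effect settings on the 10 causal slots (scale c, the mean |effect|; defaults
c = 0.4 trait units for continuous, log 2 for binary):
(1) all +c; (2) alternating +c/−c — mean exactly zero, and the alternation
(rather than a half/half block) is what makes latent correlation *reduce*
power, as neighbouring opposed effects are pushed together; (3) same-signed
ramp 0.25c…1.75c; (4) the ramp with alternating signs, centred to mean
exactly zero; (5) all +c except two at −c. Neutral slots are exactly zero.

One consequence of redrawing MAFs every replicate: even with mean-zero effects,
the burden regressor picks up the realised Σ_j β_j·var(g_j), which
fluctuates around zero across replicates. Under setting 2 (equal
magnitudes) this leaves the Sum-Test at essentially the nominal level, but
under setting 4 (magnitudes up to 1.75c) it retains a small residual power
(~0.1 at n = 1000) — the burden test is still far dominated by the
variance-component tests there, which is the property the power checks
assert.

What the simulator does **not** emulate: linkage structure from real
recombination maps, allele-frequency spectra from demography (a coalescent
simulator would provide both), covariates, case-control ascertainment, and
genotyping error. Passing calibration and power checks therefore speak to
the tests' statistical behaviour under exchangeable, prospectively sampled
data — not to robustness against confounding or ascertainment.

## Study driver and problem sizes

`run_scenario` simulates R replicates, runs the requested tests on a shared
per-replicate permutation stream, and records rejections at each nominal α.
Per-replicate seeds derive from SeedSequence([master, scenario, replicate,
attempt]); degenerate draws (constant super variant, single-class binary
outcome) are redrawn with the attempt counter bumped and counted. Results
are bit-reproducible for a given master seed and independent of execution
order.

The full calibration run (`scripts/acceptance.py`) uses the study's scale:
R = 500 replicates, B = 2000 permutations, n = 1000. The test suite runs
the same checks at reduced Monte-Carlo scale — R = 200–300, B = 300–1000,
and n = 300 for the 2000-replicate p-value-distribution check — with every
tolerance recomputed as 3 binomial/Monte-Carlo standard errors at the scale
actually run; these sizes were chosen to keep the suite's total runtime
proportionate while leaving each check's standard error well below the
effects it must detect.

## Known limitations

* No covariate adjustment: models contain only the intercept and genetic
  terms (the eigen-rotation profile extends to general X, but the interface
  does not expose it).
* Integer genotypes only; no dosages, no X-chromosome/haploid handling.
* The binary RLRT is defined through the Laplace-approximate integrated
  likelihood; other GLMM likelihood definitions (quadrature, PQL) would give
  slightly different statistics, though identical permutation calibration.
* Asymptotic p-values are deliberately not offered for the boundary tests;
  permutation is the supported calibration.
* The RLRT p-value's point mass at its maximum attainable value is a feature
  of the statistic's null point mass at zero, not a defect; power is
  unaffected.
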