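# Methods

This note records the models implemented in `splicecross`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices that affect results.

## PSI and the trait filters

PSI for an event in a sample is the length-normalized inclusion fraction
`(I/L_I) / (I/L_I + E/L_E)`. A sample with `I + E = 0` carries no
information and is treated as missing, never as PSI 0. The filter chain
applied before any genetic analysis:

| filter | rule | default |
|---|---|---|
| evidence | both isoforms ≥ `min_reads` reads in ≥ `min_samples` samples | 2 reads, 2 samples |
| coverage | `I + E ≥ min_total` defines an "estimable" sample; keep events with ≥ `min_fraction` estimable | 5 reads, 50% |
| variability | on the **percent** (0–100) scale: MAD > 1, log₂ variance > 2, \|skewness\| < 1.1 | as stated |
| sex balance | each sex ≥ `min_fraction` of the estimable samples, inclusive | 20% |

Three deliberate choices, since the thresholds alone do not pin them down:

* The variability filter operates on the percent scale — on [0, 1] a mean
  absolute deviation above 1 is impossible, so the stated thresholds are
  only satisfiable on percent units.
* MAD is the mean absolute deviation about the mean; variance is the
  unbiased (n−1) sample variance; skewness is the adjusted Fisher–Pearson
  estimator. Skewness is compared two-sided (`|skew| < 1.1`), with a flag
  for the literal one-sided reading.
* "At least" is implemented as ≥ and "greater than" as >, including the
  inclusive 20% sex-balance boundary and the inclusive 50% coverage
  fraction (72 of 143 samples passes; 71 does not).

Kept traits are transformed with the rank-based inverse-normal transform
Φ⁻¹((rank − ½)/m), average ranks for ties, missing values untouched. TPM
expression flows through the same interface (quantile normalization; the
count-based filters do not apply to it).

## Genomic relationship matrix

VanRaden method 1: `G = ZZ′ / (2 Σ p_k(1−p_k))` with `Z` the dosages
centered at `2p_k`, MAF ≥ 0.01, missing dosages mean-imputed per marker.
Under Hardy–Weinberg the diagonal averages ≈ 1 (verified by simulation).
The exact construction used by any particular upstream analysis (e.g.
rrBLUP's options) is not claimed; numerical equality with other software is
not a goal, consistency of the estimator is.

## Heritability by profile REML

Model: `y = Xb + g + e`, `g ~ N(0, σ²_g G)`, `e ~ N(0, σ²_e I)`; `X` is an
intercept plus covariates (sex throughout). With `Q` an orthonormal basis
of the complement of `X` and `Q′GQ = E diag(θ) E′`, the restricted
likelihood depends on the data only through `ω = (QE)′y`, and profiling
σ²_e reduces REML to a one-dimensional problem in the ratio
λ = σ²_g/σ²_e:

```
ℓ(λ) = −½ [ (n−p)(log 2πσ̂²_e + 1) + Σ log(λθᵢ + 1) ],
σ̂²_e = (n−p)⁻¹ Σ ωᵢ²/(λθᵢ + 1)
```

maximized by Brent search on log λ over [e⁻¹⁴, e¹⁴] with an explicit λ = 0
boundary check (tolerance 1e−10 on log λ). A property test confirms the
optimum dominates a dense 200-point grid to within 1e−6 log-likelihood.
h² = λ/(1+λ). When the projected GRM spectrum is numerically constant
(G ∝ I), σ²_g and σ²_e are not separable; the fit is flagged
non-identifiable and h² reported as NaN rather than an arbitrary number.

The test of h² = 0 is the likelihood ratio against the λ = 0 fit, with the
null distribution the 50:50 mixture of a point mass at zero and χ²₁
appropriate for a variance on the boundary (statistic 0 → p = 0.5; a plain
χ²₁ option exists for sensitivity). Null calibration at n = 143 gives a
~3% rejection rate at nominal 5% — conservative, as the mixture is known
to be in finite samples.

Genetic correlation uses the bivariate animal model with 2×2 genetic and
residual covariances, rotated into the GRM eigenbasis so each eigenvalue
contributes an independent 2×2 GLS block. The covariances are log-Cholesky
parameterised and maximized by L-BFGS-B (traits standardized first; r_G is
scale-invariant); the test of σ_g12 = 0 is a χ²₁ LRT against the
constrained fit, and the SE of r_G comes from a finite-difference Hessian
and the delta method. A direct quasi-Newton on this parameterisation was
preferred over EM iteration: same estimand and likelihood, fewer moving
parts, and robust on the problem sizes involved (pairs are fitted only for
same-gene expression/splicing combinations). Fits with either genetic
variance ≈ 0 are flagged, not reported as numbers.

FDR control is Benjamini–Hochberg everywhere (via
`statsmodels.stats.multitest`, cross-checked against a hand-rolled step-up
oracle), with Benjamini–Yekutieli available by flag.

## Mixed-model QTL scan and empirical FDR

The scan is two-step: variance components estimated once per trait under
the no-marker model, then every marker tested by GLS with that covariance
fixed — the fastGWA approach. All work happens in the GRM eigenbasis, so
the rotation, rotated design and rotated genotypes are shared across
traits, markers and permutations; per-marker tests are Wald t-tests with
n − p − 1 degrees of freedom, which makes the scan *exactly* OLS when
σ̂²_g = 0 (verified to 1e−8 relative against statsmodels OLS). Monomorphic
markers yield missing p-values, flagged rather than dropped. Missing
molecular-trait values are mean-imputed (zero on the quantile-normalized
scale) so the rotation can be shared; at the coverage levels the filters
require, this touches few cells.

Empirical FDR: the sample labels of the whole trait matrix are permuted
jointly — one permutation applied to every trait, preserving the
correlation among molecular traits — while genotypes, GRM and covariates
stay tied to sample identity; with 200 permutations by default,

```
FDR(t) = mean permuted #{p ≤ t} / observed #{p ≤ t}
```

on a log-spaced threshold grid (1e−10 … 1e−2, 33 points), and the working
threshold is the largest t with FDR(t) ≤ target (0.01 for molecular QTLs,
0.05 for phenotype QTLs). This is the standard orientation of the
estimator: the permuted count estimates the expected number of false
discoveries at t. Inside permutation scans the per-trait variance ratio is
estimated on a 65-point log-λ grid (vectorized across traits) rather than
polished by Brent — the ratio enters only through GLS weights and grid
resolution is ample there; observed scans default to the exact optimizer.

Forward selection then strips linkage-driven redundancy per trait: starting
from the scan-significant candidates, repeatedly add the candidate with the
smallest conditional p (GLS model containing the already-retained markers,
same fixed variance ratio) while that p ≤ the permutation threshold
(`p_enter`; no separate entry threshold is defined, so the genome-wide one
is reused). Ties break deterministically on (p, genomic order); candidates
collinear with the retained set are skipped and logged. Retained markers
are labelled *cis* when they lie on the gene's chromosome within 1 Mb of
its boundaries — inclusive at exactly 1 Mb — and *trans* otherwise; splice
events use their parent gene's boundaries, and traits without coordinates
get a missing label.

## Mediation

For trios (marker g, molecular mediator M, phenotype Y) where the identical
marker is significant for both the phenotype and the molecular trait
(an LD-proxy relaxation is deliberately out of scope for trio construction;
linkage makes "the same signal" ambiguous in an F2, and marker identity is
the conservative rule):

* adjustment screen: p(g) from `Y ~ g + sex` versus `Y ~ g + M + sex`;
* product of coefficients: `M ~ a·g + sex`, `Y ~ c′·g + b·M + sex`;
  ACME = a·b, direct = c′, total = a·b + c′ (equal to the slope of `Y ~ g`
  exactly, for nested linear fits on complete data), proportion mediated =
  a·b/(a·b + c′), reported raw and clipped to [0, 1].

Uncertainty and the mediation p-value come from a nonparametric bootstrap
over samples (default 1,000 draws; percentile CIs; two-sided sign test on
the ACME with add-one smoothing). In this linear, no-interaction setting
the product-of-coefficients estimand coincides with the counterfactual
(quasi-Bayesian) one, which is why the simpler engine was chosen.
Significance across trios is BH at FDR 0.05 on the model-based mediation
p-value, with the adjustment-screen p-values reported alongside. Trios
with total effect ≈ 0 have an undefined proportion and are flagged;
mediators collinear with the marker make the adjusted model unidentifiable
and are flagged likewise.

## Synthetic F2 generator

What it emulates, stage by stage:

* **Founders** — two breeds diverged Balding–Nichols-style around a shared
  ancestral frequency (ancestral p ~ U(0.1, 0.9); per-breed frequency
  Beta-distributed with Var = F·p(1−p)); default F_ST = 0.3, in the range
  reported between European pig breeds. Hardy–Weinberg within breed;
  phased haplotypes retained.
* **Meiosis** — Haldane model: crossover count per chromosome
  Poisson(length in Morgans), positions uniform, no interference. The
  simplest defensible model given nothing better is specified; interference
  would slightly shrink double-crossover rates but is irrelevant at chip
  marker spacing. Constant 1 cM/Mb (configurable).
* **Pedigree** — 10 + 9 founders → 35 F1 (A×B) → 143 F2 (random distinct
  F1×F1 pairs), matching the motivating design; sexes Bernoulli(½).
* **PSI traits** — latent logit(ψ) = μ + β·g + u + e, with u drawn from
  N(0, h²·G) using the realized GRM and residual variance 1 − h², so h² is
  the logit-scale heritability of the non-QTL part and the planted QTL adds
  variance on top. Reads: total T ~ Poisson(coverage), inclusion reads
  Binomial(T, ψL_I/(ψL_I + (1−ψ)L_E)) — the length weighting is chosen
  precisely so the PSI estimator is consistent for ψ (bias < 0.005 at
  coverage 1,000). Default coverage 50 junction reads/event, a realistic
  bulk RNA-Seq junction depth; event-class frequencies follow the SE-heavy
  mix typical of muscle RNA-Seq.
* **Expression** — same linear model on log scale, exponentiated to
  TPM-like positive values.
* **Phenotypes** — y = γ·M + δ·g + sex effect + e, with γ and δ scaled
  against the *realized* mediator-on-marker slope so the expected
  proportion mediated equals the requested value exactly.

What it does **not** emulate: read-level sequencing artifacts (mapping
bias, overdispersed coverage beyond Poisson), X-linked dosage, selection or
assortative mating, shared polygenic architecture across events in the same
gene, batch effects, or the genuine LD structure of a 50K chip (marker
density after F2 linkage pruning is a free parameter here). Passing tests
therefore demonstrate correctness of the estimators and calibration of the
testing machinery under the stated generative model — not robustness to
real-data pathologies upstream of the count tables.

## Problem sizes and determinism

Default simulated scale: 2 chromosomes × 50 Mb, 2,000 markers, 500 events,
200 genes, n = 143 (or 500 for recovery checks) — sized so the full test
suite and the acceptance script each run in minutes on one core. The
permutation-FDR calibration uses 500 PSI traits (50 with planted sQTLs of
one logit unit per allele), 250 markers and 200 permutations, replicated
10×; realized FDR counts a discovery false when its trait is null or its
marker sits on a different chromosome from the planted QTL —
same-chromosome markers are genuine linkage-mediated associations in an F2
and counting them false would measure LD, not error. The end-to-end
pipeline check runs a reduced configuration (600 markers, 80 events, 30
genes, 25 permutations) twice and compares manifest checksums.

Every stochastic routine takes an explicit integer seed
(`numpy.random.default_rng`); fixed seed ⇒ byte-identical outputs,
including the VCF/TSV files and their sha256 checksums in the run manifest.
Other numerical tolerances: REML convergence 1e−10 on log λ; collinearity
cut in forward selection at residual variance ≤ 1e−10 of the column norm;
genetic-variance "zero" flags at 1e−8.
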