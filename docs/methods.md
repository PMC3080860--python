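# Methods

## Model

The package targets case-control (and, secondarily, quantitative) GWAS
in a population with recent two-way admixture.  At a candidate SNP each
individual carries `l ∈ {0,1,2}` European-derived chromosomes (diploid
local ancestry, assumed observed — inferred upstream by a local-ancestry
method that does not distort genome-wide averages), a genotype
`g ∈ {0,1,2}` counting reference alleles, and a genome-wide European
ancestry fraction `θ` (the genome average of `l/2`).

**Stratified genotype likelihood.**  Within a local-ancestry stratum,
alleles are independent draws from their background: an African-background
chromosome carries the reference allele with probability `p_A`, a
European-background one with `p_E`.  Genotype probabilities are therefore
Binomial(2, p_A) in AA, Binomial(2, p_E) in EE, and the cross product in
AE — `((1−p_A)(1−p_E), p_A(1−p_E)+p_E(1−p_A), p_A p_E)`.  This diploid AE
form means no allele-level ancestry assignment is ever required.  Cases
replace each background frequency by its odds shift
`p⁺ = Rp/(1−p+Rp)` under the allelic odds ratio `R` (ancestry-specific
`R_A`, `R_E` for the heterogeneity test).  The sufficient statistic is
the 18-cell count table over (stratum, phenotype, genotype).

**Case-only admixture likelihood.**  Under a multiplicative per-allele
ancestry risk `Ω`, a case with genome-wide ancestry `θ` carries
`N ~ Binomial(2, q)` European alleles at the locus, with
`q(Ω) = θΩ/(θΩ + 1 − θ)`; `q(1) = θ`, so the null compares the locus to
the same cases' genome-wide expectation and no control noise enters.

**Coupling.**  A single causal variant with odds ratio `R` forces the
ancestry odds ratio `Ω(R, p_A, p_E) = (1−p_E+Rp_E)/(1−p_A+Rp_A)` — the
ratio of the mean per-allele risks on the two backgrounds.  MIX maximises
the product of the two likelihoods over only `(R, p_A, p_E)`, keeping a
single degree of freedom; SUM instead adds the two separate 1-dof
statistics (2 dof); the SUM−MIX difference asks whether the admixture
signal is fully explained by the SNP odds ratio.

All likelihood-ratio statistics are referred to χ² with the degrees of
freedom given by the extra free parameters (SNP1 3 vs 2, ADM 1 vs 0,
MIX 3 vs 2, HET 4 vs 3).

## Optimisation

Maximisation is cyclic one-dimensional search over each free parameter in
turn: frequencies within [1e-4, 1−1e-4], odds ratios on the log scale
within [ln 1/100, ln 100].  These boxes keep separated tables finite
while leaving epidemiologically plausible effects interior.  Genome-wide
runs use a *vectorised* golden-section line search run in lockstep over
all SNPs (bracket shrink 0.618 per iteration, 36 iterations, sweeps until
the log-likelihood gain drops below 1e-9, converged SNPs frozen between
sweeps).  Single-instance calls go through the same engine at batch size
one; a generic scalar coordinate maximiser (bounded Brent per coordinate
with a golden-section fallback) is also provided and serves as an
independent route in the tests.  Coordinate updates are accepted only if
they improve the objective and every alternative fit starts from its null
solution, so LR statistics are non-negative by construction.  The
heterogeneity alternative decomposes exactly into two independent
2-parameter fits (control frequencies; free case frequencies), which is
how it is computed.

Dense-grid oracles with local refinement bound the cost of accepting the
first local optimum the coordinate scheme finds: across random count
tables the engine agrees with the oracles to better than 1e-3 on the
statistic (tests `test_acceptance.py::TestPropertySuites`).

**Batch admixture term.**  The Ω-likelihood needs a sum over cases of
`ln(1 + θᵢ(Ω−1))`.  For genome-wide batches the case profiles are pooled
into 128 equal-width θ-bins carrying their within-bin mean θ; matching
the first moment makes the approximation second-order accurate (worst-case
error ~1e-3 log-likelihood units at |Ω−1| ≈ 1, vanishing at the null).
Per-SNP public calls always use the exact per-case form.

## GC-calibrated scores

ADMGC replaces the binomial admixture model by an empirical one: with
`ā` the per-SNP mean case ancestry and `μ̄` its genome-wide mean,
ADMGC = ((ā − μ̄)/σ̂)².  The scale `σ̂` is estimated by *median
calibration*, `σ̂ = sqrt(median((ā−μ̄)²)/0.454936)`, not by the sample
standard deviation: the median-based estimate is robust to contamination
by true association signals (the same reason genomic control itself uses
medians), it coincides with the SD for Gaussian `ā`, and it makes the
resulting statistics have unit genomic-control λ exactly — which is what
dividing the admixture statistics by their λ_GC amounts to.  The SD
would also be subtly unsuitable here: `ā` lives on the lattice of
multiples of 1/(2·n_cases), and the median of squared z-scores built
with a plain SD inherits a seed-dependent quantization bias of a couple
of percent.  MIXGC substitutes a normal
log-density for the admixture component with mean
`m(Ω) = μ̄ + (meanᵢ qᵢ(Ω) − meanᵢ θᵢ)` — anchored so `m(1) = μ̄` — and SD
`σ̂`.  The anchored mean function was a genuinely open design point and is
isolated so it can be revisited.  These scores require a genome-wide
first pass (≥ 100 SNPs) and refuse to run without it.  When one fixed
case set is scored across the genome, ADMGC tracks ADM divided by its
genomic-control λ almost perfectly (rank correlation > 0.99 in tests);
when the case set is re-drawn per SNP — as in the calibration
simulations — case-set composition adds variance that the empirical σ̂
absorbs, so ADMGC stays calibrated (λ ≈ 1) even though the per-SNP
correspondence with ADM/λ loosens.

## Imputed SNPs

Imputation noise shrinks observed case-control frequency differences.
The adjustment attenuates the case-frequency shift linearly by the
ancestry-specific accuracy: `p⁺_obs = p + r²(p⁺ − p)` with separate `r²`
for African- and European-background segments, applied inside the SNP1
and MIX genotype likelihoods only (local ancestry is observed, not
imputed).  This linear-in-r² form reproduces the standard result that
association non-centrality scales with imputation r²; it is deliberately
isolated in one function (`attenuated_case_frequency`) so a more refined
attenuation could be swapped in without touching any score.  ATT accepts
real-valued dosages directly (the "ATT-dose" variant).

## Synthetic cohorts

The simulator generates the statistical structure the scores assume:

* **θ**: Beta distribution moment-matched to mean 0.192, SD 0.120
  (α = 1.8765, β = 7.8968 from the exact two-moment equations), clamped
  to [0.001, 0.999]; 6,209 individuals by default.  These are the
  published ancestry moments for large African-American cohorts.
* **Frequencies**: Balding–Nichols drift around an ancestral frequency
  drawn Uniform(0.1, 0.9) with F = 0.15 (typical European–West African
  differentiation), clipped to [0.01, 0.99]; or `explicit_delta`
  construction guaranteeing |p_E − p_A| ≥ Δ, used where results should
  not depend on F.
* **Local ancestry**: unlinked mode draws `N ~ Binomial(2, θ)`
  independently per SNP (correct for the per-SNP experiments, which never
  use between-SNP correlation); `markov_blocks` mode runs two haploid
  ancestry chains per individual with exponential segment lengths at rate
  G per Morgan (default G = 6, the scale of African-American admixture)
  for block-structure experiments.
* **Phenotypes**: case-control selection draws controls uniformly without
  replacement, then cases from the remainder with relative probabilities
  1 : R : R² per reference-allele count (dominant (1, R, R), recessive
  (1, 1, R), and two-locus product weights as variants), implemented by
  the exponential-sort scheme, which is exactly successive
  probability-proportional-to-weight sampling without replacement.
  Quantitative traits are `y = εg + N(0,1)`, mean-centred.
* **Imputation emulator**: within each local-ancestry stratum Gaussian
  noise is added to the true genotype and its scale calibrated by
  bisection so the *post-clipping* squared correlation with the truth
  hits the target ancestry-specific r².

What the simulator deliberately does not emulate: real allele-frequency
spectra, fine-scale LD within ancestral haplotypes, relatedness,
assortative mating, and local-ancestry inference error.  Consequently the
published *absolute* power values (which were computed on real genotypes)
are out of reach by design; what the synthetic experiments do establish
is null calibration (λ_GC of every score ≈ 1), zero power under the null
at genome-wide thresholds, the centring of HET/QHET at 1 under shared
effects, and the power *orderings* (MIX > ATT > ADM on differentiated
case-control SNPs; QATT ahead of QSUM for quantitative traits), all of
which are spectrum-independent.

## Experiment orchestration and problem sizes

`run_power_experiment` re-draws the phenotype for every SNP (cohort
generated once per run) and processes SNPs in chunks of 2,048, reducing
each SNP to its sufficient statistics before fitting all SNPs in one
vectorised pass.  Selections consume their random streams in an order
independent of R, giving common random numbers across odds-ratio values
so power is monotone in R path-by-path.  The calibration experiments use
50,000 unlinked SNPs (λ_GC of MIX/ATT/SNP1/ADMGC), 20,000 for the
null-power check, and 2,000 causal SNPs for the HET/QHET centring runs —
sizes at which the Monte-Carlo error of a median-based λ is ~0.01 and of
a mean χ² ~0.03, comfortably inside the tolerances being checked.
λ_GC uses the median-based estimator throughout (mean-based is available
but never default).

## Numerical conventions and edge cases

* p-values are upper-tail χ² probabilities, clamped at 1e-320; report
  files print six significant digits.
* The missing code is `9` in matrices and `NA` in vectors; individuals
  missing any required variable at a SNP are excluded pairwise and the
  per-SNP effective N reported.
* Monomorphic SNPs, tables missing an ancestry background (HET), empty
  strata, zero phenotypic variance, and case profiles with no
  informative θ ∈ (0,1) are flagged `MONOMORPHIC`/`DEGENERATE` rather
  than scored; non-converged fits (bounded sweeps exhausted) are flagged
  but reported.
* θ values of exactly 0 or 1 carry no admixture information; they are
  clamped to [1e-6, 1−1e-6] inside `q(Ω)` and internally inconsistent
  (θ, N) pairs (e.g. θ = 0 with N > 0) are excluded with a warning.
* Region-max windows are clipped at array edges; the centre SNP can be
  excluded to model an untyped causal variant (40- vs 41-SNP window).

## Known limitations

Three-way admixture, covariates beyond θ, mixed models, sex chromosomes,
Bayesian region scores and full integration over imputation posteriors
are out of scope.  The quantitative scores assume randomly ascertained
traits; case-control-ascertained quantitative phenotypes would need a
generalisation that does not exist here.
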