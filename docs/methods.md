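# Methods

## Historical population and genome

The burn-in phase simulates a closed, randomly mating diploid population of
constant (or scheduled) size with two distinct parents per offspring and
discrete generations.  Candidate loci are biallelic and uniformly spaced
within each chromosome; positions are in Morgans, 0-based at the chromosome
start.  Meiosis uses the Haldane mapping: the crossover count per chromosome
per gamete is Poisson with mean equal to the map length, crossover positions
are uniform, there is no interference, and chromosomes assort independently.
Mutation flips each transmitted allele independently with probability u per
locus per gamete (implemented exactly as a binomial flip count plus a uniform
random subset of cells).

Under this symmetric two-allele flip model the stationary allele-frequency
law at a locus is Beta(θ, θ) with θ = 4Nₑu, so the equilibrium expected
heterozygosity is E[2p(1−p)] = θ/(2θ+1).  This differs from the
infinite-alleles value θ/(1+θ) except for small θ; the test suite checks the
implemented model's closed form (1/3 at Nₑ = 100, u = 2.5e-3) and runs the
equilibrium property at θ = 0.2, where the two expressions agree to ~0.02.
Defaults: Nₑ = 100 for 1,000 generations, u = 2.5e-3, initial allele
frequency 0.5, then a linear expansion over 10 generations to the founder
count required by the current design.  These defaults generate LD and
polymorphism quickly at desk scale and are fully configurable.

Marker and QTL panels are drawn uniformly at random from loci whose minor
allele frequency strictly exceeds the configured minimum, QTLs first, then
markers from the remainder (roles disjoint).  Panel frequencies are recorded
from the founder generation of the current population — the generation on
which effects are assigned — which makes the effect rescaling exact there.

## Current populations

Founders are the final historical generation (generation 1, unknown parents
coded 0).  Sexes alternate with ID parity, a deterministic rule that keeps
runs reproducible from the seed alone.  Each discrete generation draws
n_sires males and n_dams females at random (no selection) from the previous
generation; under hierarchical mating dams are nested within sires in
contiguous blocks, under random mating each dam receives a uniformly drawn
sire.  Mutation is off in the current population, so offspring genotypes are
exactly Mendelian-consistent with their parents and founder frequencies used
for effect scaling are not perturbed by new mutations.

## G-by-E effects and phenotypes

Every QTL is pleiotropic for (α₀, β, α₁); effects are drawn i.i.d. from
N(0, Σ) with the configured 3×3 covariance, then each component is multiplied
by √(target / Σᵢ2pᵢqᵢmᵢ²) so the realized variance equals its target exactly
(a zero-target component is zeroed).  Cross-component covariances are
recomputed from the scaled effects as Σᵢ2pᵢqᵢmᵢnᵢ and reported — the
pre-scaling covariance settings shape the sampling distribution only.
Breeding values are dosage-weighted effect sums, mean-centered per component
within the phenotyped generation.

The per-QTL variance uses the quadratic form 2p(1−p)m².  (A linear-in-m form
would make the covariance formula Σ2pq·m·n dimensionally inconsistent; the
quadratic form is the standard single-locus additive variance.)

Residual triplets (e₀, e₁, ε) are multivariate normal with the configured
3×3 covariance; c = β-breeding-value + ε, and y follows the full or reduced
reaction norm.  The recorded c is written out and used unchanged in
estimation, keeping assigned and estimated parameters on one scale.

Default preset (all overridable): σ²α₀ = 1, σ²e₀ = 9 (h² = 0.1 at c = 0),
σ²α₁ = 0.25, σ²β = 0, σ²ε = 1, all covariances 0, reduced model.  The σ²β,
σ²ε and covariance defaults are this package's choices for a standard-normal,
genetically inert environment; the reduced generative form matches an
estimation model with a single homogeneous residual variance.

## Threshold traits

Incidences index categories from the upper liability tail; thresholds are the
single-tailed normal deviates of the cumulative incidences.  The liability is
the trait's continuous phenotype standardized by its *sample* mean and SD —
the liability-scale assumption is standard normal while simulated phenotypes
have arbitrary variance, and sample standardization keeps realized incidences
calibrated at any scale.  Boundary ties go to the lower category (a
measure-zero event, fixed for determinism).  For correlated
binary–quantitative pairs the quantitative trait is left untouched; the
default genetic correlation of the pair preset is 0.5 with h² = 0.3 for both
traits — a mid-range value typical of correlated production/health traits.

## Relationship matrices and REML

A is Henderson's tabular numerator relationship matrix; G is the
centered-dosage cross-product scaled by 2Σp(1−p) with a 1e-6 diagonal ridge,
using observed frequencies in the genotyped sample (markers drifted to
fixation are dropped).  The reaction-norm model
y = μ1 + a₀ + c∘a₁ + e, [a₀; a₁] ~ N(0, VC ⊗ K), e ~ N(0, Iσ²e₀), is fitted
by maximizing the restricted log-likelihood over a log-Cholesky
parameterization of the 2×2 VC plus log σ²e₀ (L-BFGS-B, numerical gradients,
relative tolerance 1e-8, log-scale bounds ±12 so boundary estimates can reach
~0).  The covariance structure mixes K with diag(c), which no single rotation
diagonalizes, so each likelihood evaluation builds the dense n×n covariance
and factorizes it by Cholesky — robust and fast at n ≤ ~2,000.  A
finite-difference Hessian at the optimum supplies delta-method standard
errors and flags non-identifiable fits (condition number > 1e8), e.g. K = I
with c ≡ 0 where Var(a₀) and Var(e₀) are confounded.  Fixed effects default
to an intercept; a design-matrix hook accepts more.

## Validation experiments and problem sizes

The package validates itself at desk scale:

- **Incidence recovery**: 20 replicates × 10,000 phenotyped individuals for a
  binary trait (π = 0.3), a three-category trait (π = 0.3, 0.4) and a
  binary–quantitative pair.  The incidence-experiment genome (3 chromosomes ×
  200 candidate loci, 100 QTLs) is deliberately small: with sample-standardized
  liabilities the realized incidence is insensitive to genome size.
- **Parameter recovery**: 5 replicates × 1,000 genotyped individuals
  (10 chromosomes × 500 candidate loci, 2,000 markers, 300 QTLs, one
  generation of 10 sires × 100 dams × 10 offspring) fitted with the G matrix;
  the A matrix is fitted on the same data for the G-versus-A error
  comparison.  At this scale the restricted likelihood is flat in Var(a₁)
  (per-replicate SE ≈ 0.2), so individual estimates scatter widely while the
  across-replicate mean is unbiased; summaries are therefore reported with
  across-replicate SDs and compared at that resolution.
- **Realized covariance**: 20 effect-sampling replicates on one simulated
  genome; with zero assigned covariance the realized Σ2pq·m·n has mean 0 and
  SD ≈ 0.03 at 300 QTLs.

## What the generator does and does not emulate

Simulated data have discrete generations, random mating, no selection, no
migration, biallelic loci with recurrent mutation, cross-sectional records
(one environment value per individual) and fully pleiotropic QTLs.  Real
livestock data add selection, overlapping generations, repeated records,
non-normal environments and partial pleiotropy; passing tests here show the
generator and estimator are internally consistent, not that any particular
field data satisfy the model.  Dominance, epistasis and longitudinal
trajectories are out of scope.

## Numerical choices

- PSD validation tolerance 1e-10 relative; effect sampling uses the SVD-based
  multivariate normal so exactly singular covariances are legal.
- Rescaling raises an error if a component's pre-scaling realized variance is
  zero while its target is positive.
- Crossover parity is computed by scatter + xor-accumulate over loci; a
  crossover landing exactly on a locus position switches at that locus
  (measure-zero tie).
- REML returns `converged=False` rather than raising on optimizer failure;
  the restricted log-likelihood at the estimates is asserted (in tests) to
  dominate the likelihood at the generating truth.
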