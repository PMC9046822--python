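# Methods

`salmogs` models a family-based Atlantic salmon breeding program that moved
from pedigree BLUP to single-step genomic BLUP (ssGBLUP), and provides every
computational stage of that scheme: population simulation, genotype QC and
parentage, relationship matrices, mixed-model evaluation, two-tier SNP panel
design, low-to-high-density imputation, the selection index, and the
validation framework that compares at-spawning breeding values with
progeny-updated ones.  This note records the models, the defaults, and the
choices made where the design was genuinely open.

## The breeding program being emulated

The simulated program mirrors a commercial nucleus: roughly 200 full-sib
families per year class produced by a partial factorial in which every sire
and every dam is crossed exactly twice; families pooled at the eyed-egg
stage (~250 eggs per family, ~50,000 in total); ~8,000 presmolt sampled at
random from the pool, tagged and genotyped; about two-thirds of them
sea-transferred for sib testing (harvest weight, disease scores, maturation,
carcass quality) while the rest remain in freshwater as broodstock
candidates.  Marine fish never return to the hatchery, so selection
candidates carry no marine phenotypes: the marine information reaches them
through sibs.  Year classes are linked by repeat spawners (~15% of
broodstock) and overlapping generations; males are usable from age 2,
females from age 3, both up to age 6.  These numbers are the
`SimulationConfig` defaults.

Two facts drive the genomic design and are reproduced by the generator:

* **Within-family variation.** Full sibs share expected relationship 0.5 but
  realised genomic relationships spread around it.  Pedigree BLUP assigns
  unphenotyped full sibs identical EBV; genomic BLUP does not.  Tests assert
  both halves of this statement directly.
* **Long-range LD.** Founder linkage disequilibrium is calibrated so that
  mean r² ≈ 0.2 at 500 kbp, the regime in which a ~3K tag panel imputes well
  to a ~45K standard set.

## Founder haplotypes and LD calibration

Founder haplotypes come from a first-order Markov walk along each
chromosome: a latent Gaussian AR(1) chain with persistence exp(−d/L) in
physical distance d, thresholded at each locus at the allele-frequency
quantile (frequencies drawn from a U-shaped Beta(½, ½) truncated at
MAF 0.02).  Thresholding attenuates the latent correlation by an amount that
depends on the two allele frequencies, so L is calibrated numerically:
bivariate-normal orthant probabilities are integrated over random frequency
pairs from the founder spectrum and the root of
mean r²(latent ρ) = ld_target is found by Brent's method, after which
L = −d₀/log ρ.  On a 2-chromosome, 5,000-marker, 400-founder genome this
lands mean r² at 450–550 kbp near 0.20 (acceptance suite asserts the
[0.15, 0.25] band).  The latent-chain construction was chosen over literal
allele copying because a copy-or-redraw chain either smooths the allele
frequency spectrum toward 0.5 (copying from the previous locus) or cannot
preserve marginal frequencies when adjacent frequencies differ; and over
coalescent simulation because a single published LD statistic is the only
calibration target.

Meiosis uses Haldane's model: Poisson crossover counts per chromosome at
1 cM/Mbp (configurable), uniform crossover positions, no interference.

## Trait model and phenotypes

Traits carry a joint structure (G_p additive across traits, G_n full-sib
common-environment, R residual) with phenotypic variances normalised to 1,
so diag(G_p) are the heritabilities.  The program trait set uses the routine
evaluation's published h²: acquired AGD (amoebic gill disease) resistance
0.36, harvest weight 0.44, innate AGD resistance 0.16, maturation 0.20,
flesh colour 0.65, flesh fat 0.28, with freshwater expressions of weight and
maturation genetically correlated with their marine counterparts at 0.63 and
0.76 and AGD resistance uncorrelated with the freshwater traits.
Correlations the routine evaluation does not report are set to zero, the
common-environment fraction defaults to c² = 0.10 per trait (a typical
full-sib tank effect magnitude), and the residual covariance between
environments is zero (no individual is measured in both).

QTL effects are drawn multivariate normal across traits at 10% of loci and
then linearly transformed so the empirical founder true-breeding-value
covariance equals G_p exactly — an infinitesimal-like architecture, which is
appropriate because the GWAS screen of the real data found no large-effect
QTL.  Phenotype = trait-by-cohort effect + true BV + family deviate (shared
by full sibs, drawn from G_n) + residual (drawn from R), with each trait
expressed only in its environment.

## Relationship matrices

* **A** — tabular method with inbreeding (a_ii = 1 + F_i,
  F_i = a_{sire,dam}/2); its sparse inverse uses Henderson's rules with
  Mendelian-sampling variances from Meuwissen–Luo inbreeding coefficients.
  Both are checked entrywise against an independent recursive oracle.
* **G** — VanRaden method 1, (M−2P)(M−2P)ᵀ / 2Σp(1−p), with observed allele
  frequencies in the genotyped set (the convention of the standard ssGBLUP
  software stack).  Monomorphic markers are a hard error; QC removes them.
* **G\*** — G rescaled by the two-statistic fit α + βG matching mean
  diagonal and mean off-diagonal of A22, then blended
  G\* = (1−τ)G_scaled + τA22 with τ = 0.05.  The blend bounds the smallest
  eigenvalue below by τ·λ_min(A22), guaranteeing invertibility.  τ is a
  conventional default; the source program reports using a blending factor
  without stating its value.
* **H** — standard single-step augmentation.  Production code uses
  H⁻¹ = A⁻¹ + [0 0; 0 G\*⁻¹ − A22⁻¹]; a second, independent route builds H
  directly from the joint-distribution formula
  (H11 = A11 + A12A22⁻¹(G\*−A22)A22⁻¹A21 …) and the two agree to 1e−8 in
  tests.  With no genotyped animals H = A exactly, and with G\* = A22 the
  GEBV collapse to the EBV — the comparability property that lets gains be
  tracked across the pedigree-to-genomic transition.

## Mixed-model equations

The evaluation model is y = Xτ + Z_n u_n + Z_g u_g + e with trait-by-cohort
fixed effects, trait-by-family random effects u_n ~ N(0, I⊗G_n) (common
environment plus non-additive genetic effects), and trait-by-animal additive
effects u_g ~ N(0, K⊗G_p) with K = A (EBV) or K = H (GEBV).  Residuals
covary across traits within an individual via R; repeated records of one
trait are residual-independent.  Effects are ordered animal-major so the
additive prior precision is K⁻¹⊗G_p⁻¹.  Variance components are inputs
(REML is out of scope; the real program estimates them with dedicated REML
software), which keeps every solver claim checkable against closed forms.

Solving: direct sparse LU, switching to dense Cholesky when the coefficient
matrix density exceeds 2% (the genotyped block of H⁻¹ is dense, and sparse
LU fill-in is slower than BLAS there), or Jacobi-preconditioned conjugate
gradients; both routes agree to 1e−6 on all tests.  Standard errors are
sqrt of the animal-block diagonal of C⁻¹; when only a subset of animals
needs SEs (validation uses the ~100 parents), the columns are obtained by
unit-vector solves against one factorization.  Maturation is analysed on the
observed 0/1 scale with the linear model, matching the production models.
The GWAS screen is single-marker OLS with cohort residualisation and a
Bonferroni threshold — a screen for large-effect QTL, not a discovery
engine, and deliberately without kinship correction by default.

## Panel design

The high-density (50K-class) design: greedy left-to-right LD pruning at
r² < 0.2 per chromosome yields a scaffold tagging distinct chromosome
segments; scaffold plus trait-associated markers are force-included; all
remaining markers fall into 100 kbp half-open bins (bin k covers
[k·10⁵+1, (k+1)·10⁵] in 1-based coordinates) and filler slots are awarded by
the deterministic score rank(MAF) − rank(local mean r²), one marker to every
uncovered occupied bin before any bin receives a second.  The published
design describes the inputs to its optimisation (location, MAF, LD) but not
the algorithm; the rank-sum rule is this package's reproducible realisation
and is documented so alternates can be plugged in.  The low-density (1K/3K)
panels take the best-scored high-density marker per equal-length genome
window, forcing trait markers in.  Panel summaries (mean spacing, largest
gap, mean MAF, bin coverage) are recomputed brute-force in tests.

## Imputation

A deliberately transparent two-stage scheme stands in for black-box
imputation software (the production pipeline used an external family +
population imputation binary whose algorithm is not restated in the source):

1. **Family stage** — Mendelian fixed-point: fill a missing genotype only
   when parental dosages force it (0×0→0, 2×2→2, 0×2→1), iterating so fills
   cascade through generations; observed calls are never modified.
2. **Population stage** — sliding windows of 20 consecutive standard-set
   markers; per target and window, reference individuals (fully genotyped at
   the standard set) are ranked by mean absolute dosage difference on the
   target's observed markers and missing entries take the modal dosage of
   the 5 nearest references; windows with no observed marker fall back to
   the reference modal genotype.

Accuracy is genotype-wise (proportion of masked, originally non-missing
genotypes imputed identically), the stricter of the two possible readings.
Window/neighbour counts are config; the sensitivity sweep in
`analysis/03_impute_validate.py` shows the scaled 3K-class accuracy rising
from ~0.79 (window 20) to ~0.81 (window 50–100) because a sparse panel
leaves ~1 observed marker per 20-marker window.  Masking-based validation
predicts a held-out cohort from earlier cohorts (targets and reference
disjoint), optionally carrying the completed genotypes through a GEBV run to
report Spearman concordance between breeding values from imputed and
original genotypes — which exceeds the raw genotype accuracy, as genotype
errors average out in G.

## Selection, gain, validation

Breeding values are standardised to genetic-SD units; the index applies the
program's selection pressures (acquired AGD 38%, harvest weight 25%, innate
AGD 13%, maturation 13%, colour 13%, fat 0%), normalised internally.
Acquired-resistance breeding values are a weighted linear combination of the
post-naive disease-score BVs (equal weights by default; the production
weighting is not published).  Parent selection is truncation on the index
within sex with an optional max-per-full-sib-family cap and id tie-breaks.
Gain is reported in genetic-SD units in simulation (a founder phenotypic
baseline would be arbitrary); cumulative gain is the difference of year-class
means and annual gain the least-squares slope.

Validation follows the program's own scheme: the at-spawning EBV and GEBV of
the parents of a year class are rank-correlated (Spearman) with the updated
breeding value once progeny information exists, taking per animal the
updated run with the lowest standard error as the best estimate of the true
breeding value (GEBV preferred on ties, matching practice), and reporting
Δ = r(T̂,G) − r(T̂,E) per trait and for the index, the index being
recomputed from the updated breeding values.

## The breeding-cycle loop and scheme comparison

`simulate_breeding_cycle` runs year classes in sequence: select parents
(random until phenotypes exist, then index truncation on EBV or GEBV),
reserve the configured repeat-spawner fraction for previous parents, mate
the partial factorial, sample candidates from the pooled progeny
(multivariate-hypergeometric family counts — exactly simple random sampling
of the pool), allocate marine vs freshwater, phenotype, genotype (genomic
scheme), and record the true genetic mean.  Phenotypes of a year class are
available only to spawnings in later years, so a candidate's marine sibs are
always in the training data while the candidate itself is unphenotyped for
marine traits.  Evaluations at a spawning year are restricted to animals
that exist before that year, so at-spawning and updated runs differ exactly
by the progeny information.  All randomness flows through stage- and
year-scoped substreams of one seed (SHA-256-keyed `SeedSequence` spawns), so
identical configurations reproduce byte-identical outputs end to end.

`compare_schemes` runs genomic and pedigree-only programs as paired
replicates from identical founders and reports cumulative true-index gains,
the paired one-sided test, and a bootstrap CI for the ratio of mean gains.
With selection disabled the two schemes coincide by construction (selection
is the only stage that consumes evaluations), so the null gain ratio is
exactly 1.

## Problem sizes for tests and the acceptance script

Simulation experiments run at desk scale, chosen once: calibration runs at
2 chromosomes × 50 Mbp, 5,000 markers, 400 founders; imputation studies mask
5,000 markers down to 300 (3K-class) and 100 (1K-class) with a
parent-plus-sib reference; replicate accuracy studies use 60 families/year ×
20 pooled offspring with 600 candidates sampled per year over 3 year classes
(20 replicates); scheme comparisons use 24 families/year × 8 sampled
offspring.  Scaled cycle experiments run discrete generations (minimum
parent ages set to 1 in their configs); the age-structure logic itself is
exercised separately.  The directional claims (GEBV > EBV accuracy for
unphenotyped candidates, Δ_index > 0, genomic > pedigree gain, 3K > 1K >
frequency-baseline imputation) are scale-free; the magnitudes are not — in
particular the scaled imputation accuracies (~0.77–0.81) sit well below what
a 45K panel with a multi-thousand reference achieves, because the scaled
panel leaves far fewer observed markers per window.

## What the synthetic data do not capture

No genotyping batch effects or assay failure modes beyond uniform missing
and mistype rates; no selective genotyping; binary maturation simulated as
Gaussian rather than thresholded liability; no inbreeding avoidance in mate
allocation (the partial factorial is random within the selected set); no
genotype-by-environment interaction beyond the fixed fresh/marine genetic
correlations; a two-chromosome genome rather than 29.  Passing tests
therefore demonstrate the correctness and internal consistency of the
machinery and the direction of the genomic advantage under the stated
population structure — not field-scale accuracy magnitudes.
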