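# Methods

`panelgp` evaluates how far SNP genotyping density can be reduced before
genomic prediction of breeding values degrades, in the setting where that
question matters most economically: family-based aquaculture breeding
programs that phenotype full siblings of the selection candidates
(sib-testing). The package implements the whole evaluation pipeline —
quality control, low-density panel construction, genomic relationship
matrices, REML/GBLUP, replicated cross-validation — together with a
synthetic-data generator that emulates four published aquaculture datasets
(Atlantic salmon, common carp, gilthead sea bream, Pacific oyster) so every
stage is testable against known ground truth.

## The model

The animal model is

    y = mu + X b + Z a + e,   a ~ N(0, G sigma_a^2),   e ~ N(0, I sigma_e^2)

with `y` the phenotypes, `b` categorical fixed effects (reference-level
coded, intercept = mu), and `G` the frequency-weighted identity-by-state
genomic relationship matrix

    G_ij = (1/L) sum_l (x_il - 2 p_l)(x_jl - 2 p_l) / (2 p_l (1 - p_l)),

i.e. twice the Astle–Balding realized kinship, so E[G_ii] ~ 1 under
Hardy–Weinberg and full-sib off-diagonals sit near 0.5. Note that one
uniform cross-product formula is used for diagonal and off-diagonal entries
(VanRaden-style standardization); the GenABEL `gkin` convention of a
`0.5 (1 + f)` diagonal differs slightly on the diagonal but has the same
off-diagonal expectation — the uniform form is used because it yields a
self-consistent positive-semidefinite matrix. Allele frequencies are always
estimated in-sample, and re-estimated on each SNP panel's markers, because
no external reference panels exist for these populations. Missing dosages
are mean-imputed to `2p` by default (PSD-safe); a pairwise-complete policy
is available behind a flag. An explicit inverse of G (with an escalating,
recorded diagonal ridge when numerically singular) is provided for
mixed-model-equation solvers, though the default GBLUP path works with G
directly.

## REML and GBLUP

Variance components are estimated by restricted maximum likelihood on a
one-dimensional profile: writing V = sigma_T^2 [h2 G + (1 - h2) I] with
sigma_T^2 = sigma_a^2 + sigma_e^2, the total variance is profiled out
analytically and the restricted likelihood becomes a function of h2 alone.
Evaluated in the eigenbasis of G (one O(n^3) decomposition, O(n) per
likelihood evaluation), it is maximized by bounded scalar optimization on
h2 in [1e-6, 1 - 1e-6] with tolerance 1e-8. This is exact for the
single-random-effect model and finds the same optimum an AI-REML solver
would, with none of its step-size fragility. The standard error of h2 is
the inverse square root of the negative numerical curvature of the profile
at the optimum (central differences, step 1e-4); estimates within 1e-5 of a
bound are flagged as boundary solutions. G proportional to the identity is
rejected up front: sigma_a and sigma_e are then not separately
identifiable.

Breeding values for all individuals — phenotyped or not — come from the
conditional expectation

    a_hat = sigma_a^2 G[:, obs] V_oo^{-1} (y - X b_hat),

with `b_hat` the GLS estimate on the observed block. The equivalent
mixed-model-equations formulation (using G^{-1}) is also implemented and
the two are held to 1e-8 agreement in the tests. Individuals missing the
trait or a factor level are excluded from y/X but retained in G, which is
what lets information flow to unphenotyped sibs.

## Quality control

Four sequential filters in PLINK 1.9's fixed internal order: individuals
with > 20% missing genotypes; then, on the surviving individuals, SNPs with
> 10% missingness, SNPs failing the exact Hardy–Weinberg test at p < 1e-6,
and SNPs with minor allele frequency < 0.05. SNP statistics are recomputed
after individual removal; each excluded SNP is attributed to the first
filter it fails. The HWE test is the standard exact conditional test on the
heterozygote count (no mid-p), computed in log space and verified against
exact-rational enumeration. HWE is computed on the whole sample: in
family-structured data this inflates rejections somewhat (visible in the
simulated oyster preset, whose 23 large families lose a few percent of
markers), which mirrors how the filter behaves when applied naively to
sib-structured datasets.

## Panel design

Densities follow a fixed grid (100–5,000, plus 6,000/7,000/9,000 where
enough QC-passing SNPs remain; infeasible densities are dropped per
dataset). Two selection strategies: uniform sampling across the genome
(default and headline), and within-chromosome sampling with counts
proportional to chromosome length via largest-remainder rounding (ties
broken by descending length then label). Chromosome "length" is the span of
QC-passing marker positions, so RAD-style maps need no external assembly.
Each panel's seed derives from (master seed, strategy, density, replicate)
through a counter-based scheme, so extending the grid or adding replicates
never perturbs existing panels.

## Cross-validation

Phenotyped individuals are partitioned into 5 near-equal random folds
(unstratified — no family balancing), replicated with independent seeds.
Per fold, validation phenotypes are masked, variance components are
re-estimated on the training records (a flag allows fixing them from the
full fit; measured effect on accuracy is negligible), and GBLUP predicts
validation breeding values through G, which always contains all
individuals. Accuracy is r(EBV, phenotype) on the validation set divided by
sqrt(h2_ref), where h2_ref is the full-data, full-panel REML heritability —
the same denominator for every density, since sparse-panel heritabilities
are themselves biased down. Raw phenotypes (not pre-corrected for fixed
effects) enter the correlation; fixed effects are handled inside the model.
This estimator can exceed 1. Per density, the headline aggregates are the
pooled mean accuracy, the SD and max-minus-min range across per-panel mean
accuracies, and the proportion of the full-panel mean accuracy. A local
quadratic loess smoother (tricube weights, span 0.75) is provided for
report plots only; no numeric output depends on it.

## Synthetic data

The generator emulates the structure of the four reference datasets:

| preset   | families | individuals | SNPs   | h2   | trait scale         | fixed effects      |
|----------|---------:|------------:|-------:|-----:|---------------------|--------------------|
| salmon   |       85 |       1,481 |  9,866 | 0.24 | 31.36 ± 3.24        | tank (2 levels)    |
| carp     |      195 |       1,211 |  6,966 | 0.27 | 77.01 ± 7.11, log   | cross group (4)    |
| seabream |       73 |         741 |  7,598 | 0.20 | 10.40 ± 4.08        | none               |
| oyster   |       23 |         718 | 14,028 | 0.49 | 6.76 ± 1.91, days 1–8 | tank (2 levels)  |

Founders are unrelated, in linkage equilibrium, with per-SNP allele
frequencies uniform on [0.05, 0.5]; they form monogamous pairs, one
full-sib family each, with near-equal family sizes (total split evenly,
remainder spread). Offspring genomes are gene-dropped: per chromosome the
crossover count is Poisson with mean equal to the genetic length in Morgans
(Haldane, no interference; 1 cM/Mb default), crossover positions uniform,
chromosomes segregating independently. Within-family linkage
disequilibrium — the long shared haplotypes that make sparse panels work in
sib-testing designs — therefore arises from co-segregation, not from the
founder haplotypes.

Traits are additive: 500 causal markers by default ("most polygenic
traits"), standard-normal effects, breeding values rescaled so realized
Var(TBV)/Var(TBV + e) equals the target h2 on the phenotypic scale.
Fixed-effect levels are assigned uniformly at random with modest effects
(0.3 phenotypic SD per level step — the reference studies do not report
magnitudes). The optional log transform and day-censoring are applied last;
days-to-death is produced by monotone rounding of the continuous liability
to integers clipped at the censor day (survivors = censor day), since only
trait means and SDs, not the survival mechanism, are known. Day-censoring
costs signal: the oyster preset's full-panel REML estimate averages ~0.40
against a true 0.49, an attenuation the tests budget for.

What the generator does **not** emulate: population-level LD among
founders, factorial/half-sib mating networks, multi-generation pedigrees,
genotyping error and missingness patterns, non-additive variance. The main
visible consequence (measured, not hypothesized): at very low densities the
simulated datasets lose *more* accuracy than the real ones, because
aggregate GRM sampling noise across many small independent families is not
offset by population LD. The effect is strongest for the carp-like preset
(195 families of ~6). Cross-dataset mean proportions of full-panel accuracy
land near 0.95 (2,000 SNPs), 0.87 (1,000), 0.80 (500) and 0.50–0.58 (100),
versus 0.97 / 0.93 / 0.89 / 0.70 reported for the real datasets — the
2,000-SNP plateau and the steep sub-1,000 decline reproduce; the 100-SNP
floor is lower than in real data. Passing tests therefore demonstrate
correct machinery and the qualitative density trend, not that real
populations would lose this much accuracy at 100 SNPs.

## Problem sizes and numerical choices

The bundled study runs the four presets at full Table-scale sample and
marker counts but with reduced replication — 3 random genome-wide panels
per density at {100, 500, 1,000, 2,000} plus the full panel, 2 replicates
of 5-fold CV, and 5 replicate 200-SNP panels for the heritability-shrinkage
summary — which keeps a complete run around two minutes per seed on one
core while leaving per-density means stable to a few hundredths. Unit tests
use smaller simulations (e.g. 120 families x 8 offspring, 1,500 SNPs).
Degenerate inputs are rejected loudly rather than coerced: empty QC output,
all-missing markers, non-symmetric or identity-proportional G, constant
validation vectors, rank-deficient fixed-effect designs (a factor level
falling entirely into one validation fold skips that fold). Ties in
largest-remainder allocation and in minor-allele polarity are broken
deterministically (documented in the respective modules); all randomness
flows from explicit seeds through counter-based derivation, so every result
is a pure function of (config, seed).
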