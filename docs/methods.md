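# Methods

## Scope and model overview

`hapgs` analyses a pedigreed breeding population genotyped with a
biallelic SNP array and phenotyped in a randomized complete block design
(RCBD) with single-tree plots. Two classes of model are fitted by Gibbs
sampling and compared on heritability, genetic gain and cross-validated
predictive ability:

* the **animal model** y = Xβ + Za + ε, a ~ N(0, Aσ²ₐ), ε ~ N(0, Iσ²ₑ),
  where X carries design-block effects and A is the additive (numerator)
  relationship matrix from the pedigree;
* the **whole-genome regressions** y = Xβ + Zm + ε, where Z holds marker
  or haplotype regressors coded 0/1/2 and the models of the Bayesian
  alphabet differ only in the prior on m (details below).

Marker sets come in three flavours: all SNPs (SNP), haplotype-variant
copy counts for the blocks found by the Gabriel confidence-interval
algorithm (HAP), and haplotype variants plus the SNPs not assigned to any
block (HAP-SNP).

## Linkage disequilibrium

Genotypes are unphased, so two-locus haplotype frequencies are estimated
by EM on the 3×3 genotype table; only the double-heterozygote class is
phase-ambiguous and is split between the coupling and repulsion phases in
proportion to their current frequency products. The EM is initialised at
linkage equilibrium, which makes the all-double-heterozygote sample (whose
likelihood is symmetric in the phase) a documented D = 0 fixed point.
Convergence is declared when no haplotype frequency moves by more than
1e-10 (at most 2000 iterations).

From the fitted table, D = p₁₁p₂₂ − p₁₂p₂₁. D_max is
min{p_A1 p_B1, p_A2 p_B2} for D < 0 and min{p_A1 p_B2, p_A2 p_B1}
otherwise (stored as the positive magnitude), so D′ = |D|/D_max ∈ [0,1];
r² = D²/(p_A1 p_A2 p_B1 p_B2). Monomorphic loci raise an undefined-LD
error rather than returning 0.

**D′ confidence bounds.** The multinomial likelihood of the genotype table
is profiled over a D′ grid (step 0.01) with allele frequencies plugged in
at their MLEs and D carrying the sign of the EM estimate. Treating the
normalised likelihood as a unit mass, the lower bound is the smallest grid
value with cumulative mass ≥ 0.05 and the upper bound the smallest with
cumulative mass ≥ 0.95 — the one-sided support-interval scheme used by
Haploview's implementation of the Gabriel algorithm.

**Gabriel blocks.** A pair is *strong LD* when CI_high ≥ 0.98 and
CI_low ≥ 0.70, *strong recombination* when CI_high < 0.90, and
*informative* if either; pairs with fewer than 20 genotyped individuals
are uninformative. A candidate block [i..j] needs a strong-LD endpoint
pair, ≥ 95% strong-LD among its informative pairs, and a span of at most
500 kbp (large enough to admit the longest blocks seen in dense-array
tree data). The final set is greedy: longest span first, leftmost on
ties, no overlap. The 0.98/0.70 bounds, the 0.90 recombination bound and
the 95% fraction are all configurable.

**LD extent.** The critical r² is the squared empirical 95th percentile of
√r² over unlinked (inter-chromosomal) pairs — all of them, or a seeded
subsample of 10,000 when more exist. The decay profile bins
intra-chromosomal pairs by distance; the crossing distance is the midpoint
of the first bin whose 3-bin moving-average mean r² falls below the
critical value, reported as absent when no bin crosses.

## Haplotype encoding

Each block (2–12 SNPs in the target populations; hard cap 15) is phased by
an EM over all haplotypes compatible with the observed genotypes; missing
sites are marginalised. Individuals receive their maximum-posterior
diplotype, with ties broken toward the lexicographically smallest variant
pair so output is deterministic. Copy coding follows the field
convention: per variant, 0 = no copy, 1 = one copy, 2 = two copies, and a
block's retained-variant codes sum to 2 per individual with complete data.

Variants with EM frequency below 0.01 are dropped from design matrices
(display convention of the standard block software; configurable).
Filtered variants simply leave rows summing below 2 — no catch-all
column. SNP columns are oriented so 2 is the common-allele homozygote.
Missing values are mean-imputed per column. Every column records
pᵢ = column mean / 2; for multi-variant haplotype columns this treats each
variant as a biallelic presence dosage, the only reading under which the
2pᵢ(1−pᵢ) genomic-variance weight applies.

## Pedigree machinery

A is built by the tabular method; A⁻¹ directly by Henderson's rules with
inbreeding coefficients taken from the tabular diagonal. Unknown parents
(open-pollinated, half-sib families) contribute founder-type terms. For
the sampler the model is rotated through the one-off eigendecomposition
A = UDU′: with a = UD^{1/2}α the transformed effects are iid
N(0, σ²ₐ), so α updates use the same single-site normal sweep as the
ridge regression and no per-iteration factorisation is needed.

## Priors and samplers

All variance parameters get scaled-inverse-χ² priors with 5 degrees of
freedom. Scales are set from the data: the residual prior mode at
(1−R²)·Var(y) and the marker-variance prior mode at R²·Var(y)/Σⱼ Var(zⱼ)
with R² = 0.5 — the usual whole-genome-regression convention of
apportioning half the phenotypic variance to the markers a priori. The
animal model uses prior modes at half the phenotypic variance for both
variances. Fixed (block) effects have flat priors.

Per model:

* **BRR** — mᵢ ~ N(0, σ²_m), common variance.
* **Bayes A** — mᵢ ~ N(0, σ²_mᵢ), per-marker scaled-inverse-χ² variances
  (marginally scaled-t).
* **Bayes B** — mᵢ = 0 with probability π, else N(0, σ²_mᵢ); the
  indicator and effect are updated jointly from the marginal likelihood
  ratio; the slab scale is divided by (1−π₀) so the prior genomic variance
  is unchanged by the mixture.
* **Bayes Cπ** — as Bayes B with one common slab variance; π gets a
  Beta(1,1) prior and is sampled from its Beta full conditional (it can be
  fixed instead).
* **Bayesian LASSO** — Park–Casella scale mixture:
  mᵢ | τᵢ², σ²ₑ ~ N(0, τᵢ²σ²ₑ), τᵢ² ~ Exp(rate λ²/2),
  λ² ~ Gamma(φ₁, φ₂) with φ₁ = 1.1 and φ₂ matching the prior mean of λ²
  to 2(1−R²)/R² · Σⱼ Var(zⱼ). The plain Exp(λ²) rate convention is
  selectable, since both parameterisations circulate.

The per-column sweeps are numba-compiled, but every random variate is
drawn from a single seeded numpy Generator outside the kernels, so chains
are bit-identical for a given seed. Default desk-scale MCMC is
20,000 iterations / 2,000 burn-in / thin 10; heavier settings (e.g.
10⁶/10⁵/50) are plain configuration. Tests and the acceptance script use
3,000–8,000 iterations, sizes at which the parameter-recovery and oracle
checks are already stable. A split-chain R̂ on h² is reported and a
warning is raised above 1.2.

Ordinal traits are fitted on their observed scores as Gaussian; a
threshold (probit) treatment is a possible extension, not implemented.

## Genomic parameters

Per retained draw: σ²_g = 2σ²_m Σᵢ pᵢ(1−pᵢ) for BRR/BC (the common
variance spread over observed heterozygosity); 2Σᵢ pᵢ(1−pᵢ)σ²_mᵢ for
BA/BB, with excluded BB markers contributing zero; and
2Σᵢ τᵢ²σ²ₑ pᵢ(1−pᵢ) for BL. Genomic heritability uses the same ratio
form as the pedigree model, h²_g = σ²_g/(σ²_g+σ²ₑ), evaluated per draw
and summarised by the posterior mean and central 90% credible region.
Genetic gain is GG = (ȳ_sel − ȳ_pop)/ȳ_phe × 100 with
n_sel = round(fraction × n); for ordinal traits ȳ_phe defaults to the
arithmetic mean of the observed scores.

## Evaluation

Cross-validation holds out a random 10% per cycle, refits, and predicts
held-out GEBVs as Z_val·m̂. Two reference vectors are supported for the
predictive-ability correlation: the whole-data-fit GEBVs (the literal
historical definition) and phenotypes adjusted for fixed effects. The
whole-data reference shares training data with every fold and is strongly
optimistic — it measures agreement between two fits, not out-of-sample
accuracy — so the pipeline and the calibration checks default to the
adjusted-phenotype reference; the literal mode remains available. Cycle
splits and sampler seeds derive from (seed, cycle), so any cycle is
reproducible in isolation; zero-variance folds are skipped and logged.

Tukey–Kramer comparisons use studentized-range critical values on the
pooled within-group variance with the unequal-n standard error; the
compact letter display is assigned greedily from the best mean. Raw
per-cycle correlations are compared by default (a Fisher-z transform
would be a caller-side preprocessing step). Significance against the
pedigree estimate is flagged when the two 90% credible intervals do not
overlap; an interval-excludes-midpoint rule is selectable.

## Synthetic data

The generator emulates a progeny-trial design: ~65 families of ~10 trees
from a mix of full-sib and open-pollinated (half-sib, sire unknown)
matings; 11 chromosomes; 30 design blocks with single-tree plots; five
traits at heritabilities 0.04–0.46, two of them ordinal (7- and 6-level
scales produced by thresholding the latent value at equal-probability
empirical quantiles). Founder LD is a set of planted segments whose
haplotypes are drawn jointly from a small variant pool (default: two
complementary variants, giving within-segment D′ = r² = 1 among
founders); markers outside segments are independent with frequencies in
[0.05, 0.95]. Gametes recombine as a Poisson process at 10⁻⁸ crossovers
per bp without interference. Unknown sires are drawn fresh from the
founder distribution per offspring (open pollination). Phenotypes are
additive: block effect + Σ QTL dosage×effect + Gaussian residual, with
the residual variance solved from the realized breeding-value variance so
the target h² holds exactly in expectation; requesting h² = 0 or 1 is an
error. One master seed feeds per-stage substreams; identical seeds give
bit-identical output.

What the simulation does *not* model: coalescent/demographic realism,
LD decay by mutation-drift (a copying option is not implemented — planted
segments are block-shaped by design), genotyping error, selection over
generations, dominance or epistasis, and spatial field trends. Passing
tests therefore demonstrate correctness of the estimators under a clean
additive world, not robustness to those real-data complications.

Desk-scale problem sizes used by the tests and acceptance script (e.g.
650 trees × 1,000 markers, 20 block-recovery replicates at n = 400,
100 total null CV cycles) were chosen as the smallest sizes at which the
Monte-Carlo checks are comfortably stable.

## Numerical choices and degenerate inputs

* EM tolerances: 1e-10 (two-locus), 1e-8 (block); likelihoods clip
  probabilities at 1e-300 instead of producing −∞.
* The D′ grid CI collapses to an endpoint when the likelihood
  concentrates there (not an error); two-individual samples give
  near-[0,1] bounds.
* Greedy block selection ties break leftmost; diplotype ties break to the
  smallest variant pair; SNP orientation ties (frequency exactly 0.5)
  keep the input orientation.
* Monomorphic design columns (pᵢ ∈ {0,1}) are excluded from the genomic
  -variance sum; spike-slab updates skip zero-variance columns.
* Divergent residual variance (overflow past 10¹² × Var(y)) raises with
  the iteration number rather than continuing silently.
* `critical_r2` requires ≥ 2 chromosomes; decay profiles with no
  intra-chromosomal pairs raise.

## Known limitations

* No REML or variational alternatives; all inference is MCMC.
* Ordinal traits as Gaussian scores (above) — adequate for ranking, not
  for probability statements on the ordinal scale.
* The block-EM enumerates compatible diplotypes, so cost grows as
  2^(heterozygous sites); the 15-SNP cap keeps this bounded.
* Gabriel blocks on family data reflect familial disequilibrium as well
  as population LD; with few families, blocks can extend beyond planted
  segments.
* GEBV prediction assumes the validation individuals share the training
  population's LD structure; no cross-population transfer is attempted.
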