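# Methods

This note records the models, estimators, numerical choices and known
limitations behind `scallopop`, in the order data flows through the package.

## Drift model and synthetic genotypes

Subpopulation divergence is simulated as pure Wright–Fisher drift: each of
*s* subpopulations starts at the base allele frequencies and, per
generation, its allele counts are resampled multinomially from 2·Ne gene
copies. No mutation, migration or selection is modelled. After *t*
generations the expected standardized allele-frequency variance is

    E[F_ST] = 1 − (1 − 1/(2·Ne))^t,

which the simulator reproduces to within Monte-Carlo error (checked at
Ne ∈ {50, 100, 1000}, t ∈ {10, 20} over 10⁴ replicate loci).

Sampling is HWE within subpopulations: each diploid genotype is two
independent draws from the subpopulation's frequencies. Microsatellite base
panels default to symmetric Dirichlet(1) frequencies over k alleles with k
uniform on 8–14 (mean 11, matching a typically polymorphic panel);
SNP panels draw minor-allele frequencies uniform on (0.05, 0.5). These
priors matter: Dirichlet(1) spectra are somewhat more even than real
microsatellite spectra, which makes simulated panels slightly *more*
powerful than an equally sized empirical panel (see Power below).

RAD-style call sets attach per-genotype stack depths (default 1 + Poisson(19),
mean 20), Bernoulli missingness, and tag grouping (consecutive SNPs per tag)
to a genotype table, providing realistic input for the call filters. No
sequence-level reads are simulated.

All generators derive child seeds from one master seed via SHA-256 of
`(seed, stage-name)`, so results are bit-reproducible and stages are
insensitive to each other's draw counts.

## Summary statistics, HWE, LD, FDR

Expected heterozygosity uses the small-sample unbiased estimator
`2n/(2n−1)·(1 − Σp̂²)` on the n non-missing genotypes; Ho is the observed
heterozygous fraction. Missing genotypes are excluded pairwise per locus;
there is no individual-level deletion anywhere in the package.

The HWE test is the exact conditional probability test evaluated by Monte
Carlo: conditional on allele counts, the probability of a genotype table is
`n!·Πa_k!·2^H / ((2n)!·Πn_ij!)`, and the p-value sums tables no more
probable than the observed one. The chain state is the assignment of gene
copies to individuals; swapping two uniformly chosen copies between two
individuals is a symmetric proposal whose uniform stationary law induces
exactly the conditional table distribution, so every swap is accepted. The
p-estimate is the visit fraction of the `{logP ≤ logP_obs}` region;
its Monte-Carlo standard error comes from between-batch variance. Defaults
(dememorization 10,000; 1,000 batches of 10,000) match the classical
settings for this test; the pipeline uses shorter chains recorded in its
config. Validation: on every biallelic table with n ≤ 20 the estimate
agrees with complete enumeration within its Monte-Carlo error band (the
band is floored at the chain's resolution, 10/N samples, which matters only
for exact p below ~10⁻³; a handful of extreme low-p tables mix slowly and
sit between 3 and 5 standard errors at the test's chain lengths).

Linkage disequilibrium uses the genotypic log-likelihood-ratio G on the
genotype-class contingency table of two loci, with significance by permuting
one locus's genotypes within the population (add-one estimator) and
Fisher's method (−2Σln p, χ² on 2k df) across populations.

Storey q-values estimate π₀ at the single point λ = 0.5
(`π̂₀ = min(1, mean(p > λ)/(1−λ))`), without the spline of the original
program — more robust for the small test families here (36 pairwise tests).
With π₀ fixed at 1 the procedure is exactly Benjamini–Hochberg, which the
suite asserts. All permutation p-values use the add-one estimator and are
one-sided (greater); they can never be 0.

### Filters

Microsatellite loci significant (post-FDR) in more than
`max_deviating_pops = 4` populations are excluded — this keeps loci
deviating in ≤ 2 populations and removes 5-of-9 and 7-of-9 patterns; 3–4 is
a configurable grey zone. SNP call filtering applies, in order: stack depth
< 5 ⇒ genotype set missing; biallelic SNPs called in ≥ 40 individuals kept;
one SNP per tag retained (largest call count, ties to the first). Depth
masking precedes the call-count whitelist so that the filter is idempotent:
counts are always counts of genotypes that survive the depth rule, and
re-running the filter on its own output changes nothing.

## F_ST and population structure

θ is the Weir–Cockerham variance-components estimator, computed per locus
and allele from the standard a (among populations), b (among individuals
within populations) and c (within individuals) components with per-locus
sample sizes honouring missing data; the multilocus estimate is the ratio
of sums over loci and alleles. Monomorphic loci contribute nothing; loci
with fewer than two genotyped individuals in any included population are
skipped. θ may be negative. The implementation is validated to 10⁻¹² against
an independent mean-squares (ANOVA) formulation.

Pairwise significance permutes whole individuals (both alleles together)
between the two populations of a pair — the permutation unit used by the
standard desktop implementations — with p = (1 + #{θ* ≥ θ}) / (n_perm + 1)
and Storey FDR across all pairs. With very small groups (5 vs 5) the
permutation distribution has an atom at the observed split
(~2/C(10,5) per draw), giving an irreducible p floor near 0.009; analyses
that need every diverged pair to clear q ≤ 0.05 should use larger groups or
interpret q near the floor carefully.

Genotype PCA encodes individuals as per-allele dosage vectors (0/1/2),
mean-imputes missing genotypes per column, centers (no scaling) and
decomposes by SVD; signs follow a largest-loading-positive convention.
Structure detection in this package rests on PCA plus pairwise F_ST;
Bayesian admixture clustering is deliberately out of scope.

The Mantel test correlates upper-triangle entries and permutes rows/columns
of one matrix jointly (one-sided, add-one); it is cross-checked against
scikit-bio.

## Power analysis

The power simulation follows the classical drift design: drift all
subpopulations, sample per-population allele counts (multinomial draws of
2n gene copies — distributionally identical to sampling diploid genotypes
under HWE and counting alleles), test per-locus allele-frequency
homogeneity, and combine across the panel. The default test is Pearson's χ²
on the subpopulation × allele table with statistics and degrees of freedom
summed over loci; power is the rejection fraction over replicates, with
binomial mc_se. Allele classes whose pooled expected count per
subpopulation falls below 1 are collapsed into the adjacent class
(microsatellites) or drop the locus from that replicate (biallelic loci,
where no further collapse exists) — the usual guard for the asymptotic
test. A Monte-Carlo Fisher-exact variant (tables sampled with fixed margins,
per-locus p's combined by Fisher's method) is available; it is conservative
because the per-locus MC p-values are discrete. The classical program's
chain settings (burn-ins/batches/iterations) are accepted and recorded but
drive only the Fisher variant.

Calibration at the study design (9 subpopulations × 20 diploids,
13 microsatellite loci): type-I error 0.046 at α = 0.05 and 0.004 at
α = 0.01 (500 replicates). The SNP design (5 diploids per subpopulation) has
per-cell expected counts as low as ~1 and the summed χ² runs hot under the
null (~0.23 at α = 0.05); its power conclusions are unaffected because power
at the simulated effect sizes is saturated, and the Fisher variant is the
remedy when small-sample null calibration matters.

Because the survey's empirical allele frequencies are unavailable, reported
power values are marginalized over panel draws from the generator's prior
(25 panels × 20 replicates); a single 13-locus panel draw moves power by up
to ±0.1 at intermediate effect sizes.

## Outline morphometrics

Boundary pixels are traced with Moore-neighbor (8-connected) tracing and
Jacob's stopping rule; chains are oriented counterclockwise (mathematical
sense; note image y points down) and can be canonicalized to start at the
point of maximal x after centering. Smoothing is the cyclic three-point
moving average (default 10 iterations — enough to remove pixel noise at
512² rasterization without visibly biasing shape). Pseudo-landmarks are
placed at exactly equal arc length along the polyline (default 1000).

Generalized Procrustes alignment is full (translation, scale, rotation; no
reflection), iterating alignment to the re-estimated mean to convergence
(mean-shape change < 10⁻¹¹, ≤ 200 iterations). Because a Procrustes solution
is only defined up to a global rotation, the final frame is canonicalized by
rotating the mean shape's principal axis onto x with a third-moment sign
rule; this makes alignment deterministic and idempotent. Centroid sizes in
original units are preserved on the aligned configurations.

Elliptic Fourier coefficients follow the Kuhl–Giardina piecewise-linear
integrals with chord-length parameterization (a "uniform" equal-increment
parameterization is available; the two coincide on equal-arc-length
resampled outlines, and the uniform mode is the one under which an
analytically sampled ellipse has exactly (a₁,b₁,c₁,d₁) = (2,0,0,1)). No
first-ellipse normalization is applied — alignment has already been done by
Procrustes, and normalizing round, bilaterally symmetric outlines against
their first ellipse is unstable. Reconstruction evaluates the truncated
series at uniform parameters; coefficient round trips are exact to the
polygonal-attenuation limit (~(πn/N)²/3 per harmonic n at N reconstruction
points).

Harmonic-power calibration selects the smallest N with mean cumulative
power fraction ≥ 0.98. By default harmonic 1 is excluded from the baseline:
on Procrustes-aligned, ellipse-like shells harmonic 1 alone carries > 99% of
raw power, so a 98% criterion is only informative on the residual spectrum
(with it included the answer is always 1). Both modes are exposed.

## Shape statistics

Shape PCA centers the specimen × descriptor matrix (no scaling) and uses
SVD with deterministic signs; components are retained to 95% cumulative
variance. The one-way MANOVA reports Wilks' Λ = det(E)/det(E+H) with Rao's F
approximation and its standard degrees of freedom (for one response this is
exactly the ANOVA F); Bartlett's χ² is not provided. Note that published
MANOVA lines sometimes print df pairs that do not match Rao's layout for
the stated number of responses; this implementation always reports Rao df.
Validated against statsmodels' MANOVA and by type-I calibration.

Thin-plate splines use the kernel U(r) = r²·ln r² with exact interpolation
(no smoothing); bending energy is the kernel quadratic form (zero exactly
for affine pairs). Dense pseudo-landmark sets are subsampled (default to
~40 landmarks) before solving — the interpolation system on 1000 nearly
coincident points is ill-conditioned and adds nothing visually. Group mean
shapes for deformation grids are per-group means of aligned configurations.

## Colour

Grey conversion is the plain channel mean (R+G+B)/3 rounded half-up.
Pigmented pixels are shell pixels with grey ≤ 110 (inclusive; exposed as a
flag). The colour index is √(mean pigment grey × pigmented fraction),
implemented literally as printed even though raw mean grey makes *darker*
pigment lower the intensity term; an inverted mode (110 − mean grey) is
available but off by default, and the tension is deliberate — the index is
defined by its formula, not by a monotone-darkness requirement. Empty
pigment sets yield index 0 with undefined mean grey. Population differences
use the classical one-way fixed-effects ANOVA.

The synthetic pigmentation images place an exact-count coherent pigment
patch (grown from a random focal point) inside an elliptical shell mask,
with pigment greys drawn symmetrically around the target mean, unpigmented
shell on 150–230 and white background. They emulate the statistical targets
(mean pigment grey, extent) but none of the optics of real photographs — no
lighting gradients, colour calibration or segmentation errors — so passing
recovery tests demonstrates the estimator pipeline, not robustness to
photography.

## Association models

The genotype–phenotype association fits a random-intercept linear mixed
model by maximum likelihood: y = Xβ + u_pop + ε with u ~ N(0, σ²_b),
ε ~ N(0, σ²_e). The likelihood is profiled over the variance ratio
λ = σ²_b/σ²_e — per group V_g = I + λJ inverts in closed form — and
maximized by bounded 1-D search on log λ, always compared against the λ = 0
boundary (where the fit is exactly OLS). Per-coefficient tests are 1-df
Wald χ² = (β̂/se)² by default, with a likelihood-ratio option; ML (not
REML) is the default to match the convention of reporting χ² tests from
ML fits. The standard run puts the first two genetic PCs in together as
fixed effects and excludes a named outlier population (genetically and
phenotypically distinct populations otherwise dominate both sides of the
regression). Validated against statsmodels MixedLM (ML) and by type-I
calibration and parameter-recovery simulations.

## The plasticity scenario

The reference end-to-end scenario encodes the study's headline pattern:
nine populations; genotypes identical in distribution across eight of them
(no drift) with one outlier drifted t = 200 generations at Ne = 100
(E[F_ST] ≈ 0.63); shell-shape population means differing in hinge-related
low harmonics with between-population spread about twice the
within-population coefficient noise (echoing the strong published shape
separation); pigmentation extent rising 0.15 → 0.55 and pigment grey
70 → 95 across populations with individual jitter. Genetics are sampled at
the survey's 20 individuals per population. Expected outcome, which the
acceptance suite verifies over seeded replicates: shape MANOVA and colour
ANOVA reject at p < 0.001 in ≥ 95% of runs, every outlier pair is
significant after FDR, and ≥ 95% of non-outlier pairs are non-significant
(assessed on q-values, the table-wide convention this analysis follows
throughout; note that at raw α = 0.05
the expected non-significant fraction of truly null pairs is 95% exactly,
so a raw-α version of this check sits on a knife edge by construction).

## Problem sizes

Defaults were chosen so the full test suite and the acceptance script each
run in minutes on one CPU: 500 power replicates per cell (25 panels × 20
for the marginalized table), 200 replicates for the 2000-SNP cell, 10⁴ loci
for drift calibration, 100 scenario replicates for the recovery rates with
200 pseudo-landmarks per outline, 1000 F_ST permutations, HWE chains of
2 × 10⁴ sampled steps for the enumeration comparison. The estimators
themselves have no size-dependent shortcuts; larger runs only tighten the
Monte-Carlo error.

## Known limitations

- Drift only: no migration, mutation or selection; power and F_ST
  expectations inherit this.
- The microsatellite frequency prior (Dirichlet(1)) is slightly more even
  than real spectra; simulated panel power at intermediate effect sizes
  runs a few points high of an empirical panel of the same size.
- The summed-χ² homogeneity test is anticonservative for very small
  per-population samples (5 diploids); use the Fisher variant there.
- Image analysis starts from binary masks and grey images; segmentation of
  raw photographs is out of scope.
- No Bayesian clustering, AMOVA beyond pairwise θ, haplotype phasing or
  outlier-locus scans.
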