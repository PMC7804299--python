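# Methods

`facemodkit` implements, as a tested library, an analysis chain that
links low-frequency coding variants to multivariate 3D facial-shape
modules. This note documents the models and estimators, the parameters that
matter, the synthetic-data generator, the numerical choices, and the known
limitations.

## Shape phenotyping

**Alignment.** Landmark configurations (n × L × 3, homologous points in mm)
are superimposed by generalized Procrustes analysis: centroids to the
origin, optimal proper rotations (Kabsch fits with the reflection branch
forbidden), scaling to unit centroid size, iterated against the evolving
mean until the mean changes by < 1e-10. Pre-scaling centroid sizes are
retained and passed downstream as the facial-size covariate, so size is
removed geometrically and adjusted for statistically, once each.

**Segmentation.** Landmark similarity is the RV coefficient between the
n × 3 displacement blocks of two landmarks,
RV(i, j) = ‖X_i′X_j‖²_F / (‖X_i′X_i‖_F ‖X_j′X_j‖_F) ∈ [0, 1] — bounded,
symmetric, and invariant to a common rotation, which makes the whole stage
equivariant under rigid motion of the input. Each segment is split by the
normalized-Laplacian spectral bipartition of its similarity graph: the sign
pattern of the Fiedler vector seeds a k-means (k = 2) refinement on the
two-dimensional spectral embedding; disconnected graphs split along
connected components, and a structureless (all-equal) similarity falls back
to a deterministic half split. GPA is re-run inside every segment before it
is split again; five levels give 2⁵ − 1 = 31 nested segments. Branches
below 8 landmarks stop splitting and the hierarchy is flagged incomplete.

**Module phenotypes.** Each segment's re-aligned coordinates are reduced by
PCA; the retained dimension K comes from parallel analysis (observed
eigenvalues against the 95th percentile of eigenvalues from column-permuted
data, 100 permutations by default, floor at K = 1). PC score columns carry
a deterministic sign convention — the largest-magnitude entry of each score
column is positive — because PCA of rigidly transformed coordinates
reproduces scores only up to column sign, and the homogeneous phenotype
kernel is not sign-invariant; without the convention the end-to-end
rigid-invariance guarantee would be void.

**Covariate adjustment.** Module scores are residualized on sex, age,
height, weight, centroid size and ancestry PCs by PLS2 regression with as
many components as the covariate matrix has rank. At that component count
the PLS fit coincides exactly with the least-squares projection onto the
covariate column space, so the residualization is computed in closed form
and residuals are orthogonal to every covariate to machine precision.

**Outlier QC.** Robust squared Mahalanobis distances per module (minimum
covariance determinant center/scatter, classical fallback if singular),
flagged against a Bonferroni-style χ²_K cutoff at 1 − α/n, with Q–Q data
exported for visual review.

## Genotype preparation

Dosages are oriented to the minor allele (MAF = MAC / 2n over non-missing
calls); multi-allelic sites are skipped. The low-frequency filters keep
variants with MAF < 1% (strict) **and** MAC ≥ 4 (variants with three or
fewer minor alleles removed); genes need ≥ 2 qualifying variants. The two
filters commute. Missing dosages are imputed to 2·MAF at test time.
Variant weights are Beta(1, 25) density values at the MAF — strictly
decreasing, so rarer variants count more. Note a desk-scale consequence:
with n < 400 individuals, MAC ≥ 4 forces MAF ≥ 1% and the filters become
mutually exclusive, so all shipped experiment configurations use n ≥ 400.

## Kernel association engine

For one gene (weighted dosages G_w, n × m) and one module (adjusted scores
Y, n × K), the null multivariate regression Y = XB + E (X defaults to an
intercept, as adjustment happened at phenotyping) yields residuals R and
Σ̂ = R′R/(n − p). The score matrix is S = G_w′ R Σ̂⁻¹. The 2 × 2 kernel
grid gives

* Het × SKAT:  Q = Σ_j ‖s_j‖² = tr(SS′)
* Hom × SKAT:  Q = Σ_j (1′s_j)²
* burden variants collapse S to its column sum s_b first.

Under the null, cov(vec S) = Σ̂⁻¹ ⊗ (G_w′P₀G_w) with P₀ the covariate
projector, so each Q is a Gaussian quadratic form with eigenvalues
{a_i b_ℓ}: a = eig(Σ_P Σ̂⁻¹) with Σ_P = 11′ (Hom, rank 1: a = 1′Σ̂⁻¹1) or
I (Het), and b = eig(G_w′P₀G_w) (SKAT) or 1′G_w′P₀G_w1 (burden).
Eigenvalues below 1e-10 of the maximum are dropped; if none survive, p = 1
flagged. Σ̂ gets a 1e-8·mean-diagonal ridge when its condition number
exceeds 1e10.

**Mixture-of-χ² tails.** P(Q > q) for Q = Σλχ²₁ is computed by Ruben's
exact series — with mixing scale β = min λ the law is a true mixture of
central χ² distributions with non-negative weights, so the survival
function is a positive series evaluated directly (no cancellation for small
p), truncated when the unassigned mixture mass is below 1e-13 or 1% of p.
The series needs ≈ (λ_max/λ_min)·30 terms, so wide spectra route to
Kuonen's saddlepoint approximation (relative error a few percent in the
tails), with Liu moment matching as the last resort; a method flag records
which path produced each p-value. A characteristic-function quadrature
(Imhof/Davies-style) was rejected: its integrand decays as u^(−k/2−1), so
a one-eigenvalue problem cannot reach 1e-10 absolute accuracy by
truncation.

**Omnibus.** T = min of the four kernel p-values. B = 500 null resamples
(residual rows redrawn from N(0, Σ̂), projected, scored with the same
weights) give probit-transformed p-values whose 4 × 4 correlation feeds a
Gaussian copula; p_omnibus = 1 − P(all probits ≤ probit(1 − T)). Resample
p-values use the Liu approximation — only a monotone transform of the
resampled Q enters the correlation — while observed p-values use the exact
path. The orthant probability is Genz quasi-Monte-Carlo with a **fixed**
integration rule (scipy draws a fresh random shift per call by default,
which would leave ~1e-5 irreproducibility in every reported omnibus
p-value) and tight tolerances (abseps 1e-7). A scan shares one block of
resample draws per module across genes, which preserves per-gene copula
estimation while keeping the cost at ~m·n·K·B flops per gene.

Verified properties (test suite): each kernel's null Q matches its mixture
law (KS); Hom × Burden equals the collapsed-genotype score test to 1e-10;
K = 1 collapses Hom/Het; omnibus calibration is uniform under the null and
respects the dependence bounds T ≤ p ≤ 1 − (1 − T)⁴; rejection rates sit
within 3 binomial SEs of α at 0.05 and 0.01 over 2000 null gene-module
tests.

**Known finite-sample caveat.** The asymptotic mixture null and the exact
permutation null of the same statistic differ by a finite-population
fourth-cumulant correction of order 1/n (the permutation distribution is
slightly platykurtic regardless of the genotype/phenotype marginals). At
n = 50 this shifts central p-values by ~0.01, which is visible against a
1e5-permutation Monte-Carlo comparison; at the pipeline's working sizes
(n ≥ 400) it is far below statistical resolution. The corresponding oracle
test in the suite documents this gap rather than hiding it.

## Single-variant follow-up

For variants inside genes that pass the gene-level threshold: reverse
regression of the (rounded) genotype category on all K module PCs jointly.
Three observed classes fit a proportional-odds logistic model; two classes
reduce to binary logistic regression. The likelihood-ratio statistic
against the margins-only null (whose log-likelihood is closed-form) is
referred to χ²_K. Separation — common when carriers are a handful of
heterozygotes — triggers a Jeffreys-penalized (Firth-type) fit, flagged in
the output. Both the full table (every significant gene × module × variant)
and a best-module-per-variant view are produced.

## Multiplicity and effect sizes

The 31 modules overlap, so their tests are correlated. The inter-module
correlation is the RV coefficient between module PC score blocks, and the
effective number of independent modules is Li–Ji's
M_eff = Σ_i [1(λ_i ≥ 1) + (λ_i − ⌊λ_i⌋)] over its eigenvalues (eigenvalues
rounded at 1e-10 before the floor to keep 2.999… from counting as 2 + 1).
The significance threshold is α/(n_genes · M_eff); at cohort scale
(8091 genes, M_eff = 19, α = 0.05) this prints as 3.3e-07.
Effect size is the Euclidean distance between carrier and non-carrier mean
vectors in a module's PC space. Morph exports give the non-carrier mean
segment shape, the carrier-minus-non-carrier displacement multiplied by an
exaggeration constant (default 7), and its signed component along local
surface normals (plane fits to 8 nearest neighbours) for
depression/protrusion colouring, as ASCII PLY and TSV.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
photorealistic faces. The template is a regular 2D grid embedded as a
curved 3D patch at face scale (~120 × 160 × 30 mm). A balanced binary
segmentation of the grid fixes the ground-truth hierarchy; every tree node
contributes `deformation_rank` (default 6) spatially smooth random fields
confined to its landmarks, each scaled per individual by a Gaussian
coefficient. The coefficient SD at a node is `deformation_sd` ×
`level_decay`^(depth below leaf) (defaults 0.5 mm and 0.75). Both knobs
matter for identifiability: leaf-level variance must dominate shared parent
variance for leaves to separate, but every level must retain enough of its
own variance for the splits above the leaves to follow the tree rather
than incidental smooth structure — a steep decay makes the recursion "peel"
single leaves instead of bisecting. With the default profile the
segmentation stage recovers planted leaves with ARI > 0.9 at a leaf-SNR
(deformation_sd / noise_sd) of 4 and returns the full 31-segment tree
across seeds. Landmark noise is iid Gaussian (default 0.1 mm). Covariates
(binary sex, uniform age, Gaussian height/weight, a face-size factor,
standard-normal ancestry PCs) act through their own full-face smooth
fields, linearly in the standardized covariate; the default magnitudes put
roughly a fifth of shape variance into covariate effects, since clustering
operates on unadjusted coordinates and globally coherent covariate
variance competes with the hierarchical signal.
Genotypes are Binomial(2, MAF) dosages with MAF uniform on a configured
range, laid out on chromosomes 1–22 and grouped into genes. A planted gene
effect displaces carriers (≥ 1 minor allele anywhere in the gene — at
low frequency carriers are effectively heterozygotes) along a fixed
unit-norm field confined to one segment, by an exact total displacement in
mm. Per-individual rigid nuisance transforms (rotations to 15°,
translations to ±20 mm, scale 0.9–1.1) are applied last so GPA is
exercised non-trivially. Everything is deterministic given the seed;
stage seeds are derived by hashing the stage name with the master seed.

What the generator does **not** emulate: real mesh topology and texture,
asymmetry structure, non-Gaussian shape variation, linkage disequilibrium
between variants, relatedness, and non-European allele-frequency spectra.
Passing tests therefore demonstrate the correctness and calibration of the
estimators under the assumed data structure, not robustness to everything
real data can do.

## Problem sizes and calibrated constants

Shipped experiment configurations are desk-scale choices that keep the full
31-segment hierarchy well-posed while running in minutes: n = 400–500
individuals, L = 64–256 landmarks, 10–120 genes of 3–6 variants. The
planted-effect displacement in the power experiments is 3.0 mm over a
64-landmark leaf segment, calibrated once by simulation so that the causal
gene tops its module's omnibus scan in roughly 80–90% of replicates; the
null-calibration experiments use 5 variants per gene at MAF 0.002–0.01, the
power experiments MAF 0.004–0.008 so the planted gene reliably survives the
MAC filter at n = 500.

## Design choices on genuinely open points

* Landmark–landmark and module–module similarity both use the RV
  coefficient, keeping one similarity notion across the package; whether
  the original analysis used RV for the inter-module correlation feeding
  Li–Ji is unknown, so M_eff on synthetic data is reported as this
  package's own quantity (both raw and round-half-up integer).
* Segment boundaries can be re-estimated per dataset (default) or frozen by
  supplying a hierarchy JSON (`--hierarchy`), since either convention is
  defensible.
* GPA removes scale; facial size re-enters solely as a covariate.
* The test-time null design matrix is intercept-only (adjustment already
  happened at phenotyping) but accepts covariates.
* Multi-gene variants contribute to every mapped gene.
* Dosages imputed to 2·MAF are rounded to the nearest category for the
  ordinal follow-up model.

## Limitations

Binary/survival phenotype kernels, kinship adjustment, template-to-scan
registration, functional annotation and enrichment are out of scope. The
saddlepoint fallback has a few-percent relative error in extreme tails;
p-values below ~1e-14 should be read as "very small" rather than exact.
The copula correlation is estimated per gene from B = 500 resamples, so
omnibus p-values carry ~0.04 estimation noise in the correlation entries —
negligible for calibration, visible only in exact-reproduction exercises,
which is why scans fix their seeds.
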