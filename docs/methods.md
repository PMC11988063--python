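# Methods

`testday` implements a two-stage genomic evaluation of test-day milk fat
percentage for smallholder crossbred dairy herds, together with the
quality-control protocol that precedes it and a synthetic-data generator
that emulates the smallholder data structure.

## Data model

A **test-day record** is one fat% measurement on a cow at a given days in
milk (DIM), carrying the herd, the community development centre (CDC, an
administrative grouping of farms), the lactation number and a year-month
token.  Genotypes are biallelic SNP dosages in {0, 1, 2} with missing calls
kept distinct from homozygous-reference, per-SNP chromosome labels (cattle
autosomes 1–29, X, Y, MT) and optionally per-call GenCall quality scores.

## Phenotypic quality control

Three sequential steps, each emitting an audit ledger row
(screened/retained/dropped, with retained + dropped = screened enforced at
construction):

1. **Window and minimum count.** Records outside the closed DIM window
   [8, 340] are dropped; then any (cow, lactation) group with fewer than 4
   remaining records is removed entirely.
2. **Outlier cows.** Cows whose mean fat% lies strictly more than 3 SD
   *above* the population mean of cow means are removed with all their
   records.  The screen is one-sided by design (the protocol targets
   implausibly high fat readings); a two-sided variant is available by
   flag.  Cows exactly at the threshold are retained.
3. **Residual outliers.** An OLS regression of fat% on the stage-1 fixed
   effects (lactation number, CDC, year-month × CDC; optionally Legendre
   DIM covariates) is fit and records whose internally studentized residual
   falls strictly outside the closed band [−2, +2] are dropped.
   Rank-deficient designs (common for sparse year-month × CDC cells) are
   handled by the pseudoinverse.  Note that this band removes ≈ 4.6% of
   records even from perfectly clean Gaussian data; that is a property of
   the protocol, not a defect, and the pipeline tests budget for it.

Step 2 uses post-step-1 records only (sequential semantics).  Calendar
spacing of "monthly" records is not enforced — only counts and the DIM
window are.

## Genotypic quality control

Stages in ledger order, all retention thresholds strict ("higher than"):
GenCall screen (calls with score ≤ 0.15 set missing, skipped with a warning
when scores are absent); duplicate detection (pairwise genotype correlation
\> 0.98 over shared calls, keeping the higher-call-rate animal, ties broken
by id order); animal call rate > 0.90; SNP call rate > 0.95 and MAF > 0.01
(reported as one combined drop, as summary tables conventionally do);
restriction to autosomes 1–29.  Per-SNP statistics are recomputed over the
currently retained animals, so the ledger makes the effect of animal
removal auditable.  QC is idempotent, and the ledger supports composing the
marginal drops into the cumulative retained count.

## Stage 1: repeatability animal model

y = Xb + Z₁a + Z₂h + e with fixed effects b (lactation number, CDC,
year-month × CDC; reference-level coding with an intercept, confounded
columns absorbed by pivoted QR), a ~ N(0, σ²ₐI) (animals deliberately
treated as unrelated at this stage), h ~ N(0, σ²ₕI), e ~ N(0, σ²ₑI).

Variance components are estimated by **EM-REML on Henderson's MME**: the
classic updates σ²ᵤ = (û'û + σ²ₑ tr(Cᵘᵘ))/qᵤ and
σ²ₑ = y'(y − Wŝ)/(n − rank(X)).  Two numerical choices matter in the
smallholder setting:

* the fixed-effect block is absorbed once (Schur complement), so each
  iteration factorizes only the (animals + herds)-dimensional system;
* because ~44% of herds hold a single cow, animal and herd effects are
  partially confounded and plain EM crawls along a likelihood ridge; the
  component-wise geometric trajectory is therefore Aitken-extrapolated
  (capped jumps, positivity floor), a standard EM acceleration that leaves
  the fixed point unchanged.  Convergence is declared when each component's
  change, relative to max(itself, 0.1% of var(y)), drops below 1e-5;
  components below that scale are effectively boundary values and do not
  stall the test.

Solving the MME at the estimates yields BLUE(b), BLUP(a), BLUP(h).  The
**adjusted record** is y − Xb̂ = â + ĥ + ê, reported per record as
IFE (the record-level residual ê), ARE (â) and HRE (ĥ), with
AFP = IFE + ARE + HRE holding exactly.  The label "individual fixed
effect" for the first component follows the source convention for this
table even though the quantity behaves as a residual; the additivity of the
three components to the adjusted record is the defining property.

## Genomic relationship matrix

VanRaden method 1: W = M − 2p, G = WW'/(2Σpⱼ(1−pⱼ)), with frequencies
observed from the data unless supplied; method 2 (per-SNP scaling) by flag.
Missing calls are mean-imputed before centering (QC caps missingness at
5–10%).  Column centering makes G singular in the ones direction, so a
blend G* = (1−w)G + wI (default w = 0.01) is applied before any solver and
verified positive definite; w = 0 is an identity transform.

## Stage 2: Bayesian inference

### Random-regression GBLUP engine

y* = μ1 + Z₁a + Z₂p + Z₃h + e on adjusted records, where each animal's
additive genetic (a) and permanent environmental (p) coefficients, and each
herd's coefficients (h), multiply a normalized Legendre basis
φₖ(x) = √((2k+1)/2)·Pₖ(x), x = 2(t−8)/(340−8) − 1, of order m.  The
covariance structure is var(a) = G⊗Ka, var(p) = I⊗Kp, var(h) = I⊗Kh, and
the residual variance is homogeneous within and heterogeneous between DIM
classes (default bands 8–45, 46–115, 116–225, 226–340 when more than one
class is requested; boundaries are a design choice, configurable).

Gibbs updates: coefficient blocks from their multivariate-normal full
conditionals (joint per effect type); Ka, Kp, Kh from inverse-Wishart full
conditionals IW(ν₀+q, S₀ + A'G⁻¹A) with identity-proportional prior scale
(0.01·var(y)·I) and minimal proper degrees of freedom (dim + 2); residual
class variances from scaled inverse-χ² (ν = 4, scale 0.5·var(y)); the
intercept from its normal conditional.  Chains get independent
`SeedSequence`-spawned streams; retained draws per chain are exactly
⌊(n_iter − burn_in)/thin⌋.

When the model is intercept-only (m = 0, no PE/herd, one residual class) an
exact fast path is used: with D = Z'Z diagonal, D^{-1/2}G⁻¹D^{-1/2} is
eigendecomposed once and every coefficient draw costs O(n²).  It samples
the same full conditionals (reparameterized to genetic-value space,
σ²_g = Ka₀₀/2) and is cross-checked against the general Cholesky path in
the tests.

Per-draw summaries: Va = the DIM-window average of φ(t)'Ka φ(t) (for m = 0
simply σ²_g), Ve = the record-weighted mean residual-class variance, and
**h² = Va/(Va + Ve)** — permanent-environment and herd variances are
excluded from the denominator, matching the convention in which the total
phenotypic variance is reported as Va + Ve.  GEBV per animal is the
DIM-window average of the genetic trajectory (for m = 0, the genetic
value), averaged over retained draws.

### BayesR SNP-mixture engine

On one aggregated record per genotyped animal (the m = 0 reduction):
ȳ = μ1 + Wβ + ε with each βⱼ from a four-component normal mixture with
variances (0, 1e-4, 1e-3, 1e-2) × σ²_g (the first component exactly zero).
Per sweep, each SNP's class is sampled from the component posterior odds
and its effect from the normal full conditional; π from
Dirichlet(1 + counts); σ²_g and σ²_e from scaled inverse-χ².
GEBV = W·(posterior-mean β).

A known identifiability property, verified analytically and in the tests:
under pure-noise data the 1e-4 component is statistically indistinguishable
from the zero class (its per-SNP Bayes factor versus the null has
E[log BF] ≈ 0), so posterior mass splits between classes 1 and 2 rather
than concentrating on class 1 alone.  The identifiable statements — the
effectively-null mass (classes 1+2) dominates, the large-effect classes
empty out, and the fitted signal (h², effects, GEBVs) is negligible — are
what the tests assert.

### Convergence diagnostics

Split-chain potential scale reduction (implemented in-package with explicit
zero-variance semantics: identical half-chains → 1, disjoint constant
chains → ∞) and effective sample size via ArviZ, per scalar parameter.

## Synthetic-data generator

The generator's defaults are the study conditions it emulates:

* herd sizes i.i.d. from the published smallholder composition (83.9% of
  1,260 herds hold one or two cows; the open "7 and above" class is drawn
  as size 7), herds dealt round-robin to CDCs at ~22 herds per CDC (the
  study-scale farms-per-centre ratio);
* Hardy–Weinberg genotypes at frequencies uniform on the MAF range
  (default 0.05–0.5), chromosomes cycling over autosomes, 5,000 SNPs by
  default (a scaled-down stand-in for a post-QC 50K panel);
* SNP effects from the BayesR-type mixture, proportions
  (0.95, 0.03, 0.015, 0.005), variance fractions (0, 1e-4, 1e-3, 1e-2) of
  the genic variance.  Drawn effects are rescaled so the *realized* genic
  variance Σ2pq·β² equals the configured Va exactly
  (`standardize_genic_variance`, on by default): with ~25 large-effect SNPs
  carrying ~¾ of the variance, the unstandardized realized Va has a ~20%
  coefficient of variation, which would make recovery experiments measure
  mixture sampling noise rather than estimator behaviour;
* variance components Va = 0.012, Ve = 0.106 fat%² (herd and PE variances
  default to 0, as in the evaluation they emulate); fixed-effect levels for
  lactation, CDC and year-month × CDC drawn i.i.d. N(0, 0.05²) around a
  base fat% of 4.5 (magnitudes are a design choice — none are published);
* 8 test days per lactation, equally spaced in [8, 340] (jitter optional),
  year-month tokens advancing monthly from a random calving month;
* defects (duplicates, low call rates, monomorphic/non-autosomal SNPs,
  outlier cows, residual-outlier records, short lactations) injected after
  clean simulation with an exact expected-removal manifest.  Duplicate rows
  are appended last, copying the possibly-masked original, so the
  keep-higher-call-rate rule removes exactly the manifest entry.

What the generator does **not** emulate: linkage disequilibrium and
admixture structure (SNPs are independent, so GRM off-diagonals are pure
noise around zero), genotyping-intensity artifacts, calendar seasonality of
fat%, culling/selection, and pedigree relationships.  Passing recovery
tests therefore demonstrate correctness of the estimators under the stated
model, not robustness to population structure.

## Validation experiment sizes

The headline recovery experiment uses 333 herds (~490 cows) × 8 records,
5,000 SNPs, and 3 chains × 5,000 iterations (1,000 burn-in, thinned by 10)
on the m = 0 GBLUP path; the full-length chain configuration
(3 × 25,000 / 5,000 / 10) remains the library default for real analyses.
Unit tests use smaller populations (tens of herds, hundreds of SNPs) with
seeds fixed throughout.  Stage-1 fixed-effect estimation with sparse
year-month × CDC cells absorbs a little genetic and residual variance, so
posterior means sit within a few percent of the simulation truth rather
than exactly on it; the recovery tolerance (±0.03 on h²) reflects that.

## Known limitations

* The exact hybrid the published analysis ran (an animal-level
  random-regression model "executed using the Bayes R method") is not
  recoverable from its description; this package provides both coherent
  readings — RR-GBLUP with G⊗Ka, and a BayesR SNP mixture on the
  aggregated reduction — behind one posterior interface.
* EM-REML convergence on heavily confounded animal/herd designs yields a
  well-converged likelihood but an imprecise σ²ₐ/σ²ₕ split; adjusted
  records (y − Xb̂) are insensitive to that split.
* The mean-dosage imputer is a baseline for the masking-concordance
  metric, not a substitute for haplotype-based imputation.
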