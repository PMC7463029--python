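# Methods

This note documents the models behind `aortaflow`, the defaults and why
they were chosen, the numerical strategy of the fits, and what the
synthetic cohort can and cannot tell you about real data.

## Flow metrics

A subject's raw input is a cine of 2D cross-sectional velocity maps (m/s)
with a boolean lumen mask and pixel spacing.  Per frame we compute the
spatial mean and maximum over masked pixels and the lumen area
CSA = (masked pixels) × (pixel area).  Over the cycle:

* U_pm = max over frames of the spatial mean (peak bulk velocity, usually
  at systole);
* U_max = max over frames of the single-pixel maximum;
* D = 2√(CSA/π), the equivalent-circle diameter.  We derive D from the
  traced area rather than a caliper measurement because it is reproducible
  from the mask and insensitive to non-perpendicular measurement;
* Re_pm = ρ·U_pm·D/μ and Re_max = ρ·U_max·D/μ, with blood density
  ρ = 1050 kg/m³ and dynamic viscosity μ = 3×10⁻³ N·s/m² by default.
  Both Reynolds numbers include ρ; a definition of Re_pm without it is
  dimensionally inconsistent with Re = ρUL/μ.

Numerical conventions: velocities are stored in m/s and a declared
`units="cm/s"` input is converted (a single division by 100) on
construction; negative (regurgitant) velocities enter the spatial mean
as-signed, with a magnitude-based maximum available behind a flag; ties in
either maximum resolve to the earliest frame and row-major first pixel, so
results are deterministic; velocities beyond a declared Venc warn (likely
phase aliasing) but do not error.  The straight-pipe turbulence threshold
Re = 4,000 is exposed as `flow.TURBULENT_RE_THRESHOLD` and the fraction of
subjects above it is reported by the pipeline.

## Synthetic cohort

The generator produces the study conditions the pipeline is tested under.

**Pedigrees.**  Families are three-generation units: an optional
grandparent couple (probability 0.3), a parent couple, and a sibship drawn
from {3: 0.5, 4: 0.3, 5: 0.2} — every sibship has at least three members,
matching an ascertainment rule that requires quantitatively assessable
sibships.  Spouses are unrelated founders.  One sib per family is the
proband, always phenotyped and always hypertensive; other members attend
imaging with probability 0.65 (sibs), 0.20 (parents), 0.05
(grandparents).  With 108 families this yields ≈344 phenotyped members in
expectation (≈3.19 per family).  These attendance probabilities are a
calibration of the cohort's size and kinship spectrum, not a
reconstruction of any recruitment history.

**Genotypes.**  Founder alleles are i.i.d. Bernoulli(p_i) (Hardy–Weinberg
at the panel frequency); non-founders receive one uniformly chosen allele
from each parent (gene dropping), so transmissions are Mendelian-consistent
by construction and allele frequencies are conserved in expectation.  SNPs
are independent (no linkage disequilibrium); the GREML and QC properties
tested here do not require LD, and an LD-aware panel would change none of
the estimators' contracts.

**Covariates.**  BMI ~ N(25.88, 3.77²), clinical systolic BP
~ N(139.71, 21.83²), ~49% male.  Ages follow the generational structure:
sibship anchors ~ N(48, 8²) per family, each parent generation ~N(28, 4²)
years older, clipped to 19–73.  Hypertension prevalence among the
*phenotyped* cohort is calibrated to 39% by solving the mixture with the
always-hypertensive probands.  SBP is drawn marginally (not conditionally
on hypertension) so its moments are exact.

**Traits.**  y = Σβ·covariate + g + e with h² = σ²g/(σ²g+σ²e) held exactly
by construction.  In kinship mode g ~ MVN(0, 2Φσ²g) per family block; in
causal-SNP mode g sums standardised effects of randomly chosen panel SNPs
and is rescaled so its realised variance equals σ²g exactly (which removes
one source of between-replicate variance in recovery experiments).

**Velocity phantoms.**  A disc lumen of radius R with radial profile
u(r) = v_c·(1 − (r/R)^k), scaled by a normalised half-sine systolic
waveform (peak exactly 1, diastolic level 0.05) plus i.i.d. Gaussian pixel
noise.  The spatial mean of the profile is v_c·k/(k+2).  A parabolic
profile (k = 2, Poiseuille) is the default for a bare phantom, but the
*cohort* default uses k = 2.6: a fully developed parabolic profile forces
U_pm/U_max = 0.5, while large-artery flow is blunter, and k = 2.6 gives
mean/centre ≈ 0.565, which reproduces the target cohort means
U_pm ≈ 0.45 m/s and U_max ≈ 0.79 m/s simultaneously.  Radii ~ N(15.5,
1.75²) mm on a 64×64 grid of 1.25×1.25 mm pixels give D ≈ 0.031 m.  Pixel
noise is 0.005 m/s by default.

Known divergence from real cohorts: radius and centreline velocity are
generated independently, whereas physiologically mean velocity scales
roughly with flow/CSA and anticorrelates with lumen size.  Consequently
the *mean per-subject* Re_pm here (≈4,800) sits near the product of the
marginal means, higher than the ≈4,100 typical of real ascending-aorta
cohorts whose U–D anticorrelation pulls the product down.  Passing tests
therefore validate the estimators under a realistic kinship and noise
structure, not the joint U–D distribution of any particular population.

## Covariate adjustment

Bidirectional stepwise linear regression per trait over
{age, age² (of centred age, to curb collinearity), sex, BMI, SBP,
hypertension}: forward entry of the most significant candidate with
partial-test p < 0.05, then backward removal of any included covariate
with p ≥ 0.05, iterated to a fixed point.  The removal threshold is
configurable (0.10 reproduces SPSS's default asymmetric rule; we default
to the symmetric 0.05 since only the 0.05 inclusion criterion is given).
Residuals from the final model are z-scored (exactly mean 0, variance 1),
and individuals with |z| > 3 are excluded *without* refitting — fit →
standardise → exclude, with an optional refit flag.  On Normal data the
3-SD rule excludes ≈0.27%, reproducing the modest per-trait attrition seen
in covariate-adjusted imaging cohorts.

## Genotype QC

Filter order is fixed and logged: SNP call rate (< 0.95 removed) → MAF
(< 0.05 removed; a value exactly at the threshold is kept) → exact HWE
(p < 10⁻⁸ removed, founders only by default since relatedness inflates
rejection) → sample call rate → per-individual heterozygosity window
(inclusive bounds; defaults to mean ± 3 SD of the observed distribution,
because any published window such as 0.31–0.33 is cohort-specific) →
Mendelian checks.  The order matters (MAF is computed before any sample is
dropped) and the suite documents a case where permuting it changes counts.
A two-stage runner mirrors pre-imputation (MAF 1%) and final (MAF 5%)
passes back to back, imputation itself being out of scope.

The HWE test is the exact conditional test: given the allele counts, the
heterozygote count follows a hypergeometric-type distribution
P(n_Aa = h) ∝ n!·2^h / (n_AA!·h!·n_aa!), and the p-value sums the
probabilities of all configurations no more probable than the observed one
(mid-p variant available, off by default so the enumeration oracle is the
reference).  Log-gamma arithmetic with a normalising log-sum keeps it
stable to large n.

Mendelian checks flag impossible child dosages for trios (full
impossibility table) and duos (opposite homozygotes).  Flagged *child*
genotypes are set to missing and the check iterates to a fixed point — an
approximation to full multi-generation consistency analysis; blanking the
whole trio (PLINK's behaviour) is deliberately not done so that injected
single-genotype errors are recovered exactly.

## Variance-components heritability

Both estimators fit y = Xβ + g + e with cov(g) = K·σ²g.

**Pedigree ML.**  K = 2Φ from the recursive kinship coefficients
(founders unrelated; φ_jj = (1+φ_fm)/2; φ_jk = (φ_fk+φ_mk)/2).  Families
are independent blocks, so Ω = σ²(h²·2Φ + (1−h²)I) is block-diagonal.
Each family's 2Φ is eigendecomposed once; in that basis the mean (GLS) and
total variance σ² have closed-form profile maximisers, leaving a bounded
1-D search over h² ∈ [0, 1] (21-point coarse grid, then Brent refinement
to 10⁻¹⁰).  This replaces a generic 2-D quasi-Newton optimisation with
multistart: the profile likelihood in h² is cheap, the boundary is handled
exactly, and there are no convergence failure modes to guard.  The
environment-only null has closed-form MLEs, and the LRT
2(ℓ_full − ℓ_null) is referred, by default, to the ½χ²₀ + ½χ²₁ mixture
appropriate when σ²g = 0 lies on the boundary (plain χ²₁ available as the
conservative option; both conventions are reported because published
analyses rarely state which their software used).  The SE of ĥ² comes from
the curvature of the profile log-likelihood at an interior optimum.  When
2Φ ≈ I (all subjects unrelated) only σ²g + σ²e is identifiable; the fit
flags this and pins h² at the boundary rather than returning an arbitrary
split.

**GREML (AI-REML).**  K = A, the genomic relationship matrix with
standardised-dosage off-diagonals A_jk = (1/m_jk) Σ (x_ij−2p̂)(x_ik−2p̂)/(2p̂q̂)
over pairwise-complete SNPs, and the corrected diagonal
A_jj = 1 + (1/m_j) Σ (x² − (1+2p̂)x + 2p̂²)/(2p̂q̂) whose expectation is
1 + F.  Pairwise-complete counts (not mean imputation) handle
missingness; QC keeps missingness ≤ 5% so the difference is small.
Monomorphic SNPs raise an error naming the SNP — reaching the GRM with one
means the MAF filter was bypassed.  The restricted likelihood of
V = A·σ²g + I·σ²e is maximised by average-information updates
θ ← θ + AI⁻¹·score; A is eigendecomposed once (with a 10⁻⁸ ridge), making
every iteration O(n·p).  Any AI step that leaves the parameter space or
lowers the restricted likelihood falls back to an EM step
(σ² ← σ² + σ⁴(yᵀPQPy − tr(PQ))/n), which cannot decrease it;
monotonicity is asserted every iteration and non-convergence after
``max_iter`` raises with the iteration trace.  Convergence is |ΔlogL| <
10⁻⁸.  SE(ĥ²) uses the inverse AI matrix and the delta method; the
p-value is the boundary LRT against the closed-form σ²g = 0 null.  Fixed
effects default to an intercept over pre-adjusted residuals (matching a
pipeline that standardises before the genetic stage); covariates can
instead be passed into the REML fit via ``X``.

ML is used on the pedigree side and REML on the SNP side deliberately:
these mirror the two tools such analyses conventionally contrast, and the
suite checks that the two agree on h² (on the same relationship matrix)
within sampling error at h² ∈ {0, 0.4, 0.8}.

**MLMA.**  The association scan fixes (σ²g, σ²e) at the null REML
estimates, whitens by V^(−1/2) via the eigendecomposition, and fits each
SNP by OLS in the whitened space; the Wald statistic β̂²/SE² is referred
to χ²₁ and SNPs below 5×10⁻⁸ are flagged.  Variance components are
estimated once, not per SNP, and no leave-one-chromosome-out correction is
applied (the scanned panel is the simulated genotyped panel; with causal
SNPs excluded the scan is null-calibrated, λ_GC ≈ 1).  Missing dosages
are mean-imputed per SNP for the scan only; zero-variance SNPs are skipped
with a warning.

## Pipeline

`run_pipeline` chains the stages: cohort → two heritable latent variables
(default h² 0.30 for lumen radius, 0.40 for peak velocity, with covariate
effects on sex/age/BMI/hypertension) → per-subject cines → metrics →
stepwise adjustment → QC (a random ~10% of members are marked ungenotyped,
so SNP-based sample sizes are smaller than pedigree ones) → both
heritability fits per trait → MLMA for configured traits.  Output is a
per-trait summary (trait, method, P, h² %, n) plus a manifest with the
config hash, every derived stage seed, and the turbulence-threshold
fraction.  All writers are atomic (write-then-rename); any stage error
aborts with the stage name.  All randomness derives from the single config
seed via `numpy.random.SeedSequence` spawning.

## Problem sizes and test design

The simulation experiments in the test suite use 108 families
(~340 phenotyped), 2,000-SNP panels for recovery experiments and a
20,000-SNP panel for GWAS null calibration, 200 replicate cohorts for
recovery means, and 500 replicate cohorts for null LRT calibration —
enough that Monte-Carlo error is small against the stated acceptance
bands, while the full suite completes in a couple of minutes.  Likelihood
oracles (two-stage dense grid search, exact-integer HWE enumeration,
gene-dropping Monte-Carlo for kinship) are implemented independently in
the tests, never via the code paths they validate.

## Limitations

* No linkage disequilibrium, no imputation, no population stratification;
  ancestry checks and PCA are out of scope.
* No dominance or shared-environment variance components — a shared-
  household effect would inflate both estimators here as it does in real
  family designs.
* The U–D independence noted above makes the simulated Re_pm distribution
  wider and higher-mean than a physiological cohort's.
* The pedigree estimator assumes founders are unrelated and cross-family
  kinship is zero; the mixture reference distribution for the LRT is
  asymptotic in the number of families and measurably conservative
  (empirical size ≈0.04 at α = 0.05 with 108 families).
* Venc aliasing, eddy-current artefacts and segmentation error are not
  modelled; pixel noise is the only measurement imperfection.
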