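# Methods

`mrmediate` implements a summary-statistics causal-inference pipeline:
two-sample Mendelian randomization (MR) from instrument selection through
multivariable MR (MVMR) mediation, together with a generator of coupled
synthetic GWAS summary statistics that provides ground truth for every
stage. This note records the models, the numerical conventions, and the
design choices made where the methodology left them open.

## The causal model

Let G_j (j = 1..J) be independent biallelic SNPs instrumenting an exposure
X, with per-allele effects γ_j. A mediator M and outcome Y are linked by
the structural equations

    M = α·X + (δ_k instruments of M) ,   Y = c′·X + b·M + pleiotropy ,

so the total X→Y effect is θ = c′ + α·b, the indirect (mediated) effect is
α·b, and the proportion mediated is 100·α·b/θ. The two-sample design
assumes X, M and Y are measured by GWAS on non-overlapping samples, so the
sampling errors of β̂_Xj, β̂_Mj and β̂_Yj are mutually independent.

MR's validity rests on the three instrumental-variable assumptions:
relevance (γ_j ≠ 0, checked via the F-statistic), independence from
confounders, and exclusion restriction (no path to Y except through X).
Horizontal pleiotropy — a direct SNP→Y effect e_j — violates the third and
is what the Egger intercept and the robust estimators address.

## Estimators

Per-variant **Wald ratio**: β̂_Yj/β̂_Xj with first-order SE σ_Yj/|β̂_Xj|
(exposure-side noise ignored, the usual NOME approximation).

**IVW**: with weights w_j = β̂²_Xj/σ²_Yj, the estimate is the w-weighted
mean of the ratios, identical to a zero-intercept weighted regression of
β̂_Y on β̂_X. Cochran's Q = Σ w_j(ratio_j − β̂)² on J−1 df measures
heterogeneity. The default flavour is multiplicative random effects: SE =
(Σw)^{−1/2}·max(1, √(Q/(J−1))), which inflates under heterogeneity but
never drops below the fixed-effect SE. The fixed-effect flavour is
available by flag; both are reported because either may correspond to a
published IVW number.

**MR-Egger**: weighted regression of β̂_Y on β̂_X with a free intercept,
weights 1/σ²_Yj, after orienting every pair so β̂_Xj ≥ 0 (negating both
members of a pair leaves the ratio invariant; the orientation is required
for the intercept to be identified). The intercept estimates the mean
directional pleiotropic effect; its t-test on J−2 df is the pleiotropy
diagnostic (p > 0.05 read as no evidence of directional pleiotropy).
Slope/intercept SEs are multiplied by max(1, σ̂) where σ̂² is the weighted
residual mean square — the conventional floor that prevents
under-dispersion from shrinking SEs below the fixed-effect level. The same
floor is used for MVMR.

**Weighted median**: order the ratios, attach normalized inverse-variance
weights, and linearly interpolate the ratio at cumulative weight 0.5 using
midpoint positions p_j = (S_j − w_j/2)/S_J. Consistent when valid
instruments carry > 50% of the weight. Its SE comes from a seeded
parametric bootstrap: β̂_Xj and β̂_Yj are redrawn from
N(β̂_Xj, σ²_Xj), N(β̂_Yj, σ²_Yj) and the point estimate recomputed
(default 1000 replicates).

**Simple and weighted mode**: the peak of a Gaussian kernel density over
the ratios, bandwidth 0.9·min(sd, MAD)·J^{−1/5} scaled by a user factor,
kernel weights equal (simple) or inverse-variance (weighted); density is
evaluated on a 512-point grid spanning the ratios ±3 bandwidths.
Consistent when the largest cluster of instruments is valid. Bootstrap SE
as for the median. When the ratios are numerically identical the common
value is returned directly (zero bandwidth is degenerate).

P-values are two-sided normal for IVW, median and modes, and t on J−2 df
for the Egger slope and intercept.

## Instruments and harmonization

Selection thresholds follow common practice for this setting: p < 1e-6
for a primary disease exposure, relaxed to p < 1e-5 for microbial-abundance
exposures whose GWAS rarely reach genome-wide significance; greedy LD
clumping at r² < 0.001 within 10,000 kb. Because bundling a reference
panel would force downloads, LD is supplied as a user-provided pairwise r²
table; absent pairs count as independent (a distance-only mode treats any
within-window pair as linked). Ties in p break lexicographically by
variant id so clumping is order-invariant.

Instrument strength uses F = (R²/k)·((n−k−1)/(1−R²)) with
R² = Σ 2·eaf_j(1−eaf_j)·β̂²_j, the variance-standardised-trait convention
(the convention matters and is stated because summary files rarely say
which scale β is on). F > 10 is the conventional weak-instrument cut.

Harmonization aligns everything to the exposure's effect allele: swapped
codings negate the outcome beta and reflect EAF; strand complements are
resolved before declaring a pair incompatible. Palindromic variants (A/T,
G/C) are kept only when both EAFs are available and lie strictly outside
0.5 ± 0.08 (window configurable, including a drop-all mode), oriented by
whether the frequencies sit on the same side of 0.5; missing EAF on a
palindrome excludes it (conservative). The ±0.08 default is the common
ambiguity window; the exclusion itself is standard, the width a
convention.

## MVMR and mediation

MVMR regresses β̂_Yj on (β̂_X1j, β̂_X2j) with weights 1/σ²_Yj and no
intercept; the coefficient on each exposure is its direct effect
conditional on the other. A second-exposure column that is identically
zero is dropped, reducing the fit exactly to univariable IVW; columns with
|correlation| > 0.999 raise a conditioning error rather than returning
unstable estimates. Conditional instrument strength is not computed; the
per-exposure marginal F is the available diagnostic.

The mediation decomposition reports both routes: the **product** (two-step)
method, indirect = step1 × step2 from the two univariable MRs, is the
default; the **difference** method, total − direct, is reported alongside.
The indirect-effect SE is first-order delta with zero covariance between
the steps — exact for non-overlapping GWAS samples:
se = √(β₁²σ₂² + β₂²σ₁²) (product) or √(σ²_total + σ²_direct)
(difference, an approximation since total and direct share data; stated,
not corrected). The total effect is IVW unless the Egger intercept test
signals pleiotropy (p ≤ 0.05), in which case a significant Egger slope is
adopted; if neither qualifies the result is flagged `no-valid-total` and
the proportion mediated withheld. Proportions outside [0, 100]
(inconsistent mediation, opposing paths) are returned as-is with a flag.

## Screening

The discovery screen runs forward IVW (with Q and Egger-intercept
diagnostics) for every candidate outcome, applies Benjamini–Hochberg FDR
within the forward family, then reverse MR for the survivors (candidate as
exposure at the lenient threshold) with its own BH family; survivors whose
reverse q-value is significant are flagged reverse-causal and removed from
the mediation hand-off. Families are per screen direction, matching
per-analysis correction of a taxon-wide scan. Pairs with fewer than two
harmonizable variants are skipped and logged, never imputed. Without
Steiger-type directionality filtering (out of scope), a genuinely forward
pair can be reverse-flagged when the outcome's strongest SNPs are the
exposure's instruments; the flag is reported, not silently applied.

## Synthetic data

The generator works directly at the summary level — no individual-level
genotypes. True marginal effects follow the structural model above;
estimates add Gaussian noise with SE 1/√(2·maf(1−maf)·n), the standard
approximation for a variance-standardised trait. P-values come from the
Wald z. Defaults encode the scenario the package's validation runs on:
J = 50 instruments per trait with γ, δ ~ U(0.05, 0.15), MAF ~ U(0.05,
0.45), n = 50,000 per GWAS, α = −0.2, b = −0.3, c′ = 0.1 (total 0.16,
proportion mediated 37.5%) — effect sizes chosen as typical of
well-powered GWAS instruments, since real instrument–exposure magnitudes
vary by orders of magnitude across traits. Pleiotropy is injected on the
outcome betas of the exposure instruments, with a correlation knob against
γ for InSIDE-violating scenarios, and an overlap knob correlates exposure
and outcome sampling noise when the two-sample assumption is to be broken
deliberately.

Mediator-specific instruments (the δ block) are part of the design: with
instruments acting only through X, β_M = αγ is exactly proportional to
β_X = γ, MVMR's design matrix is singular and the mediator→outcome step
unidentified. Real microbiome GWAS instruments are likewise not
instruments of the upstream disorder, so the block also makes the
simulation more faithful.

Planted complications: a requested fraction of variants gets palindromic
allele pairs, and a fraction of the mediator/outcome records has its
allele coding swapped (beta negated, EAF reflected), so harmonization is
exercised rather than bypassed.

What the generator does **not** emulate: LD structure between instruments
(SNPs are placed ≥ 20 Mb apart), realistic allele-frequency spectra,
binary-trait liability scale, winner's-curse selection of instruments, and
population stratification. Passing recovery tests therefore demonstrate
correctness of the estimators under the stated model, not robustness to
those real-data pathologies.

The cohort generator draws per-group Gaussians and categoricals from
specified marginals; its default specification mirrors a large population
biobank contrasting a small neurodevelopmental-disorder case group
(n = 232) against ~210k controls (cases: more cheese and oily fish, less
fiber, calcium and fruit, male-skewed, more deprived). It models marginals
only — no within-subject correlation between diet variables.

## Cross-sectional layer

Continuous case/control contrasts use the Mann–Whitney U test (exact
enumeration below 20 per group without cross-group ties, tie- and
continuity-corrected normal approximation otherwise); categorical
contrasts use the Pearson chi-square statistic with an optional seeded
Monte-Carlo p-value from random tables with fixed margins (Patefield
sampling) — a literal exact multivariate test is intractable at biobank
margins, a stated divergence from "exact chi-square" labels. The matched
sensitivity analysis is 1:1 greedy propensity matching without
replacement: logistic propensity on the chosen covariates,
nearest-neighbour on the logit with a 0.2·SD(logit) caliper, cases visited
in descending propensity (both caliper and order are conventions, stated
because they are rarely printed).

## Validation sizes and numerical choices

The statistical acceptance checks run at: 200 triangle replicates for
parameter recovery (2 Monte-Carlo-SE bands around θ = 0.16, c′ = 0.10 and
37.5% mediated), 1,000 null replicates for IVW type-I error ([0.03,
0.07]), 200 null screens of 211 outcomes for realized FDR, 400 balanced-
pleiotropy replicates for the Egger intercept's nominal 5% rejection, and
500 replicates for 92–98% delta-interval coverage. Oracle equivalence
(IVW vs an independent weighted mean) is asserted at 1e-10, the MVMR
reduction at 1e-8. Bootstrap SEs default to 1,000 replicates seeded from
the pipeline configuration. Summary tables round-trip floats at 10
significant digits with `NA` as the missing token.

Known limitations: no proxy-SNP lookup for variants missing in the
outcome; no MR-PRESSO/contamination-mixture estimators; no LD computation
from a reference panel; no sample-overlap correction beyond the simulation
knob; the difference-method SE ignores the total–direct covariance.
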