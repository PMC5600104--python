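# Methods

## Two-sample MR estimators

For each harmonized SNP j with exposure effect β_x(j) (cups of coffee/day per
effect allele) and outcome effect β_y(j) (cigarettes/day or SD-cotinine per
allele), the Wald ratio is β_y/β_x. The default delta-method SE is first
order, se = |se_y/β_x|, which ignores exposure-side uncertainty; the
second-order form sqrt(se_y²/β_x² + β_y²·se_x²/β_x⁴) is available via
`order="second"`. First order is the default because consortium exposure SEs
are an order of magnitude smaller than outcome SEs here, and the first-order
weights reproduce the fixture estimates to rounding precision.

Fixed-effects IVW combines ratios with weights w = se⁻²: estimate
Σwr/Σw, SE (Σw)^(−1/2). All intervals are estimate ± 1.96·SE and p-values
are two-sided normal — no t-correction, consistent with the interval
convention. No heterogeneity statistic is computed (deliberately out of
scope; see Limitations).

The weighted median sorts ratios, forms normalized cumulative mid-weights
p_j = (Σ_{i≤j} w_i − w_j/2)/Σw_i, and interpolates linearly at p = 0.5;
outside [p_1, p_m] it clamps to the extreme ratio. Its SE comes from a
parametric bootstrap (default 1000 replicates): each replicate redraws
ratio*_j ~ N(ratio_j, se_j) and recomputes the weighted median; the SE is
the SD across replicates. The seed is mandatory — there is no wall-clock
seeding anywhere in the package. The estimator is consistent when at least
half the total weight comes from valid instruments, which is why it serves
as the pleiotropy sensitivity analysis.

Degenerate inputs are errors, not silently filtered: β_x = 0 raises, ratios
are never winsorized, and an empty estimate list raises.

## Harmonization and LD pruning

Both summary sources must express effects on the same allele. Matching
effect/other alleles are kept; swapped labels flip the outcome beta sign;
anything else (a genuine allele mismatch) is an error naming the SNP.
Palindromic SNPs (A/T, C/G) are strand-ambiguous without frequency
information; the default policy rejects them ("strict"), and an "allow"
policy assumes a shared strand. None of the eight instrument SNPs is
palindromic, so frequency-based resolution is not implemented.

LD pruning removes one member of each pair with r² at or above the
threshold, chosen uniformly at random from an explicit seed; pairs are
visited in sorted-snp_id order so the random stream — and therefore the
retained set — is reproducible. The canonical instrument models are fixed
SNP lists (8-SNP ⊃ 6-SNP ⊃ 2-SNP, the 2-SNP model being the
caffeine-metabolism loci AHR and CYP1A1).

## One-sample MR

The genetic risk score is score_i = Σ_j w_j·dosage_ij with *external*
per-allele weights (the exposure GWAS betas); instrument strength is the
squared t-statistic of the score in a covariate-adjusted regression of
exposure on score, with incremental R². In contrast, the per-SNP Wald ratios
use *in-cohort* regressions of exposure and outcome on dosage — the two
uses are deliberately distinct. All individual-level regressions use HC3
sandwich standard errors (small-sample leverage-corrected), the common
choice when residuals are non-normal. The analysis-sample filter keeps
individuals with exposure > 0 and a truthy smoker flag. SNPs whose
in-cohort exposure effect falls below a tolerance (default 1e−8) are
excluded with a logged warning rather than producing exploding ratios.

## Power

Power for detecting causal effect β with an instrument explaining R² of
exposure variance in n individuals: standardize b = β·σx/σy, form
NCP = n·R²·b², and evaluate Φ(√NCP − z_{1−α/2}) + Φ(−√NCP − z_{1−α/2}).
The far-tail term makes the size exactly α at β = 0. Defaults σx = 2
cups/day and σy = 8.5 cigarettes/day describe the biobank-scale smoking
sample; with n = 8072 and R² ∈ [0.005, 0.01] the formula gives 61–89% power
to detect β = 1.5. The library reports fractions; the CLI prints whole
percent.

## Enzyme kinetics

All four classical reversible-inhibition types are one rate law,
v = Vmax·S/(Km(1 + I/Ki_c) + S(1 + I/Ki_u)): competitive (Ki_u = ∞),
uncompetitive (Ki_c = ∞), noncompetitive (Ki_c = Ki_u), mixed (both finite,
unequal). Closed-form plot geometry drives estimation and classification:

- Dixon lines (1/v vs I per substrate level) intersect at
  (−Ki_c, (1 − Ki_c/Ki_u)/Vmax); parallel lines mean no competitive
  component.
- Cornish–Bowden lines (S/v vs I) intersect at
  (−Ki_u, Km(1 − Ki_u/Ki_c)/Vmax); parallel lines mean no uncompetitive
  component, and an intersection on the I-axis means Ki_c = Ki_u.

The Ki of record is −(median of pairwise intersection abscissae), robust to
unequal noise across substrate levels; a direct nonlinear fit of the rate
law is provided as a cross-check only. Line fits are plain unweighted OLS,
mirroring graphical laboratory practice.

**Parallel-line decision.** A family of lines is "parallel" when the
relative slope spread is below 0.02 (exact-data contract) or a weighted
chi-square test on the per-line slopes cannot reject a common slope at
α = 0.01. The slope SEs feeding that test are HC3 sandwich SEs: under
constant-CV velocity noise the transformed responses 1/v and S/v are
strongly heteroscedastic, and classical OLS slope SEs are biased low enough
to make genuinely parallel families appear to intersect. The
noncompetitive-vs-mixed decision compares the Cornish–Bowden intersection
ordinate to zero at 0.3× the mean |intercept| — mixed inhibition with
Ki_u/Ki_c far from 1 puts the ordinate at the same order as the intercepts,
while its sampling noise is an order smaller. Both parallel → verdict
"undetermined" with diagnostics, never an exception.

**Pre-incubation test.** Mechanism-based (irreversible) inhibitors are
activated by the enzyme during pre-incubation and inactivate it, so percent
activity remaining, 100·v(I)/v(0), drops in the pre-incubated arm. The test
is a one-sided paired t-test across the matched (substrate, inhibitor > 0)
grid at α = 0.05; a pre-incubated arm that is equal or *higher* is
"not-mechanism-based" by the one-sided direction contract. In the
simulator, the inactivation multiplier applies only to wells that contain
inhibitor: pre-incubating without inhibitor cannot inactivate, and a global
multiplier would cancel out of the percent-activity normalization entirely.

**Fractional inhibition.** At physiological nicotine concentrations (far
below the CYP2A6 Km) competitive inhibition reduces turnover by
I/(I + Ki); with a substrate concentration supplied the exact competitive
fraction 1 − v(S,I)/v(S,0) is used instead. Unit conversion is
μM = 1000·(mg/l)/MW with MW 180.16 g/mol for caffeic acid; note that
1.28 mg/l converts to 7.10 μM by this arithmetic, 0.02 μM below the 7.12 μM
figure circulating for that intake level — the package reports its own
conversion.

## Synthetic-data generators

Cohorts follow linear structural equations: independent Hardy–Weinberg
dosages (an optional Gaussian-copula mode adds exchangeable LD solely to
exercise pruning), a standard-normal confounder U, exposure
X = μx + Σγ·dosage + c_x·U + ε_x and outcome Y = μy + β·X + c_y·U + ε_y.
The observational Y-on-X slope is biased by c_x·c_y/Var(X) — recorded in
`true_params` and verified by test. Defaults describe the smoking/coffee
setting: n = 8072, per-allele effects 0.03–0.09 cups/day, exposure SD 2
around a mean of 3 cups/day, outcome SD 8.5 around 15 cigarettes/day, and
confounding (c_x = 0.6, c_y = 3.0, Var(X) = 4) that produces an
observational slope of +0.45 cigarettes/day per cup/day over the causal
effect. Effect-allele frequencies (0.20–0.60) are plausible European values
chosen once, as the source tables do not print them. Phenotypes are
continuous by default; an optional flag rounds exposure to whole cups.

Two-sample tables come from two *independent* cohorts (exposure betas from
one, outcome betas from the other) by per-SNP simple regression; an
allele-swap option randomly relabels outcome alleles to exercise
harmonization. Kinetic velocities are rate-law values times
LogNormal(0, cv) noise — laboratory velocity errors are scale-proportional.
All generators are bit-reproducible under their seeds.

**What the generators do not emulate:** selection effects, genotyping
error, population stratification or relatedness in cohorts; time-courses,
enzyme depletion or analytical-chemistry artefacts in assays. Passing tests
demonstrate estimator correctness under the stated models, not robustness
to those real-data pathologies.

## Problem sizes in the test suite

Coverage of the IVW interval is checked at consortium-scale samples
(30 000/38 000 per arm, 100 replicates) under the null — where IVW coverage
is exactly nominal conditional on the exposure-arm betas, so the
weak-instrument regime of realistic per-allele effects is safe for this
check. Parameter-recovery checks use deliberately strong instruments
(4× per-allele effects, n = 100 000 per sample) so that weak-instrument
attenuation (~F/(F+1)) is negligible against the ±0.15 recovery band.
Classifier round-trips run 200 replicates per inhibition type on a
4-substrate × 4-inhibitor triplicate design at 5% CV — the standard
enzymology layout for type determination — and Ki recovery uses the
2-substrate design at the same noise. The full suite runs in well under a
minute on one core.

## Known limitations

- No MR-Egger, modal estimators, Cochran's Q, or random-effects
  meta-analysis; the weighted median is the only pleiotropy-robustness
  check.
- First-order Wald SEs understate uncertainty when exposure betas are
  imprecise; use `order="second"` in that regime.
- Dixon/Cornish–Bowden linearizations are noise-amplifying at high
  inhibition (small v); the nonlinear cross-check fit is steadier there but
  is intentionally not the Ki of record.
- The palindromic-SNP policy cannot rescue strand-ambiguous variants; they
  must be resolved upstream or dropped.
- The one-sample pipeline assumes complete dosage data; real-data
  missingness is limited to per-SNP mean imputation
  (`impute_mean_dosages` + the cohort's `imputed` flag).
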