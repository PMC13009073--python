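# Methods

This note documents the statistical procedures the package implements, the
choices made where a convention had to be fixed, what the synthetic-data
generator does and does not emulate, and known limitations.

## Study design and data model

The target design is a two-group cross-sectional cohort: a binary outcome
(0 = control, 1 = case; the motivating application is euthyroid vs
hyperthyroid cats, 19 + 16 = 35 animals) observed with (a) an untargeted
serum metabolome delivered as a samples × features peak-height matrix
(~389 features, arbitrary units, no missing values — any imputation is an
explicit step) and (b) a targeted urinary panel of 14 parabens and phthalate
metabolites with analyte-specific limits of quantitation (LOQ) and urine
creatinine per sample for dilution adjustment.

A `FeatureTable` carries a processing-stage tag that advances monotonically
`raw → blank_filtered → mtic → log → pareto`; every operation validates the
stage of its input, so the chain cannot be applied out of order or twice.

## Preprocessing

**Blank filter.** Feature *j* is removed when `max_i(x_ij) / blank_j < 10`.
The rule removes strictly-below ratios (a ratio of exactly 10 is kept). A
feature with blank average 0 has an infinite ratio and is kept — absence
from the blank is the cleanest possible pass. The filter is idempotent.

**mTIC normalization.** Each value is divided by its sample's summed
intensity over the annotated ("known") features, so each sample afterwards
sums to exactly 1 over that set. Whether the divisor should use annotated
features only or all features is ambiguous in practice; both are supported
(`annotated_ids=...` vs `all_features=True`), annotated-only being the
default interpretation of a *metabolite* TIC.

**Log transform.** `y = ln(x + 1)`, natural log. The base matters: the
fold-change convention below divides a log-mean difference by ln 2, which
yields a base-2 exponent only if the transform is the natural log. The +1
offset keeps zero intensities finite but biases recovered effects toward
zero when intensities are small relative to 1; with raw peak heights on the
order of 10⁵ the bias is negligible, but after mTIC rescaling (values ≈
1/p) the transform is nearly linear. This interaction is a property of the
convention chain itself, faithfully implemented and visible in the
package's own simulations.

**Pareto scaling.** Per feature, `(y − mean) / sqrt(sd)` with the sample
standard deviation (n − 1 denominator; conventional for small-n omics).
Zero-variance features cannot be scaled; they are set to all-zero and
reported via a warning list. The per-feature mean and SD are stored on the
output so downstream consumers can invert the affine map.

## Differential abundance

Per feature, a classical equal-variance one-way ANOVA between the two
groups (df1 = 1, df2 = n − 2); with two groups F equals the squared pooled
t statistic. Welch correction is deliberately not applied — the procedure
mirrors classical ANOVA macros, and no heteroscedasticity correction is
part of the specification. Because the Pareto map is affine per feature, F
is identical whether computed on the log or Pareto stage (asserted in
tests); group means are always reported on the log(value+1) scale by
inverting the stored Pareto parameters when needed.

Zero within-group variance is handled by convention: p = 0 if the group
means differ, p = 1 otherwise, with a warning.

**Fold changes.** With `d = mean_log_case − mean_log_control`:
`FC = exp(d)` and `L2FC = d / ln 2`, so `FC = 2^L2FC` identically and an
L2FC of 1 is a doubling. Because means are taken on the log scale, FC is a
ratio of (shifted) geometric means — a known bias relative to
arithmetic-mean ratios for near-zero intensities, documented rather than
corrected.

**BH adjustment.** Default is the standard monotone step-up
`q(i) = min_{j≥i} p(j)·m/j` capped at 1 (delegated to statsmodels). A
non-monotone variant `q(i) = p(i)·m/rank(i)` without the step-up minimum is
also provided because some legacy report tables print exactly those values
for mid-ranked rows; it is never the default. Significance is declared at
adjusted p < 0.05.

## Pathway enrichment

Each of the nine pre-defined pathway groups is tested with a two-sided
Fisher's exact test on `[[sig_in, notsig_in], [sig_out, notsig_out]]`. The
two-sided p-value uses the minimum-likelihood convention — the sum of
hypergeometric probabilities of all tables with the observed margins that
are no more probable than the observed table. Two-sided Fisher conventions
differ across software; this one is stated explicitly, implemented via
scipy, and verified in the tests against exhaustive enumeration for every
2×2 table with total ≤ 12. BH runs across exactly the nine pathway tests.
A pathway containing every feature has no out-group; its p is defined as 1
with a warning.

The package reproduces the published nine-pathway summary from its printed
count triples (shipped as `thyromet/data/table2_counts.csv`): every raw p
matches the printed three decimals and the monotone BH value for the lipid
pathway is 0.160. The printed BH column for mid-ranked rows matches the
non-monotone variant (e.g. 0.509 = 0.16976·9/3), which is why that variant
exists. The two pathways with counts 0/7 and 0/8 have raw p 0.602961 and
0.603258 — distinct values that both legitimately print as 0.603.

## Weighted sub-network analysis

1. Pearson correlation `r` between all feature pairs (Pareto stage;
   zero-variance features excluded with a warning).
2. Signed soft-power adjacency `a_ij = sign(r_ij)·|r_ij|^β` for
   `|r_ij| ≥ τ`, else 0; zero diagonal. Defaults β = 6, τ = 0.1: β = 6 is
   the conventional signed soft-thresholding power and τ = 0.1 removes
   noise-level correlations; both are parameters, and no scale-free-fit
   criterion is applied.
3. TOM on the unsigned weights u = |a| (the overlap formula requires
   non-negative weights; sign information stays in r and a):
   `TOM_ij = (Σ_l u_il·u_lj + u_ij) / (min(k_i,k_j) + 1 − u_ij)`,
   `TOM_ii = 1`, with `k_i = Σ_u u_iu`. The bound 0 ≤ TOM ≤ 1 is asserted
   on random adjacencies and the matrix form is tested against a
   direct-summation oracle.
4. Dissimilarity `1 − TOM`, divided by its maximum off-diagonal entry
   (identity if 0), diagonal forced to 0 — "normalized" is interpreted as
   max-scaling to [0, 1].
5. Ward hierarchical clustering of the dissimilarity (scipy linkage on the
   condensed matrix), cut to exactly k modules (default 5); labels 1..k are
   ordered by decreasing module size, ties broken by the smallest member
   index, so labelings are deterministic and permutation-equivariant.
6. Module eigenmetabolite: the first left-singular (score) vector of the
   column-centered member submatrix, unit-normalized and oriented so its
   mean correlation with member features is positive; `var_explained` is
   the first singular value's share. Single-feature modules fall back to
   the standardized feature with a warning.
7. Association: point-biserial Pearson r with t-based p, and a univariate
   logistic regression of outcome on the eigenmetabolite standardized to
   unit variance (so odds ratios are per SD — the OR scale must be fixed
   somewhere for simulated-recovery targets to be well defined). The fit is
   Newton/IRLS (statsmodels) to gradient norm < 1e-8; Wald χ² = (coef/se)²
   and the 95% CI is exp(coef ± 1.96·se). Perfect separation is detected
   before fitting and reported as a flagged association with an unbounded
   CI instead of a crash.

Outcome coding is fixed at 1 = case throughout, so a module whose
eigenmetabolite rises in cases has r > 0 *and* OR > 1. (Published WSNA
reports sometimes pair a positive r with OR < 1, implying an inverted
coding in one of the two procedures; this implementation keeps the coding
consistent rather than reproducing such an inversion.)

## Multivariate projections

**PCA** is an SVD of the column-centered matrix — covariance PCA of the
already-scaled data, with no re-standardization (the pipeline scales once,
Pareto, then projects). Sign convention: within each component the
largest-magnitude loading entry is positive, making runs bit-reproducible.
`n_components_for_variance` returns the smallest count reaching a
cumulative explained-variance fraction (default rule 0.90). Feature loading
vectors over those components are Ward-clustered (default k = 15) to group
features by contribution pattern, and each feature's point-biserial
correlation with the outcome orders the heatmap input within clusters
(most positive to most negative).

**PLS-DA** uses a single centered indicator response (sufficient for two
classes) and extracts components sequentially: weight `w ∝ X_d'y_d`
unit-normalized, scores `t = X_d w`, deflation of X by `t p'` with
`p = X_d't/t't` and of y by `q t` with `q = y_d't/t't`. Per-LV explained
percentages come from the deflation sums of squares (exact identities:
`ΔSSY = q²·t't`, `ΔSSX = t't·p'p`). VIP over the retained LVs is
`VIP_j = sqrt(P·Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a)`, which forces
mean(VIP²) = 1. The first two components are cross-checked against
scikit-learn's NIPALS up to sign in the tests; the package's own
implementation is the one used, since the per-LV variance accounting and
VIP definition must match the formulas above exactly.

## Urinary EDC processing

Values strictly below the analyte LOQ are replaced by LOQ/√2 — the standard
single-value substitution for left-censored biomonitoring data (values at
the LOQ are untouched). Creatinine adjustment converts ng/mL to µg analyte
per g creatinine via `100·value/creatinine(mg/dL)` (ng/mg ≡ µg/g); the ×100
convention is the standard biomonitoring unit choice. Molar indices divide
adjusted concentrations by molar mass (µg/µmol): sum PCP = MBP/222 +
MEP/194; sum DEHP = MECPP/308 + MEHHP/294 + MEOHP/292 + MEHP/278; sum AA
aggregates the anti-androgenic metabolites MBP, MBzP, MiBP, computed on the
molar scale for consistency with the other indices using configurable
masses MBzP = 256 and MiBP = 222 µg/µmol. (sum AA is sometimes reported as
a mass sum; the definitions mapping is a parameter.) Family totals
sum_paraben and sum_phthalate are mass sums in µg/g. A sample missing any
constituent of an index gets NaN for that index, never a silently truncated
sum. All indices are homogeneous of degree 1 in the adjusted
concentrations. Group comparison of EDC analytes reuses the differential
module (log(value+1) + ANOVA + BH), so urinary analytes and serum features
share one inference path.

## Synthetic-data generator

The generator defines the conditions under which the pipeline is validated.

- **Cohort**: 19 controls + 16 cases by default; urine creatinine
  log-normal with geometric mean 80 mg/dL and log-SD 0.5 (typical feline
  urine values).
- **Metabolome**: natural-log intensities
  `z_ij ~ N(base_log_mean + d_j·group_i, Σ)`, exponentiated. Defaults
  `base_log_mean = 11.5` (peak heights ≈ 10⁵ arbitrary units, the order of
  magnitude of untargeted LC-MS peak-height thresholds) and
  `noise_sd = 0.7` (moderate biological + technical log-scale spread).
  Σ is block-exchangeable: constant correlation `within_corr` inside each
  planted module (realized by a shared per-sample standard-normal factor),
  zero between. Block-exchangeable structure was chosen over factor models
  because its empirical moments are analytically checkable (within-module
  mean r ≈ within_corr). Pathway labels (nine groups) are assigned by
  seeded permutation independently of module blocks, except that a
  configurable fraction (default 0.4) of planted-effect features is steered
  into the designated enriched pathway — the mechanism that makes pathway
  enrichment detectable with known truth; a flag aligns pathway and module
  blocks instead.
- **Blank profile**: a seeded random fraction of features receives blank
  averages putting their sample-max ratio in [2, 9) (certain removal at
  threshold 10); the rest get ratios ≥ 200 (certain retention). The
  generator takes the paired feature table because "fails the filter" is
  only defined relative to the table's sample maxima.
- **EDC panel**: per-analyte log-normal concentrations with configurable
  geometric mean/SD and a case-group multiplier; draws below the LOQ are
  flagged censored but retain their true value in the truth object, so
  imputation error is measurable.

Determinism: every generator takes a seed and identical seeds give
bit-identical outputs.

**What the generator does not emulate** — chromatographic drift, batch
effects, heteroscedastic or heavy-tailed noise, missing values,
feature-intensity-dependent variance, correlated pathway/module structure
in real biology, and annotation error. Passing recovery tests therefore
demonstrates correctness of the statistical machinery under its own model
assumptions, not performance on real cohort data.

## Validation sizes and numerical choices

The simulation-based checks use: null calibration at n = 35, 1,000
features, 200 replicates (KS uniformity on one replicate's 1,000 p-values;
BH false-discovery proportion as the across-replicate mean of "any
rejection", which the complete null makes equal to the realized FDP);
module recovery on five 20-feature modules (within_corr 0.8, n = 35, 50
seeds, adjusted Rand index ≥ 0.8); effect recovery with d = 1.0 on 20 of
400 features (noise_sd 0.7, 50 replicates, median mean-L2FC within ±0.15 of
1/ln 2); logistic coverage at n = 500 over 200 replicates; planted-pathway
enrichment at 389 features with the enriched pathway holding 40% of 20
planted effects (100 replicates). These sizes keep each experiment at
seconds of runtime while leaving comfortable Monte-Carlo margins.

Numerical conventions: BH ties take ordinal ranks from a stable sort;
Fisher's minimum-likelihood tie comparison uses a 1 + 1e-9 relative guard
(matching scipy); TOM values are clipped to [0, 1] against floating-point
overshoot; PCA/eigenmetabolite signs follow the deterministic conventions
above; module labels are size-ordered with index tie-breaks. Degenerate
inputs (zero-variance features, zero mTIC divisors, separated outcomes,
all-feature pathways, single-feature modules) produce defined results or
named errors, never silent NaNs.

## Known limitations

- The +1 log offset interacts with mTIC rescaling as described above; when
  absolute fold-change recovery matters, run the differential stage on
  log(raw + 1) intensities (the validation experiments do).
- Only two-group contrasts are supported; no covariates, mixed models, or
  >2-group Tukey paths.
- The network stage fixes the module count k rather than selecting it
  (no dynamic tree cut, module merging, or scale-free-topology fit).
- Published module-level statistics from the motivating study (cluster
  r/OR values, PLS-DA variance percentages, significant-feature counts)
  are functions of the unreleased raw data and are not reproduction
  targets; only the printed enrichment table is recomputable exactly, and
  the remaining claims are validated as statistical properties on
  synthetic data.
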