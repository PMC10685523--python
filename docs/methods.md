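# Methods

## The model

`mr2s` implements two-sample Mendelian randomization (MR) from GWAS
summary statistics. Genetic variants G are used as instrumental variables
for a modifiable exposure X (here, standardized circulating metabolite
levels) against an outcome Y (a binary disease phenotype on the log
odds-ratio scale, or a continuous trait in SD units). For instrument j,
let b_xj (se s_xj) be the per-allele association with the exposure and
b_yj (se s_yj) the association with the outcome, estimated in
non-overlapping samples. Under the instrumental-variable assumptions
(relevance, independence from confounders, and no effect on Y except
through X), each ratio r_j = b_yj / b_xj estimates the causal effect θ.

Estimators, with first-order weights w_j = (b_xj / s_yj)²:

- **Wald ratio** (single instrument): θ̂ = r, se = s_y / |b_x| — the
  first-order delta method with outcome noise only, the usual two-sample
  convention (a second-order term is negligible for strong instruments).
- **IVW**: θ̂ = Σ w_j r_j / Σ w_j, equivalently weighted regression of b_y
  on b_x through the origin. Fixed effects: se = (Σ w_j)^{-1/2}.
  *Multiplicative random effects*: the fixed se is inflated by
  max(1, √(Q/(k−1))), where Q = Σ w_j (r_j − θ̂)² is Cochran's
  heterogeneity statistic. The multiplicative (not additive) form is the
  convention of the TwoSampleMR ecosystem and never deflates below the
  fixed model; the choice is recorded in every output header as an
  assumption.
- **MR-Egger**: weighted least squares of b_y on b_x *with* an intercept,
  weights 1/s_y², instruments oriented so b_x ≥ 0. The slope is consistent
  for θ in the presence of directional pleiotropy provided the InSIDE
  condition holds (pleiotropic effects independent of instrument
  strength); the intercept estimates the average directional pleiotropic
  effect. Standard errors carry the overdispersion factor
  max(1, √(RSS_w/(k−2))) and inference uses t(k−2), appropriate for the
  small instrument counts typical of metabolite MR.
- **Weighted median**: the ratio at cumulative normalized weight 0.5
  (linear interpolation of the ordered r_j at s_j = Σ_{i≤j} w'_i − w'_j/2);
  consistent when valid instruments carry >50% of the weight. The standard
  error is a seeded parametric bootstrap: both betas of every pair are
  perturbed by their standard errors and the point estimate recomputed
  (default 5000 resamples).
- **Weighted mode**: the argmax of a weighted Gaussian kernel density over
  the r_j; bandwidth = bandwidth_factor × 1.4826 × MAD of the ratios
  (factor default 1, recorded in output metadata). Density is evaluated on
  a 512-point grid spanning the ratios ±3 bandwidths; exact ties between
  modes resolve deterministically to the smaller mode value. Bootstrap se
  as for the weighted median. When the MAD is zero (at least half the
  ratios identical) the weighted median is returned.

Confidence intervals are β ± 1.96·se throughout, and printed odds-ratio
CIs are inverted with the same constant (se = (ln CI_high − ln CI_low)/3.92);
using 1.96 rather than 1.959964 matters because the meta-analysis layer
reconstructs 2-decimal printed intervals, and the difference is below
reporting precision.

## Analysis pipeline

Candidate instruments pass a Bonferroni-corrected genome-wide threshold
(default 5×10⁻⁸/102 ≈ 4.9×10⁻¹⁰, the metabolome-adjusted level for 102
tested metabolite signals). Correlated candidates are pruned by greedy
p-value-ordered LD clumping (PLINK convention): candidates are visited in
ascending p (ties broken by chromosome, position, id so the result is
independent of input order) and accepted iff r² < 0.01 with every
already-accepted variant within 10 Mb on the same chromosome. Pairs absent
from a sparse LD table count as r² = 0 with a logged warning. An
exhaustive-enumeration oracle over all pairwise-compatible subsets backs
the greedy rule in the tests.

Instruments absent from an outcome GWAS are replaced by the best proxy
with r² > 0.8 inside a positional window (highest r², ties by distance
then id); with no qualifying proxy the instrument is dropped and logged.
The proxy window is a parameter: published analyses print values from
hundreds of kb up and the package imposes no hard-coded ceiling. Proxy
outcome effects are re-oriented by the sign of the dosage correlation when
the LD table carries it, else flagged for review in the action log — allele
identity alone cannot orient a proxy.

Harmonization aligns each outcome record to the exposure's effect allele:
matching alleles pass through, swapped alleles negate b_y and complement
the allele frequency, and strand-complemented records (A↔T, C↔G) are
complemented before comparison — multi-cohort GWAS sources mix strand
conventions. Palindromic variants (A/T, C/G) default to `drop_all`,
reproducing the common practice of removing them outright; a
`frequency_inference` policy instead orients by which allele is minor on
each side and drops only records where either frequency lies inside the
ambiguity band min(eaf, 1−eaf) > 0.42, for sources that report outcome
frequencies. Pairs and drops partition the instrument set and every action
is recorded per variant.

The method plan is keyed to the harmonized instrument count k: k = 1 →
Wald ratio; 2 ≤ k ≤ 3 → fixed-effects IVW; k ≥ 4 → multiplicative
random-effects IVW with weighted-median and MR-Egger sensitivity analyses
attached. Discovery and replication estimates are combined by fixed-effect
inverse-variance meta-analysis on the log-OR scale, with between-stage
heterogeneity by Cochran's Q. Evidence labels use a Bonferroni band over
the number of exposures analysed (default 20): p < 0.0025 "strong",
0.0025 ≤ p < 0.05 "suggestive". Further stages reuse the machinery:
confounder exclusion (instrument sets minus a supplied id list, with
flags when k falls below method thresholds), conservative analysis
(restriction to biologically/genetically prioritized ids, Wald or
fixed-effects IVW only, not-assessable records when the list is empty),
reverse-direction MR (disease liability as exposure with a configured
instrument list, fixed-effects IVW plus weighted median and mode), and a
continuous outcome reported as SD difference per SD of exposure with no
odds-ratio columns. Stage failures become structured records — a run never
aborts on one exposure.

Instrument strength is reported per variant as F ≈ (b/se)², the standard
single-instrument approximation (F > 10 conventionally "strong"); the
R²-based formula agrees to O(1/n). Explained variance for a standardized
trait is 2p(1−p)b², summed over independent instruments.

## Synthetic study generator

`synthetic_gwas.simulate_two_sample` emulates the standardized-trait
summary-statistics model: allele frequency p_j ~ U(maf_range), true
exposure effect magnitude |b_j| ~ U(effect_range) with random sign
(emulating arbitrary effect-allele coding), direct (pleiotropic) outcome
effect α_j defined per copy of the exposure-increasing allele, true
outcome effect θ·b_j + sign(b_j)·α_j, and observed effects adding
independent Gaussian noise with se = 1/√(2p_j(1−p_j)n) for each sample —
the same conversion used on the ingestion side, so z-scores and p-values
are internally consistent and the selection stage is exercised. Binary
outcomes are generated directly on the log-OR scale; this tests estimator
algebra and calibration without individual-level logistic sampling, at the
cost of ignoring case-control imbalance effects on the noise.

Defaults are sized to the study design the package targets: exposure
sample n = 85,000 (metabolite-GWAS scale), outcome n = 20,000 (small
enough that causal-effect uncertainty is visible at desk scale), k = 10
instruments, |b| ∈ [0.05, 0.15] (per-variant explained variance roughly
0.1–1%, the span seen for amino-acid instruments), θ = 0.35 (an
alanine-like log-OR per SD). Pleiotropy is `none`, `balanced(sd)` (mean
zero, InSIDE holds) or `directional(mean, sd, fraction)`;
`inside_violation` rescales α_j by |b_j|/mean|b|, coupling pleiotropy to
instrument strength. Optional block LD: dosage columns load ρ =
within_r2^(1/4) on a shared block factor, giving pairwise correlation ρ²
and r² ≈ within_r2; columns are linearly rescaled into [0, 2], which
preserves correlations exactly. The LD table feeds the clumping and proxy
stages; the summary-statistic noise itself is drawn independently per
variant, so the generator does not emulate correlated effect estimates
within LD blocks — tests of clumping exercise the selection logic, not
joint sampling of correlated statistics.

What passing synthetic tests do *not* show about real data: no allele
frequency spectrum or LD structure from a reference panel, no sample
overlap between exposure and outcome, no winner's-curse in instrument
discovery, no misclassified outcomes, and binary outcome noise that
ignores the case fraction.

## Calibration experiments

The acceptance surface (`scripts/acceptance.py`, mirrored in the test
suite) recomputes, per run seed:

- the combined alanine odds ratio from the two printed stage estimates
  (deterministic arithmetic);
- the two corrected significance thresholds;
- IVW calibration at default study conditions, 2000 replicates each:
  type-I error of the nominal 5% test under θ = 0, 95% CI coverage under
  θ = 0.35, and the mean of Cochran's Q against its k−1 = 9 degrees of
  freedom;
- estimator robustness with k = 120 instruments, |b| ∈ [0.01, 0.25], and
  a constant directional pleiotropic effect α = 0.15 on 30% of instruments
  (InSIDE holding), 1000 replicates: absolute bias of the weighted median
  versus IVW, and the rate at which the Egger intercept CI excludes zero.
  The instrument count is large here by design: under mixture pleiotropy
  the intercept's t-statistic plateaus near
  0.3α/√(var(α)) · √(k/(1+x̄²/var(b_x))), so reliable (≥80%) detection of
  a 30% directional component needs on the order of a hundred instruments
  — with 10–20 instruments the Egger intercept is severely underpowered,
  which is itself the documented behaviour of the estimator;
- agreement of greedy clumping with the exhaustive oracle on 500 random
  instances of up to 8 candidates.

Problem sizes (2000/1000/500 replicates, k = 10 and 120) keep the whole
surface within about half a minute on one core while leaving Monte-Carlo
error well inside the tolerance bands.

## Numerical choices and edge cases

- Single-instrument IVW returns the Wald ratio object itself, so the k = 1
  reduction is exact to the bit, not merely to rounding.
- Egger base standard errors come from (X'WX)⁻¹ directly, which is finite
  even when the weighted RSS is exactly zero (points on a line).
- Zero bootstrap spread (noise-free inputs) is floored at the smallest
  positive double so the se > 0 contract holds.
- Duplicate variant ids in an input file keep the smallest p-value and log
  the drop; files round-trip bit-for-bit via `float_precision="round_trip"`
  parsing.
- Degenerate cases raise typed errors naming the offending field: zero
  exposure effect (ratio undefined), constant dosage column (correlation
  undefined), k below an estimator's minimum, malformed alleles,
  frequencies outside (0,1).

## Known limitations

- No MR-PRESSO, multivariable MR, or contamination-mixture estimators;
  no additive random-effects IVW.
- Proxy substitution is single-best-proxy; no LD-based imputation of
  missing outcome associations.
- No genome-build liftover, VCF parsing, or reference-panel LD
  computation; LD arrives as a pairwise table or a dosage matrix.
- The bootstrap se for median/mode estimators ignores between-instrument
  correlation (instruments are assumed clumped to approximate
  independence).
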