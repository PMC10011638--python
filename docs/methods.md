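# Methods

## The model

Two-sample Mendelian randomization treats genetic variants as instrumental
variables: if a variant affects the outcome only through the exposure
(no horizontal pleiotropy), the ratio of its outcome association to its
exposure association estimates the causal effect. The package assumes the
standard summary-data model: for instrument *j*,

    β̂x_j ~ N(γ_j, σx_j²),   β̂y_j ~ N(θ·γ_j + α_j, σy_j²),

with γ_j the true instrument–exposure effect, θ the causal effect of
interest and α_j a per-SNP direct (pleiotropic) effect, zero for a valid
instrument. The two samples are assumed non-overlapping, so β̂x and β̂y are
independent. Estimation requires the three core instrumental-variable
assumptions: relevance (γ_j ≠ 0), independence from confounders, and
exclusion restriction (α_j = 0) — the estimators differ in how they relax
the third.

## Estimators and their conventions

**Wald ratio.** θ̂_j = β̂y_j/β̂x_j with the first-order delta-method SE
σy_j/|β̂x_j|. Exposure-side uncertainty is deliberately ignored: this is
the dominant two-sample convention, it makes IVW exactly equal to weighted
least squares of β̂y on β̂x through the origin with weights 1/σy² (an
identity the tests exploit as an independent oracle), and its cost — mild
CI under-coverage when instruments are weak — is quantified by the
recovery simulations below. Single-instrument analyses report only the
Wald ratio (an exposure proxied by one locus, such as a ratio trait driven
by a single deiodinase variant, cannot support regression-based methods).

**IVW.** Fixed-effects SE (Σw)^(−1/2); the random-effects flavor is
*multiplicative*: SE inflated by max(1, √(Q/(J−1))). The floor at 1 means
RE can never be more precise than FE; the point estimate is identical.
p-values use the standard normal (the choice between normal and t reference
for IVW is genuinely open in the literature; the normal is used and noted
here). The random-effects row is the pipeline's headline estimate because
it is robust to unmodelled balanced pleiotropy and coincides with FE when
instruments are homogeneous.

**MR-Egger.** Weighted regression with a free intercept after orienting all
instruments to positive exposure effects (the regression is not
orientation-invariant, so `egger` orients internally). The residual
dispersion is estimated as max(1, RSS_w/(J−2)) — no "super-efficiency"
below the theoretical minimum — and both coefficients use t tests with
J−2 df, matching the dominant published implementations. The slope is
consistent under InSIDE (instrument strength independent of direct
effects); when pleiotropy correlates with strength, the bias moves into
the slope and the intercept test loses power — a documented failure mode,
not something the package can detect.

**Weighted median.** Ratios sorted ascending; with normalized weights w_(j)
the partial sums s_j = Σ_{i≤j} w_(i) − w_(j)/2 define a step function whose
crossing of ½ is linearly interpolated. The SE is a parametric bootstrap:
each ratio redrawn from N(θ̂_j, se_j), weights held fixed, estimate
recomputed n_boot times (default 1000), SE = SD of the replicates. A seed
is mandatory; there is no global random state anywhere in the package.

**Penalized IVW.** Each SNP's heterogeneity contribution
q_j = w_j(θ̂_j − θ̂_IVW)² is referred to χ²₁; weights become
w_j·min(1, 20·p_j). The constant 20 follows the established
penalized-weights convention. The pipeline adds this row automatically when
Cochran's Q has p < 0.05, mirroring how heterogeneous few-instrument
analyses (e.g. antibody traits) are conventionally handled.

## Sensitivity suite

Cochran's Q (df J−1) measures dispersion of the ratios about the IVW
estimate; Rücker's Q (df J−2) the dispersion about the Egger fit. The
intercept can only absorb weighted residual, so Q_Rücker ≤ Q_Cochran on
every dataset — asserted as an invariant. Heterogeneity is declared at
p < 0.05.

**MR-PRESSO.** The observed statistic is the inverse-variance-weighted
residual sum of squares in which each SNP's expected outcome effect comes
from the IVW slope fitted *without* that SNP. The reference distribution
is simulated: n_sim datasets with β̂x* ~ N(β̂x, σx) and
β̂y* ~ N(θ̂₋ⱼ·β̂x_j, σy) (the no-pleiotropy model), the same leave-one-out
statistic recomputed on each. The weighting of the RSS is left implicit in
the original description; this implementation weights residuals by 1/σy²,
and because the null simulation uses the identical statistic the empirical
p-values are valid regardless of that choice. Global p is the exceedance
probability with (count+1)/(n_sim+1) smoothing (floor 1/(n_sim+1), never
zero). Per-SNP outlier tests compare each observed weighted squared
residual against its simulated distribution and flag at a
Bonferroni-adjusted α (default 0.05/J). The distortion test compares the
IVW shift from removing the flagged set against the simulated shift from
removing equally many randomly chosen instruments (two-sided, smoothed);
it is reported as not-applicable when nothing is flagged. Defaults
n_sim = 1000, α = 0.05. The pipeline removes flagged outliers once, before
the estimator suite, and retains both pre- and post-removal IVW estimates —
so reported instrument counts reflect attrition from both LD screening and
outlier removal, and the provenance log decomposes it.

**Leave-one-out** refits IVW-RE J times, each omitting one instrument, and
flags entries whose 95% CI reading (sign and whether zero is excluded)
disagrees with the full-set conclusion. **Funnel data** emits (ratio,
precision) coordinates only; symmetry is assessed visually, so no statistic
is computed.

## Instrument selection

Genome-wide significance filtering uses strict inequality p < 5×10⁻⁸.
Clumping is greedy: the smallest-p remaining candidate becomes an index
SNP and removes same-chromosome candidates within the window
(|Δpos| ≤ window_kb·1000, default 10,000 kb) whose r² with it is ≥ the
threshold (default 0.001). Ties break by position then rsid, making the
result independent of input row order. LD is an explicit input — a
delimited r² matrix — because the package performs no genotype
computation and bundles no reference panel; with no matrix supplied,
absent pairs are treated as r² = 0 with a warning (appropriate for
simulated independent instruments, conservative for real data, and
surfaced in the run header). The F statistic β̂x²/σx² is always reported
as a min–max range; the default f_min = 0 screens nothing, reflecting the
common practice of screening by inspection rather than exclusion.

## Harmonization

Outcome records are aligned to each exposure instrument's effect allele:
direct match kept; swapped alleles negate β̂y and complement the
frequency; strand-complemented alleles are complemented and re-evaluated.
Palindromic variants (A/T, C/G) are oriented by allele frequency and kept
only when both frequencies lie outside 0.5 ± 0.08 and their orientation is
consistent; the 0.08 band is the widely used conservative convention.
Every failure becomes a dropped record with a machine-readable reason
(missing_in_outcome, palindromic_ambiguous, incompatible_alleles) rather
than an exception, and the audit log preserves the full decision trail.
Duplicate outcome rsids resolve to the smaller SE at read time.

## Synthetic data

The generator draws maf ~ U(maf_low, maf_high) and sets
σ = 1/√(2·maf(1−maf)·n), the SE of a per-allele regression coefficient for
a standardized continuous trait; binary outcomes reuse the formula with an
effective sample size on the log-odds scale (a deliberate simplification —
adequate for validating estimator behavior, not a case-control power
model). Instrument strengths are set via target F statistics drawn
log-uniformly on [30, 500], spanning the weak-to-strong range reported for
real thyroid-trait instruments. Defaults describe a well-powered study:
J = 50, θ = 0.3, n_x = 70,000, n_y = 50,000, maf ∈ [0.1, 0.4], 20%
palindromic variants, no pleiotropy. Balanced pleiotropy simulations use
α_j ~ N(0, 0.005), comparable to the outcome SEs these sample sizes imply.

What the generator does *not* emulate: LD between instruments (identity by
default; block matrices can be attached), winner's-curse selection of
instruments in the exposure GWAS, sample overlap between the two GWAS,
allele-frequency differences between cohorts, and case-control ascertainment.
Passing recovery tests therefore demonstrates correctness of the estimators
under the stated model, not robustness to those real-data complications.

Four canned regimes (`study_fixture`) mirror the instrument profiles of a
published thyroid-function analysis suite: 61 candidates / 39 significant
with a binary outcome (OR ≈ 1.44 design value), 31/10 with a continuous
outcome, a single strong instrument, and 5/4 with pervasive balanced
heterogeneity (alternating ±2-SE direct effects) calibrated so that
heterogeneity survives outlier removal and triggers the penalized-IVW
path. Candidates designed to pass the significance filter get target
F ∈ [100, 580]; the rest F ∈ [1, 4], so the survivor counts are stable
across seeds.

## Numerical and design choices

- 95% CIs are estimate ± 1.96·SE on the linear scale, exponentiated for
  binary outcomes; `or = exp(estimate)` holds exactly in every report row.
- p-values of exactly 0 in input files are clamped to the smallest positive
  normal float with a warning (log-scale diagnostics need positivity).
- Weighted-median interpolation at the boundary (first or last ratio
  carrying the crossing) returns that ratio.
- Zero exposure effect makes the Wald ratio a hard error; harmonization
  never produces one because β̂x comes from genome-wide-significant records.
- All stochastic components (weighted-median bootstrap, MR-PRESSO,
  generators) take explicit seeds through `numpy.random.default_rng`;
  reports are byte-identical across re-runs.

## Validation scale

The shipped validation (tests and `scripts/acceptance.py`) uses 100 random
instances for the oracle-equivalence checks, 500 replicates per θ for bias
and coverage, 2000 replicates for the intercept test's type-I error, and
n_sim = 1000 for MR-PRESSO — sizes at which the Monte-Carlo error of each
checked quantity is comfortably below its acceptance band and the whole
suite runs in seconds on one CPU.

## Known limitations

No mode-based estimators, MR-RAPS, multivariable MR, Steiger filtering or
proxy-SNP lookup; no LD computation from genotypes; no remote data
fetching. The Egger slope's InSIDE sensitivity and the first-order Wald SE
are inherent to the chosen conventions and documented above rather than
worked around.
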