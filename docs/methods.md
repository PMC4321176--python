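# Methods

## Study design and data model

The pipeline analyzes a *matched* two-tissue design: every subject
contributes one sample per tissue, and both tissues are measured on the same
probe panel. The in-memory containers are a `BetaMatrix` (probe x sample
DataFrame of methylation fractions plus an optional detection p-value
matrix) per tissue, and a `MatchedDataset` holding the two matrices aligned
by probe and subject, a probe annotation table and a sample sheet. Matching
removes genetic background and environment as confounders of between-tissue
comparisons; every between-tissue statistic in the package is paired.

All file I/O is tab-separated UTF-8 with `NA` for missing values and floats
printed at 10 significant digits, so repeated writes are byte-identical and
read(write(x)) preserves values to that precision.

## Quality control

Probe filters (all evaluated per tissue; a probe failing in either tissue is
dropped from both, since downstream statistics are matched):

1. SNP-overlapping probes (annotation flag);
2. sex-chromosome probes (chromosome in {X, Y}, case-insensitive, with or
   without a `chr` prefix) — removed because mixed-sex cohorts otherwise
   confound methylation with sex;
3. polymorphic-CpG probes (annotation flag);
4. probes with β = 0 in more than `n_subjects − 2` subjects (zero-heavy
   probes measure nothing); the count generalizes the ">23 of 25" behaviour
   to other cohort sizes;
5. probes whose detection p-value exceeds 0.05 in more than 3 subjects
   (strict inequality: a probe with exactly 3 failures survives). The
   detection threshold is configurable because array platforms differ.

After filtering, remaining exact-zero betas are replaced by the smallest
strictly positive beta observed anywhere in that tissue's matrix — a floor
imputation that makes the logit transform finite without disturbing any
other value. `replace_zeros` is idempotent.

## Tissue specificity

- **Paired t-test** per probe on differences d = β_B − β_A:
  t = mean(d)/(sd(d)/√n), df = n − 1, two-tailed. Working on differences
  needs no equal-variance assumption. Degenerate inputs are handled
  explicitly: all-zero differences give (t = 0, p = 1); constant nonzero
  differences give signed infinite t with the smallest positive double as p,
  so such probes sort first instead of propagating NaN.
- **BH adjustment** (step-up; statsmodels) with significance at adjusted
  p < 0.001.
- **Effect classes**: tissue-specific = adjusted p < 0.001 and |Δβ| > 0.2;
  highly tissue-specific additionally |Δβ| > 0.4. Thresholds are arguments.
- **Methylation categories**: hypo (< 0.20), heterogeneous ([0.20, 0.80],
  both boundaries inside), hyper (> 0.80), computed on per-tissue mean beta.
- **ICC (one-way consistency, k = 2)**: from the one-way ANOVA table with
  subject as the grouping factor,
  `ICC = (MS_between_subjects − MS_within_subjects) /
  (MS_between_subjects + MS_within_subjects)`
  with df n − 1 and n. Bounded in [−1, 1] for two measurements; −1 means the
  between-tissue difference dominates, +1 the between-subject difference.
  Zero total variance returns NaN (undefined) rather than a silent value.
- **Sample-wise correlations**: Pearson over probes for all n(n−1)/2 sample
  pairs within each tissue; between tissues the default pairs each subject
  with itself (`matched`), with an `all`-pairs mode available because either
  convention is defensible; the mode is recorded in the output. Per-class
  means are computed on probe subsets (HC/IC/LC/uncategorized).
- **Global shift**: subject mean betas per tissue compared by the exact
  two-tailed Wilcoxon signed-rank test (zero differences dropped, ties fall
  back to the normal approximation). At n = 25 the smallest attainable
  two-tailed exact p is 2/2²⁵ ≈ 6.0e-8.

## CpG-density classes

From island metrics, strict inequalities, high-density rule tested first:
HC if GC > 0.55 and obs/exp CpG > 0.75 and length > 500 bp; else IC if
GC > 0.50 and obs/exp > 0.48 and length > 200 bp; else LC. Probes with
missing metrics and no preassigned class are `uncategorized`: retained in
all analyses and counted in enrichment populations, but never used as a test
category.

## Differential variability

- **Transform**: the default variance-stabilizer is the M-value,
  log2(β/(1−β)), which undoes the variance truncation of beta values near 0
  and 1; arcsine-square-root is available as an alternate, and the choice is
  recorded in output metadata.
- **Levene test** per probe between the two tissues' transformed values,
  default center = median (Brown–Forsythe), mean-centering by flag. At
  n = 25/group the median-centered variant is conservative (type-I ≈ 4%)
  while the mean-centered classic statistic is near-nominal; the test suite
  documents both. BH-adjusted p < 0.05 is the primary call; the
  unadjusted-p count is also reported.
- **Concordance band**: a probe is `within_band` iff its tissue-B
  transformed-scale variance lies inside [0.8, 1.2] x the tissue-A variance
  (closed interval); a raw-beta-scale mode exists for sensitivity analysis.
  The classification is scale-invariant.
- **Variable loci**: raw-beta SD strictly above 0.1 (or 0.3), because those
  cutoffs are beta-scale magnitudes; transformed-scale variances are also
  emitted.
- **Cross-tissue probe correlation**: Pearson r of the n matched subject
  values across tissues per probe, two-sided p, Storey q. Zero-variance
  probes yield missing r and are excluded from FDR.

## Enrichment

`Hypergeometric(N, K, n)` tails computed via scipy's log-space machinery.
Conventions follow R's `phyper`: enrichment p = P(X > k) (exclusive upper
tail, `lower.tail = FALSE`), depletion p = P(X ≤ k); the two are exact
complements. The scan auto-selects the direction per category by comparing
the observed overlap with its expectation nK/N and flags the degenerate
equality case. No correction is applied across the three density classes by
default (a BH flag exists). Under uniformly drawn subsets the
fixed-direction rejection rate is nominal up to the discreteness of the
distribution, which the calibration tests allow for explicitly.

## Demographic associations

Per tissue and variable: binary variables (sex, ethnicity) use the
two-sided Wilcoxon rank-sum test, exact when the combined n ≤ 50 with no
ties, otherwise the continuity-corrected normal approximation; continuous
variables (age, BMI, alcohol) use two-tailed Pearson correlation with the
t transformation. Effects are the group mean-beta difference (binary) or
the fitted beta difference between the covariate's minimum and maximum
under the least-squares line (continuous), so the "|Δβ| > 5%" filter has a
single meaning. Multiple testing uses Storey's q-value: π₀(λ) estimated on
a λ grid (0.05…0.95), cubic-polynomial smoother evaluated at the largest λ
and clamped to (0, 1]; for fewer than 100 tests a fixed λ = 0.5 keeps small
fixtures deterministic. With π₀ = 1 the q-values equal BH exactly (a tested
identity). Significance is q ≤ 0.05, boundary inclusive. Each scan also
reports p-value-distribution diagnostics — a 20-bin histogram, the fraction
of p < 0.05, and a one-sample KS statistic against uniform — because a
left-skewed raw-p distribution is evidence of association even when no
single probe survives FDR.

## Synthetic cohort generator

The generator emulates the study conditions so that every stage has
planted-truth tests. Defaults: 25 subjects (15 male / 10 female,
18 Caucasian / 7 non-Caucasian, ages 26–45, BMI ~ lognormal clipped to
18–48), 998 clean probes split 21% LC / 14% IC / 50% HC / 15% uncategorized
by largest-remainder allocation.

Values are generated on the M-value scale as
`baseline + subject effect + tissue effect + demographic effect + noise`,
then inverse-transformed and clipped to (1e-6, 1 − 1e-6):

- **Baselines** are drawn from a three-component bimodal mixture (low
  0.03–0.14, mid 0.20–0.80, high 0.86–0.97) with class-dependent weights —
  high-density islands mostly unmethylated (0.78/0.08/0.14), low-density
  contexts more intermediate/high (0.22/0.48/0.30) — chosen so the pooled
  hypo/heterogeneous/hyper fractions land near 60/18/22% and the density
  classes differ in cross-tissue behaviour as in real promoter panels.
- **Tissue-specific probes**: 18% of probes, |Δβ| ~ U(0.2, 0.6) with the
  sign chosen to keep the target mean inside [0.03, 0.97], selection biased
  2x toward LC probes. All probes also get a +0.02 global tissue-B offset.
- **Variance-discordant probes**: 15% of probes with a planted
  transformed-scale variance ratio of exactly 3 or 1/3 (probabilities
  0.6 for 1/3, i.e. tissue A larger), realized by rescaling the deviations
  of whichever tissue the ratio makes more variable.
- **Inter-individual structure**: a per-probe dispersion multiplier
  (lognormal, σ = 0.35) shared across tissues produces the heavy-tailed SD
  distribution real probes show; a subject effect (SD 0.2) shared across
  tissues produces cross-tissue correlation of individual values; tissue A
  carries a 1.6x noise scale so the buccal-like tissue has the larger range
  distribution, as observed in matched cohorts. Independent noise SD is
  0.35 per measurement.
- **Demographic effects**: 50 sex-associated probes (β effect 0.15)
  planted in tissue B only, so tissue A doubles as a within-run null.
- **QC artifacts**: 20 SNP-flagged, 15 sex-chromosome, 10 polymorphic,
  5 zero-heavy (exact zeros in all but one subject) and 5 detection-failing
  probes appended on top of the clean panel (1053 in, 998 surviving QC).

Identical config and seed give byte-identical output. The truth table
records, per probe, the planted tissue effect, variance ratio, associated
variable and artifact type; `truth_recovery_report` scores any pipeline
output against it (sensitivity, specificity, observed false discovery).

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: probe cross-hybridization, batch/plate
effects, genotype-driven methylation (mQTLs), cell-composition
heterogeneity within a tissue, and realistic between-probe correlation
along the genome. Because tissue A's variability excess is modelled as a
global noise scale, the background (non-planted) probes have a true
between-tissue variance ratio of ~0.46 rather than 1; the Levene
truth-recovery metrics therefore count planted discordance only, and the
±20% band classifies most background probes as outside the band — a known
divergence from matched-cohort data, where most probes have similar
variance in both tissues.

## Problem sizes and numerical choices

- Calibration suites use 2,000 null Levene probes, 5,000 null Pearson
  probes, 400 uniform enrichment subsets, and 10-seed null q-value scans;
  recovery suites use 40 generator seeds for the LC-enrichment power check
  and 10 seeds for sex-association recovery. These sizes give binomial /
  KS sampling error well below the asserted margins.
- The Levene-sensitivity acceptance band is not a fixed number: it is
  re-derived in the test from a direct Monte-Carlo oracle of the identical
  procedure (same group sizes, planted ratios, BH correction), and the
  pipeline's sensitivity must fall within mean ± 3 SD of the oracle (with a
  small allowance for the generator's group correlation, which the oracle
  omits).
- Percentages in run summaries are `round-half-up(100·count/total, 1)`
  computed in decimal arithmetic to avoid binary-float rounding surprises.
- p-values of zero are reported as the smallest positive double; NaNs are
  reserved for genuinely undefined quantities and always excluded from FDR
  explicitly.

## Known limitations

- The exact signed-rank test caps at p = 2/2^n; global shifts are
  detectable but their p-values saturate quickly at n = 25.
- The Brown–Forsythe default trades type-I accuracy (conservative at
  n = 25) for robustness to non-normal methylation distributions.
- Storey's smoother needs a few hundred tests to beat the fixed-λ fallback;
  both are exposed.
- Enrichment p-values use a data-selected tail direction; across many
  scans those p-values are not uniform under the null (they concentrate
  below 0.5), which is why the calibration tests fix the direction.
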