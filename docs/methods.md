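# Methods

`purinedelta` implements the statistical core of a comparative
metabolomics study design: given metabolite × sample intensity tables
from two or three groups (species, genotypes, or cell-line classes), it
asks whether individual metabolites, whole pathways, and in particular
de novo purine biosynthesis, differ between the groups — together with
the numeric reductions of the biophysical assays used to characterise
the enzyme ADSL (adenylosuccinate lyase), which catalyses two steps of
de novo purine synthesis (SAICAR→AICAR and SAMP→AMP).

## Preprocessing model

All statistics operate on log-scale intensities. The preprocessing
chain mirrors standard handling of quantified MS tables:

1. **Internal-standard normalization** (`normalize_internal_standard`):
   each value becomes `log10(3000 · value / standard)`, where the
   standard is the per-sample intensity of a spiked compound (e.g.
   ¹³C-sorbitol). The factor 3000 (default, configurable) keeps
   metabolite/standard ratios positive after the log. The standard must
   be detected in every sample; anything else is a hard error naming
   the offending sample.
2. **Missingness filter** (`filter_missingness`): metabolites with
   ≥ 50 % missing entries (default threshold, i.e. detected in fewer
   than half the samples) are dropped. The comparison is `≥` so that
   exactly-half-missing is removed. With a stratifying column the
   fraction is evaluated per stratum and a metabolite is dropped only
   when it fails everywhere; per-tissue analyses subset first (the
   pipeline does this), which is the operative per-stratum rule.
3. **Upper-quartile normalization** (`upper_quartile_normalize`): the
   75th percentile of each sample's detected log intensities is
   subtracted — the log-scale equivalent of dividing linear intensities
   by the upper quartile. The step is idempotent and invariant to
   per-sample constant offsets.
4. **Outlier samples** (`detect_outlier_samples`): PCA on samples
   (complete metabolites only, or mean-imputed); a sample is reported
   when its PC1 or PC2 score lies more than 3 SDs (default) from the
   component mean, in a single pass. Detection and exclusion are
   separate calls — the pipeline excludes what it reports.
5. **Run-order confounding** (`flag_run_order_confounded`): per
   metabolite, a Gaussian-kernel support-vector regression of intensity
   on instrument run order (bandwidth = median pairwise run-order
   distance; intensities z-scored before fitting). Metabolites whose
   fitted trend explains ≥ 30 % of variance (default, configurable) are
   returned for explicit exclusion, not corrected. Constant metabolites
   have R² defined as 0.

## Differential statistics

* `diff_test` — per metabolite, the log fold change is
  `mean(log A) − mean(log B)` over observed values (pairwise deletion;
  no imputation). P-values are two-sided, from Welch's t-test by
  default (a pooled-variance option exists; with "Student's t-test"
  unqualified, Welch is the safer modern default) or the exact-where-
  possible rank-sum test. Metabolites with fewer than 3 observed values
  in either group are skipped. Benjamini–Hochberg adjustment is applied
  across the stratum's tested metabolites on request; the `direction`
  call (up/down/none) gates on the adjusted p when BH is active.
  Degenerate zero-variance metabolites get p = 1 when the group means
  agree.
* `lineage_specific` — a metabolite is focal-specific when both
  focal-vs-outgroup contrasts are significant at α (default 0.05,
  unadjusted) with the same sign while the outgroup–outgroup contrast
  is not. Note the two focal contrasts share the focal samples, so
  their test statistics are correlated (ρ = 0.5 for equal group sizes);
  the null rate of focal-specific calls is therefore
  ≈ 2·Φ₂(z>c, z>c; ρ=0.5)·(1−α) ≈ 0.009 at α = 0.05 — far below α but
  roughly 3.6× the α² one would get from independent calls. Screens
  using this filter should calibrate expectations against the
  correlated null, e.g. with the synthetic generator.
* `cross_stratum_correlation` — Pearson correlation of log fold changes
  over metabolites shared by two result sets (e.g. two tissues), with
  the two-sided p and the intersection size.

## Permutation count test

`permutation_count_test` addresses the screening question "are there
more nominally significant metabolites than label noise produces?".
Group labels are shuffled preserving group sizes; for each of B = 1000
(default) shuffles, the number of metabolites with inner-test p < 0.05
is recomputed with the same vectorised Welch machinery used on the true
labels; eligibility (≥ 3 observed per group) is frozen under the true
labels. The p-value is the add-one estimator
`(1 + #{null ≥ observed}) / (1 + B)`, which cannot return 0. When the
design admits ≤ B distinct assignments the null is enumerated
exhaustively (with the plain ratio; the identity assignment keeps
p ≥ 1/B). Samples are canonicalised by id before shuffling so results
do not depend on input column order.

Two calibration caveats, both verified by simulation and intrinsic to
the procedure rather than to this implementation:

* the p-value is **discrete and conservative**: the count statistic is
  integer-valued, and with 200 metabolites at α_inner = 0.05 its pmf
  peaks near 0.12, so the tie mass makes the add-one p super-uniform
  (empirical KS distance from uniform ≈ 0.14 across null datasets). A
  mid-p variant would be nearly uniform, but the equal-or-greater
  convention is the documented estimator here.
* with many strongly shifted metabolites, shuffles that nearly
  reproduce the true labelling (overlap 9–10 out of 10; about one per
  thousand draws) retain most of the planted signal, so the permutation
  p does not hit its 1/(B+1) floor in every run — at 30/200 metabolites
  shifted 0.4 log10 over 0.2 log10 noise, the floor is reached in ≈ 86 %
  of runs.

## Pathway statistics

* `pathway_cumulative_p` — for each pathway, member metabolites whose
  fold change has the requested sign are aggregated by Fisher's method
  (χ² tail of −2Σln p at 2k df); the cumulative p is reported per
  pathway together with the detected and direction-consistent member
  counts, and `enriched` flags cumulative p < 0.01 (default). "Cumulative
  p-value" admits more than one reading; Fisher's combination over
  direction-consistent members is the default scorer, and a
  hypergeometric over-representation test (direction-consistent members
  vs the detected background) is available via `method="hypergeom"`.
* `pb_vs_rest` — two-sided rank-sum comparison of fold-change
  distributions: purine-biosynthesis-flagged metabolites vs all other
  annotated metabolites, plus the difference of medians. The purine
  flag is data (a curated restrictive metabolite set in the pathway-map
  TSV), not a name match. At least 3 flagged detected metabolites are
  required.
* `direction_binomial` — exact binomial test of the number of decreases
  among n detected members against a fair coin. Sidedness is an
  explicit argument with no default anywhere (CLI included), because
  one-sided and two-sided readings of a decrease tally differ exactly
  by the factor two that decides borderline calls; the one-sided tail
  is taken in the direction of the observed deviation, the two-sided p
  doubles it, capped at 1.

## Biophysical assay computations

* `specific_activity`: least-squares slope of A₂₈₂ vs time, converted
  by Beer–Lambert with ε = 10,000 M⁻¹cm⁻¹ (the adenylosuccinate → AMP
  reaction default), the cuvette/well path length and the reaction
  volume, expressed in nmol·min⁻¹·µg⁻¹ protein. Path length and
  reaction volume are required inputs with no defaults — microplate
  path lengths depend on fill volume, and the unit chain is exposed so
  either volume convention can be reproduced. An optional
  initial-window selector maximises R² over prefixes of ≥ 5 points to
  discard late substrate-depletion curvature.
* `bca_concentration`: linear least squares through the BSA standards
  (0–200 µg/ml), unknown inverted through the fit; out-of-range
  unknowns are flagged as extrapolated.
* `estimate_melting_midpoint`: the CD melt signal is rescaled to
  fraction folded using 3-point edge plateaus (folded = low-temperature
  end, so the estimate is invariant to affine transforms and sign of
  the ellipticity), and the 50 %-folded temperature is located by linear
  interpolation at the first crossing.
* `tetramer_fraction` / `half_dissociation_concentration`: T/(M+T) per
  native-gel lane, and the GdnHCl concentration where the fraction
  crosses ½ by interpolation across lanes.
* `activity_ratio`: single-substrate over mixed-substrate specific
  activity.

## Synthetic data: what it emulates and what it does not

`simulate_intensity_table` draws per-metabolite baselines from a wide
hyperdistribution (log10 mean 3.5, SD 1.0), adds planted per-pathway
group shifts, Gaussian between-sample noise (default SD 0.2 log10
units, roughly a 1.6-fold CV — a free parameter, since real
per-metabolite variances vary), detection dropout (missing completely
at random by default; an intensity-dependent left-censoring mode
exists), smooth run-order drift (sum of 1–3 random sinusoids scaled to
a configurable amplitude, applied to a 10 % metabolite subset), and
globally shifted outlier samples (default 5 between-sample SDs, with
metabolite-level heterogeneity of relative SD 0.5 — a perfectly uniform
shift would be removed exactly by upper-quartile normalization and is
not what degraded or mis-diluted samples look like). Identical design +
seed gives bit-identical tables.

The generator does **not** simulate raw spectra, retention behaviour,
adducts, batch-specific dropout structure, heteroskedastic
per-metabolite variances, or correlated (co-regulated) noise between
metabolites. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated sampling model, not robustness
to every artefact of real MS data.

Default design sizes used across the test suite and the acceptance
script were chosen to mirror the study designs the package targets
(primate tissue panels, mouse genotype cohorts, cell-culture groups)
while staying
desk-scale: two groups of 10 (genotype comparison, 200 metabolites),
three groups of 4 (species comparison), B = 1000 permutations, 50–200
simulation seeds for power/calibration checks.

## Numerical choices and degenerate inputs

* p-values are clipped to (tiny, 1]; zero-variance groups with equal
  means give p = 1 (different means: p = 0).
* Fisher combination rejects p ≤ 0 or > 1; a single p is returned
  unchanged.
* Rank-sum tests fall back to p = 1 when all values are identical.
* The permutation test errors when no metabolite is testable, and
  reduces to exhaustive enumeration (with a warning) on tiny designs.
* Upper-quartile normalization requires ≥ 4 detected values per sample;
  PCA outlier detection requires ≥ 4 samples.
* TSV round-trips preserve float values exactly (repr-precision
  output), missingness as empty cells, and the scale flag as a
  `# scale=` header comment.

## Known limitations

* The lineage filter's null rate and the permutation test's calibration
  caveats above.
* Run-order flagging uses training R² of an SVR; with very short series
  or duplicated run-order values the median-distance bandwidth can
  degenerate (it falls back to 1.0).
* `pb_vs_rest` treats metabolites as exchangeable; correlated
  metabolites within a pathway (shared biosynthetic flux) make the
  rank-sum p anti-conservative on real data.
* No covariate adjustment, mixed models, or batch correction — the
  supported designs are the simple group comparisons described above.
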