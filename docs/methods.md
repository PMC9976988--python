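# Methods

This note documents the statistical procedures, their assumptions, the
default parameters and the deliberate design choices in `taskgrad`,
together with what the synthetic-data experiments do and do not establish.

## Profiling

**Parcel extraction.** `parcel_means` averages finite voxel values per
integer label. β and label grids must match exactly; no resampling is
performed — spatial normalisation is treated as preprocessing and out of
scope. A parcel with no finite voxel becomes missing (NaN) and propagates
as such; all downstream means skip missing values.

**System profiles.** Unweighted means over each system's parcels. The
seven-system scheme is the default; a 17-system table passes through
unchanged (names are labels, not semantics).

**Gradient bins.** "Equal-sized" bins are read as equal parcel
*occupancy*, not equal gradient-value width: parcels are sorted by
gradient value (ties broken by parcel id, with a warning when all values
tie) and cut into `n_bins = 20` contiguous groups whose sizes differ by at
most one, larger groups at the unimodal end. Bin 1 is unimodal/sensory,
bin 20 the transmodal default-mode apex. The sliding-window option widens
each bin's rank range by `overlap_frac · P / (2 n_bins)` ranks per side
(window width ≈ `(1 + overlap_frac) · P / n_bins`). The default is
`overlap_frac = 0`, i.e. plain bin means: the window parameters of prior
descriptions of this approach are not standardised, and a zero-overlap
default makes results exactly reproducible and equal to the binned means.

**Covariate adjustment.** Per column, OLS of the value on [intercept,
age, sex] fitted across *all* subjects pooled over groups; output is the
residual plus the fit at the covariate means, so slopes are removed and
the mean level is preserved. Pooled fitting is the default (matching the
common practice of adjusting before group comparison); per-group fitting
is available behind the ``adjust_per_group`` config flag. Likewise
``bin_mode`` switches the gradient discretisation from equal-occupancy
(default) to equal-value-width bins.
Adjustment is idempotent and its output is exactly orthogonal to the
covariates (both are tested).

A consequence worth knowing: *residualise-then-permute* is mildly
conservative for downstream label-permutation tests, because the realised
alignment between the group labels and the covariates is removed from the
observed contrast but not from permuted ones; the effect grows when
covariates genuinely differ between groups (here: patients' age). The
acceptance script measures this directly (`null_type1_error_adjusted`
versus `null_type1_error`); calibration of the permutation primitive
itself is checked on exchangeable columns, where it is exact.

## Inference

All tests are two-tailed with Monte-Carlo permutation p values
`p = (1 + #{|T*| ≥ |T|}) / (1 + n_perm)`, so `p ≥ 1/(n_perm+1)` and ties
count as exceedances (conservative). Defaults: `n_perm = 10000`,
`fdr_q = 0.05`, `alpha = 0.05`.

- **One-sample** (control effects vs 0; patient Z vs 0): t statistic under
  independent random sign flips of the values. Raw values are flipped, not
  ranks.
- **Two-sample** (FLE vs TLE): pooled-variance t under random reassignment
  of group labels preserving group sizes; Cohen's d (pooled SD, first
  argument minus second) is attached.
- **Deviation mapping:** Z = (Act − μ_CTR)/σ_CTR computed per column from
  the *adjusted* control distribution (adjust first, then standardise);
  σ_CTR uses ddof = 1, so controls scored against themselves have sample
  mean 0 and SD 1. Columns with zero control SD raise upstream.
- **AbC:** the area between two groups' bin-mean curves with unit bin
  width, i.e. the mean absolute difference of the curves; the absolute,
  unsmoothed difference is used. Any positive scaling of the
  integration measure leaves the permutation p unchanged, which is the
  reported quantity. Per-bin two-sample results with BH-FDR across bins
  accompany the global p.
- **Correlations:** both variables residualised on [intercept, nuisance]
  (Spearman: rank first, then residualise — a pragmatic partial-rank
  scheme); the null permutes the y residuals.
- **FDR:** Benjamini–Hochberg step-up (delegated to statsmodels, checked
  in tests against the brute-force definition), applied across systems or
  bins within each comparison family.

**Randomness.** One master seed per invocation; families of columns
derive one independent stream per column from (seed, column index), so
results for a column never depend on which other columns are present.
Fixing the seed fixes every reported number bit-exactly; this is tested
end-to-end on the packaged fixture.

## Quality control and cohort statistics

Subjects with mean framewise displacement strictly greater than 0.5 mm
(threshold configurable) are excluded before any analysis, and each
exclusion is logged. Mean FD is a roster input; the package does not
recompute it from motion parameters.

Demographics tables use Pearson χ² without continuity correction (this is
the statistic that reproduces the published values recomputed in the
acceptance script; Fisher's exact p is provided separately for 2×2
tables), one-way ANOVA — computable from per-group (n, mean, SD)
summaries alone, which is what published tables provide — Kruskal–Wallis
with tie correction, ANCOVA partial F from nested OLS models, and
Bonferroni post-hoc correction (p·m capped at 1). Pairwise deletion is
used for missing data throughout.

## The synthetic generator

The generator emulates the statistical structure of a three-group
task-fMRI study at the parcel level, with defaults mirroring the
published cohort the package's conventions follow: group sizes 52/56/64
(CTR/FLE/TLE), per-group age means and SDs of 34.1 (10.4), 33.4 (10.2)
and 39.2 (10.7) years, female fractions 30/52, 29/56 and 44/64, 200
parcels with seven-system occupancies (31, 35, 26, 24, 13, 26, 45), and
patient clinical covariates (onset age, duration, log seizure frequency,
FBTCS history, days since last seizure) with realistic locations.

Per subject *s*, parcel *p* of system *k*:

    β[s,p] = m_k + δ[group,k]·σ_subj + a_k·(age_s − mean age) + b_k·sex_s
           + u[s,k] + e[s,p]

with `u ~ N(0, σ_subj²)` a subject-by-system random effect shared across
the system's parcels and `e ~ N(0, σ_jitter²)` independent parcel jitter
(defaults σ_subj = 0.1, σ_jitter = 0.08, both in β units). The random
effect is deliberately at the system level so that deltas specified in
subject-SD units survive averaging over a system's parcels and translate
directly into Cohen's d / normative-Z targets; it also induces realistic
within-system correlation (and hence correlation between gradient bins of
the same system — a property the validation experiments must respect when
counting independent replicates).

Default effect magnitudes echo reported healthy-adult task profiles:
frontoparietal/salience activation around 0.08–0.10 β for a fluency-type
contrast, dorsal-attention/control activation 0.20–0.26 β with
default-mode and somatomotor deactivation around −0.08 β for a verbal
working-memory contrast; patient deltas are negative on task-positive
systems (larger in TLE for working memory) and positive on the default
mode (reduced deactivation, larger in FLE). Age/sex confounding is on by
default — patients are sampled slightly younger or older per the group
age parameters, with small age slopes on task-relevant systems — so the
adjustment stage is genuinely exercised. Mean FD is log-normal
(median 0.18 mm, σ_log = 0.5), putting ~2% of subjects above the 0.5 mm
exclusion threshold. Performance scores are a monotone, by default
log-normal (right-skewed) transform of the subject's task-positive signal
plus noise, so rank correlations have something to detect.

The gradient is built as a per-system expected position (visual lowest,
default mode highest) plus Gaussian overlap noise (SD 0.3), making the
transmodal apex essentially pure default mode while mid-gradient systems
interleave. The label volume lays parcels out as 2×2×2-voxel cubes on a
lattice — topologically nothing like a cortex, which is irrelevant here
because all statistics operate on label membership, not geometry.

**What passing tests show — and don't.** The generator has Gaussian
noise, no spatial autocorrelation, no haemodynamics, exact linear
covariate effects and exchangeable subjects within group. Calibration and
recovery results therefore validate the *statistical machinery* under the
assumed model; they do not establish robustness to autocorrelated fMRI
noise, non-linear age effects, lesions or site effects in real data.

## Validation experiment sizes

Chosen for precision per unit runtime on a single CPU: type-I calibration
uses the 7 system columns (mutually independent under the generator) of
600 null cohorts (4200 near-independent replicates; binomial SE ≈ 0.003);
AbC uniformity uses 200 cohorts (one global p each, KS test); deviation
recovery averages 5 cohorts with 200 patients each; detection power uses
60 cohorts at 50 subjects per group with 999 permutations per test.
Measured on these conditions, the injected +0.6 subject-SD deviation is
recovered as mean transmodal Z ≈ 0.56–0.65 and detected (any
default-mode-dominated bin flagged at P_FDR < 0.05 with positive Z) in
~80–88% of cohorts. The detection rate has a structural ceiling: the
normative-Z one-sample t has expectation ≈ δ√n_p but variance
≈ 1 + n_p/n_CTR, because μ_CTR and σ_CTR are estimated from a control
group of the same size; at 50/50 that caps power near 0.85–0.87 at the
BH-corrected threshold regardless of noise scale. A larger normative
control sample is the only remedy — worth knowing when planning a study
around deviation mapping.

## Known limitations

- Profiling operates on parcels (any location-indexed vector), not
  vertices; studies profiling in surface space differ in resolution.
- The pooled adjust-then-permute composition is mildly conservative when
  covariates differ between groups (measured, see above); a
  Freedman–Lane-style scheme would remove this but is not what the
  profiled-β literature does, so it is not the default behaviour.
- Voxel-wise inference (FWE-corrected SnPM-style maps) is out of scope,
  as are gradient computation, laterality indices and surface rendering.
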