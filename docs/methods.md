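# Methods

This note documents the statistical procedures implemented in `connsig`,
the synthetic study conditions used to exercise them, the numerical
choices, and the known limitations.

## Connectome representation

A parcellation of R regions (default 64, grouped into 12 networks in
near-equal blocks) yields L = R(R+1)/2 connectivity values per subject:
all between-region Pearson correlations of the region-mean time series plus
one within-region value per region, all Fisher-transformed
(z = arctanh r). The canonical vector ordering is the lower triangle with
diagonal, column-major: `index(i, j) = j(j+1)/2 + i` for i ≤ j — one
bijection shared by every module and by the TSV column layout
(`c<i>_<j>`).

Numerical choices:

- Correlations are clipped to ±(1 − 1e−7) before arctanh so all vectors are
  finite for downstream linear algebra; `fisher_z(1.0)` ≈ 8.41.
- The within-region value is the Fisher transform of the **mean pairwise
  channel correlation** inside the region (mean of r, then arctanh), not
  the mean of Fisher-z values. With voxel/channel-level aggregation the two
  conventions differ slightly; mean-r was chosen because averaging raw
  correlations is the convention for summarizing a correlation block, and
  it is documented here because upstream tooling often leaves it implicit.

## CWAS

Connectomes are standardized per cohort against that cohort's **controls
only**: x ↦ (x − mean_ctrl)/SD_ctrl (sample SD, ddof = 1). Subtracting the
control mean (not just scaling by the variance) makes the global shift
interpretable as a displacement of cases relative to controls, in
control-SD units.

Per connection, ordinary least squares of the z-scored value on an
intercept, clinical status (0/1), and covariates — by default sex (0/1,
sorted levels), site (one-hot, first level dropped), age and mean framewise
displacement (linear). β is the status coefficient; significance is a
two-tailed t-test with df = n − p; BH-FDR is applied across exactly the
L tests of one CWAS, never pooled across cohorts. Cohen's d is computed on
the covariate-adjusted values (OLS residuals plus the status effect), so
its mean difference is exactly β and its scale is the pooled residual SD.
Rank-deficient designs raise an error naming the collinear columns; n ≤ p
raises a sample-size error.

**Global shift.** Mean β over all L connections. The null is built by
re-running the contrast after shuffling case/control labels (covariates
stay attached to their subjects); p = (1 + #extreme)/(1 + n_perm), default
5,000 permutations. The two-sided variant (|shift*| ≥ |shift|) is the
default; a one-sided "greater" variant and the plain frequency estimator
are available behind flags because the directional reading of the test is a
legitimate alternative. The +1-smoothed estimator is the default to avoid
p = 0.

**Null FC-signatures.** The same label shuffling yields full β maps under
the null; these are reused as the reference distribution by the mirror
test, the PLSR permutation test, and the per-gene empirical tests, so all
permutation inference in a run shares one null construction.

**Mirror statistic.** Per connection, the product β_del · β_dup; negative
products mean opposite-direction (mirror) dosage effects. Products are
averaged within network groupings: a connection whose two regions share a
network contributes to that network's statistic; cross-network connections
form their own pair groupings (78 groupings for 12 networks). The two-sided
empirical p compares the observed statistic with the same statistic on
paired null signatures; this permutation construction is this package's
own definition of significance for the mirror statistic, documented here
because the statistic itself does not dictate a null.

## Signature similarity

Before similarity scoring, each subject's connectome is residualized on
sex, site, age, head motion and the subject's mean connectivity over all L
connections, with cases and controls of a cohort pooled into a single OLS
basis — separate per-group residualization would make case and control
scores incomparable.

Similarity is Pearson's r between a group-level signature (β vector) and a
subject's adjusted connectome. Cases vs controls are compared by
Mann–Whitney U: exact enumeration when n₁ + n₂ ≤ 12 and there are no ties,
otherwise the normal approximation on midranks with tie-corrected variance.
The rank-biserial correlation 2U/(n₁n₂) − 1 ∈ [−1, 1] is the effect size.

The whole-brain scan runs every directed (signature source → target cohort)
pair — 42 tests for 7 groups — and FDR-corrects over the tests actually
run; subject overlap between a signature's source cohort and its target
raises a leakage error. The regional scan breaks the β matrix into its 64
rows (region profiles, within-region diagonal entry included by default,
excludable by flag since its membership in the profile is a convention) and
FDR-corrects over the 64 regions. Note that Pearson's built-in centering
makes the regional correlation equivalent to correlating mean-centered
profiles, and that a connection (k, j) belongs to both region k's and
region j's profile — signal planted "in a row" therefore legitimately leaks
into every other region's test at large n.

Behavior correlations: per (region, score) pair with ≥ 3 non-missing
subjects, Pearson r between regional similarity scores and the score, with
BH-FDR across all pairs tested; all-missing scores are skipped with a
warning.

## Imaging transcriptomics

**Alignment.** Donor expression samples (gene-level values, one region per
sample) are normalized with a scaled robust sigmoid,
s(x) = 1/(1 + exp(−(x − median)/(IQR/1.35))), min–max rescaled to [0, 1]
(1.35 converts IQR to a normal-equivalent SD; the method reference names
the normalization, the constant and rescale are the standard completion).
Stage 1 normalizes each sample across genes; stage 2 normalizes each gene
across a donor's samples; stage 3 averages samples within region per donor;
stage 4 averages across donors. Regions without any sample are NaN and
dropped pairwise downstream (never imputed). Stage 1 couples genes within a
sample: a gene's normalized value depends on the other genes sampled in the
same region, which slightly distorts even a noiseless spatial signal — a
property of the method itself, visible in the tests.

**Leave-one-donor-out consistency** rebuilds the panel once per left-out
donor and reports the mean pairwise correlation of the panels' leading
principal axes (gene loadings, sign-aligned). Because the leave-one-out
panels share all but one donor, they are correlated even for unstructured
donors; the diagnostic is therefore read as "near 1 under shared
structure", not "0 under independence".

**Regional response.** Region k's response is the mean of row k of the
symmetric β matrix ("global connectivity alteration"). Because row means
weigh between-region entries twice relative to the triangle, the mean of
the response vector equals the global shift only for constant maps.

**PLSR.** Partial least squares regression (NIPALS deflation,
tolerance 1e−6, deterministic initialization) of the centered response on
standardized gene-set expression; standardization prevents high-variance
genes from dominating and is this package's choice where the convention is
not fixed. r² is the response variance explained by k components (default
k = 2) on the fitted regions; p = (1 + #{null r² ≥ r²})/(1 + n_null) over
responses derived from the label-shuffled null signatures. A per-region
variant regresses each region's 64-value profile with BH-FDR over regions.
PLS reproduces a k-gene span exactly in k components only for orthogonal
predictors (Krylov property); with correlated predictors the guarantee
holds at k = min(R − 1, G).

**Gene-level tests.** Per gene, the spatial Pearson correlation with the
response; an empirical two-sided p against the null responses; BH-FDR
across genes; and the percentile rank of r in the genome-wide distribution.
Gene-set specificity uses two statistics against random same-size sets
(default 10,000): the set's median correlation, and the count of set genes
above the genome-wide 98th correlation percentile (over-representation of
top-ranking genes). Both p-values use +1 smoothing.

## Synthetic study conditions

The generators define the conditions under which the pipeline is validated:

- **Cohorts** are drawn directly in z-space: per-connection Gaussian noise
  (SD 1) around a zero baseline with site offsets (SD 0.1), sex offsets
  (SD 0.05), centered age slopes (SD 0.005/year) and motion slopes
  (SD 0.5/mm) drawn once per cohort; cases additionally receive the planted
  effect map plus any global shift. Covariates: age uniform on 6–45 years,
  balanced sex, 2 sites, framewise displacement log-normal around 0.16 mm —
  loosely modeled on developmental case/control cohorts, not fitted to any
  dataset. Default n = 40 + 40; the canonical planted contrast is
  Δ = 1.0 control-SD on 50 of 2,080 connections, sized like a
  large-effect-size mutation contrast.
- **Mirror pairs** give the duplication arm −dosage_ratio × the deletion's
  effect map with independently resampled controls and noise.
- **Behavior scores** are slope · similarity + Gaussian noise.
- **Expression**: each gene's regional profile mixes a target map (weight
  w) with one shared smooth spatial gradient (weight 1 − w) plus regional
  and sample noise; per-gene affine distortions emulate raw microarray
  units that the sigmoid normalization must remove; default 6 donors.
- A channel-time-series mode generates region-coupled latent signals so the
  raw correlation pathway (region means, within-region channel
  correlations) is exercised end to end.

What the generators do *not* emulate: BOLD autocorrelation and
haemodynamics, scanner noise, motion artifact structure beyond a linear FD
slope, distance-dependent connectivity structure, diagnosis heterogeneity
and comorbidity, or the AHBA's probe-level filtering and spatial sampling
bias. Passing tests therefore demonstrate the statistics behave as designed
under the assumed additive Gaussian model — calibration of the permutation
and rank tests, FDR control, recovery of planted effects — not that real
cohorts satisfy those assumptions.

## Problem sizes in the tests and acceptance script

Permutation and random-set counts default to the full-scale analysis
(5,000 permutations and null signatures, 10,000 random gene sets); the test
suite and the acceptance script run the same machinery at reduced counts
chosen as their problem sizes (typically 200–1,000 permutations, 500–10,000
random sets, 50–200 replicates, R = 16–64), which keeps every check
exercising the full code path. Calibration checks use Kolmogorov–Smirnov
uniformity at the 0.01 level; the +1-smoothed permutation p is bounded
below by 1/(1 + n_perm) and slightly conservative by construction.

## Known limitations

- Fixed-effect site covariates only; no mixed-effects or empirical-Bayes
  site harmonization.
- The mirror-test and gene-set nulls are permutation constructions defined
  here; other null choices are defensible and would change p-values.
- Expression alignment starts from gene-level sample values; probe-to-gene
  mapping and intensity filtering are upstream of this package.
- The regional-profile similarity inherits the row-overlap property
  described above: regional tests are not independent localizers.
- Adult expression only; no developmental trajectory modelling.
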