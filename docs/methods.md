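# Methods

## Scope and model

`coordmeta` implements coordinate-based meta-analysis of group-difference
neuroimaging findings in the effect-size-map-reconstruction (seed-based d
mapping) tradition. The unit of input is not an image but a study's
*report*: group sizes, covariates, and a table of peak coordinates with
test statistics. The pipeline has five statistical stages — effect-size
conversion, map reconstruction, random-effects pooling, cluster
inference, and moderation/robustness analyses — each exposed as a
library function and orchestrated by `pipeline.run_*`.

### Effect sizes

Two-sample peak t statistics convert to Hedges g with the standard
small-sample correction `J = 1 − 3/(4·df − 1)`, `df = n₁+n₂−2`, and
variance `v = (n₁+n₂)/(n₁n₂) + g²/(2(n₁+n₂))`. Z statistics are mapped
through their two-tailed p to the equivalent t quantile at the study's
df. Peaks reported without any statistic receive the lower-bound effect
at the study's own reported voxel threshold (two-tailed t quantile at
that p), signed by the peak's direction and flagged as imputed — the
conservative convention for "significant but magnitude unreported".

### Coordinate spaces

Talairach-space peaks are converted to MNI through the inverse of the
Lancaster *icbm2tal* affine for SPM-normalised data, stored as a single
documented 4×4 matrix (`study_io.ICBM2TAL`). The conversion is exact,
deterministic, and invertible; MNI input passes through unchanged.

### Map reconstruction

The common grid is isotropic (2 mm default) with a boolean analysis
mask. Two masks ship as code: a full MNI152 bounding box with a coarse
ellipsoidal gray-matter stand-in (centre (0, −18, 8) mm, semi-axes
(65, 85, 70) mm), and compact spherical box grids for simulation; any
user NIfTI mask is accepted. Each voxel of a study's effect map receives
the kernel-weighted **mean** of the peak effects reaching it, with the
un-normalised Gaussian kernel (FWHM 20 mm, truncated at 30 mm, where the
untruncated weight is already < 0.002). Consequences of the mean rule:
a voxel served by a single peak carries that peak's full g however far
(within truncation) it lies, and |voxel value| can never exceed the
largest contributing |g| (also enforced explicitly). Voxels reached by
no kernel are 0, and their variance is floored at `v(g=0)` so that
random-effects weights exist everywhere. Peaks falling outside the mask
are snapped to the nearest in-mask voxel with a logged warning.

### Pooling, heterogeneity, meta-regression

Pooling is DerSimonian–Laird at every voxel: τ² from the moment
estimator, weights `1/(vᵢ+τ²)`, analytic standard-normal two-tailed p on
Z = effect/SE. Sample size influences the result through v, matching the
"weighted by sample size and intra-study variability" description of the
method family. Cochran's Q with χ²(k−1) p-values maps between-study
heterogeneity. Meta-regression is weighted least squares of study
effects on (1, covariate); its τ² is the method-of-moments estimate from
the residual Q of the fixed-effect-weighted fit (k−2 df), the standard
meta-regression analogue of DL, re-used for the final weights. Studies
missing the covariate are dropped listwise and counted; the pipeline
additionally enforces the availability rule that a covariate analysed
must be reported by at least `min_covariate_studies` (default 10)
studies. p-values are analytic throughout; determinism was preferred to
a randomisation null.

### Inference and robustness

Clusters are 26-connected components of suprathreshold voxels
(p < 0.005), split by effect sign, discarded below 10 voxels or peak
|Z| < 1, and sorted by extent; the cluster peak is the member voxel of
maximum |Z| with smallest-linear-index tie-break. 26-connectivity is the
most inclusive standard neighbourhood and is configurable. The jackknife
repeats the pooled analysis leaving each study out once and counts, per
main-analysis cluster, the repeats in which a same-sign suprathreshold
cluster shares at least one voxel with it ("k out of N"). Egger's test
at each cluster peak regresses gᵢ/sᵢ on 1/sᵢ (OLS, two-tailed t test of
the intercept on k−2 df) and returns the funnel coordinates; when every
study has identical SE the least-squares intercept is undefined and is
reported as exactly 0 with p = 1 (all signal attributed to the slope).
For parameter-recovery scoring, the location estimate of a recovered
cluster is the pooled-effect extremum *within* the cluster
(`cluster_effect_peak`) — the |Z| peak coincides with it up to the
plateau of near-equal Z values that reconstruction produces inside a
homogeneous effect region.

### Cohort-level comparability

Age is pooled as the Hedges-g SMD (patients − controls) over studies
reporting mean and SD for both arms; the sex ratio as the log relative
risk of male sex (patients vs controls, delta-method variance, 0.5
continuity correction on zero cells), both with DL random effects and
Wald CIs. An odds-ratio variant (`measure="or"`, Woolf variance) is also
provided: on the shipped PSP table the strict relative risk computes to
1.05 while the male-sex odds ratio computes to 1.12 — the value the
source literature reports as a "relative risk", so both scales are
exposed and labelled. The orientation convention (patients over
controls; values > 1 = relatively more men among patients) is fixed and
documented.

## Synthetic-data generator

The generator emulates what the meta-analysis actually consumes:
studies that measure a noisy effect-size field, threshold it, and report
only surviving peaks.

* **Truth**: spherical clusters of constant Hedges g (default: one
  10 mm-radius reduction of g = −0.8 at (−6, 4, 2)); k = 18 studies;
  per-arm sizes uniform on 12–30 (the shipped study table's arms span
  5–24 patients and 8–80 controls); between-study heterogeneity as a
  study-level N(0, τ²) shift of the *cluster amplitude* (a whole-field
  offset would be a global intensity artifact, not effect
  heterogeneity); optional linear links from study covariates (age,
  UPDRS-III, MMSE, duration) to the amplitude for meta-regression
  experiments.
* **Noise**: a stationary smooth Gaussian random field (periodic
  convolution, unit marginal variance, FWHM 10 mm — inside the 6–12 mm
  smoothing kernels of the source studies) scaled voxel-wise by the
  Hedges-g sampling SD. Smoothness is essential, not cosmetic: with
  independent voxel noise a study's reported peak is the maximum of
  hundreds of independent draws and overstates the local effect by
  roughly one sampling SD, which no pooling can undo.
* **Reporting**: voxels nominally significant two-tailed at the study's
  threshold (default p = 0.05, the modal reported threshold in the
  study table) are clustered with the same 26-connectivity convention as
  the analyzer; each cluster of ≥ 5 voxels (40 mm³ — source studies
  report clusters well below the meta-analytic extent threshold)
  contributes one peak row (max-|d| voxel) with its t-equivalent.
  Setting the threshold to a family-wise-corrected level (e.g. 1e−5)
  emulates corrected studies, which report nothing under the null.
* **Grid**: simulations run on a compact spherical mask (42 mm radius,
  2 mm voxels). The mask must be comfortably larger than the 30 mm
  kernel truncation radius; on a barely-larger mask every false peak's
  kernel support covers the whole mask and spurious overlap dominates.

All randomness flows from one seeded `numpy` generator; datasets
round-trip through the same TSV formats the loader reads, with the truth
serialised as JSON alongside.

The free emulation parameters above (study threshold, noise smoothness,
reporting extent floor, arm sizes, simulation mask) were fixed by
design-time calibration so that the generator operates in the regime the
package's recovery oracles specify — individual studies usually detect
the planted effect, reported peak magnitudes are only mildly censored,
and the pooled analysis localises the planted centre to within a few
millimetres. At the frozen defaults, measured over 300 fresh-seed
replicates: the pooled-effect peak of the recovered significant cluster
falls within 6 mm of truth in 98% of replicates (the |Z|-peak in 96%),
and the mean |pooled effect| at that peak is 0.76 against a planted 0.8.

### What the generator does and does not emulate

It reproduces the statistical skeleton of CBMA inputs: thresholded peak
reporting with censoring, sample-size-dependent noise, between-study
heterogeneity, covariate moderation, and multi-study pooling. It does
not simulate raw T1 images, segmentation, registration error,
non-stationary anatomical covariance, correlated peak locations across
studies of shared lineage, or selective outcome reporting beyond simple
thresholding. Passing recovery tests therefore validates the pipeline's
statistical machinery under a faithful reporting model — not the claim
that real VBM literatures are this well behaved. Two realistic
pathologies the generator *does* reproduce are worth noting: at lenient
reporting thresholds, false study peaks can agree by chance and produce
spurious meta-analytic clusters (the jackknife and Egger diagnostics
flag them, as the examples show); and threshold censoring makes small
studies report larger surviving effects, a genuine small-study asymmetry
that Egger's test correctly detects at spurious peaks.

## Numerical choices and degenerate inputs

* p-values are clipped to (1e−300, 1] so p maps satisfy their (0, 1]
  contract at any Z.
* τ² is truncated at 0 (both pooling and meta-regression).
* Cluster peak ties break to the smallest linear (C-order) index;
  cluster lists sort by extent descending, then sign, then peak
  coordinate — all runs are bit-reproducible, and re-running a pipeline
  config yields byte-identical TSV outputs.
* Constant covariates and k < 3 meta-regressions raise; k < 2 pooling
  raises; zero-peak studies reconstruct to all-zero maps with floor
  variance (the encoding of "no significant differences").
* Egger with no precision spread returns intercept exactly 0, p = 1.
* The pooled SE always lies below every study's random-effects SE
  sqrt(vᵢ + τ²); it can exceed a study's *raw* SE when a single outlier
  inflates τ², which is expected behaviour, not an error.
* Zero cells in sex 2×2 tables get the 0.5 continuity correction on all
  cells (logged).

## Study-table fixture

The packaged TSV transcribes the demographic/clinical/imaging table of
the 18 PSP VBM studies (identified by first author and year), with `NA`
for cells the source table leaves unreported; ambiguous cells stay
missing and are never imputed. The `PSP-RS-criteria` subgroup tag marks
the 14 studies whose patients were diagnosed by the NINDS-SPSP clinical
criteria; the mapping excludes the pathologically-defined nfvPPA-PSP
cohort and the three studies explicitly mixing PSP-RS with PSP-P, an
assignment inferred from the narrative description (documented here
because the source lists counts, not study names). Loading and
re-serialising the fixture is byte-identical by construction (the
canonical writer produced it), which the data-integrity test enforces.

## Problem sizes used by tests and the acceptance script

Simulation-backed checks run at sizes chosen to estimate each quantity
well while keeping the default suite quick: cluster recovery uses 100
seeded datasets of 18 studies on the 42 mm simulation mask;
meta-regression slope recovery and Egger type-I calibration use 500
scalar replicates of 18 studies; the null suprathreshold-fraction
calibration uses 60 single-study fields on a smaller 22 mm mask. The
Monte-Carlo standard errors at these sizes are an order of magnitude
below the corresponding test tolerances.

## Known limitations

* The map-reconstruction conventions (weighted-mean combination, cap
  rule, variance floor, truncation radius) are this package's documented
  choices within the effect-size-CBMA family; they are not claimed to
  replicate any specific proprietary implementation detail.
* Analytic normal/χ² p-values stand in for randomisation nulls; at the
  default thresholds this is slightly anticonservative for reconstructed
  maps (whose null distribution is not exactly normal), which is one
  reason spurious clusters appear under lenient reporting and why the
  robustness battery exists.
* The ellipsoidal gray-matter mask is a coarse stand-in; serious use
  should supply a real GM mask via NIfTI.
* No FWE/FDR machinery beyond the extent rule, no trim-and-fill, no
  anatomical labelling — coordinates only.
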