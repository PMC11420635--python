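# Methods

`dceauc` implements a pretreatment DCE-MRI perfusion biomarker workflow for
radiotherapy cohorts (laryngeal/hypopharyngeal tumors being the motivating
setting): native T1 mapping from two variable-flip-angle scans, conversion of
the dynamic signal to gadolinium concentration, a model-free AUC60 perfusion
map with voxel quality control, tumor-level summaries, and cutpoint-based
survival analysis. This note records the models, the defaults and why they
were chosen, and what the synthetic tests do and do not demonstrate.

## Signal model and T1 mapping

All volumes are treated as spoiled gradient echo (SPGR) acquisitions in
steady state:

    S = M0 sin(a) (1 - E1) / (1 - E1 cos(a)),    E1 = exp(-TR / T1).

Two pre-contrast scans at flip angles 6 and 16 degrees (the protocol's VFA
pair, TR = 5 ms by default) determine T1 per voxel by the standard
linearisation y = S/sin(a), x = S/tan(a): the slope through the two points is
E1, so T1 = -TR/ln(E1) and M0 follows from the intercept. With exactly two
angles this inversion is exact, which the tests exploit (noiseless recovery
to 1e-9, agreement with a brute-force least-squares grid over
T1 in [0.05, 5] s at 1 ms steps). Voxels whose slope falls outside (0, 1), or
whose implied M0 is non-positive, have no physical solution; they are marked
invalid and carried as NaN through every later stage — masked, never imputed.
No B1 correction or multi-angle fitting is attempted.

## Concentration conversion

Gadolinium concentration enters through the linear relaxivity model
R1(t) = R1_pre + r1 C(t), with r1 = 4.5 L mmol^-1 s^-1 (gadobutrol at 3 T)
as the default. Per voxel, M0 is re-anchored on the mean signal of the
designated baseline (pre-contrast) frames together with the VFA T1, so that
the baseline mean maps to C = 0 by construction. Each dynamic frame is then
inverted exactly: E1(t) from the SPGR equation, R1(t) = -ln(E1)/TR,
C(t) = (R1(t) - R1_pre)/r1. Exact inversion was chosen over the common
small-enhancement linearisation because it is the conservative superset —
identical at low enhancement, unbiased at high concentration; the linear
approximation (dR1 ~ (S - S_pre)/(S_pre T1_pre)) remains available via
`method="linear"` for comparison. Frames whose signal implies E1 outside
(0, 1) — e.g. motion spikes — cannot be inverted; they become NaN and are
counted in a QC tally rather than raising.

The baseline window defaults to all frames before contrast onset (minimum
three); its indices are an explicit argument everywhere.

## AUC60 perfusion read-out

The arterial input function (AIF) is taken from a caller-supplied artery ROI
or a pre-extracted CSV — artery selection is manual in practice and automatic
vessel detection is out of scope. The AIF peak is the earliest global argmax
of the curve (plateaus anchor at their first frame); a curve with no positive
value is rejected as "no contrast arrival". The integration window starts one
frame before the peak — circa five seconds at the 4.95 s frame spacing of the
protocol — and spans exactly 60 s. Because 60 is not a multiple of 4.95, the
final partial interval is integrated against the linear interpolant of the
two bracketing frames (trapezoid elsewhere); a "snap to nearest frame"
alternative exists behind a flag but is off by default, since the interpolated
rule is exact on linear curves and keeps the window length exactly 60 s.

Voxel quality control runs in a fixed order:

1. **Percentile filter.** For each frame, the 2nd and 98th percentiles of
   concentration are computed across all tumor voxels (linear interpolation
   between order statistics, the scientific-stack default, fixed everywhere
   for reproducibility). A voxel strictly below the 2nd or strictly above the
   98th percentile at *any* frame is removed. The reference population is
   per-frame-across-voxels by default because that is the reading that
   catches frame-localised motion spikes; a pooled-over-the-4D-block variant
   is available via `percentile_scope="pooled"`. Strict inequalities make the
   all-identical case well defined: nothing is removed. Note a structural
   consequence: on any tumor whose voxel ordering is stable across frames
   (e.g. curves differing only by amplitude), the filter removes roughly 4%
   of voxels even without noise — the filter trades those voxels for
   robustness.
2. **Negative-AUC filter.** After the percentile pass, voxels whose AUC60 is
   negative are removed.
3. **Missing data.** Voxels with an uninvertible frame inside the window are
   excluded and tallied separately.

The tumor summary is the median and the 95th percentile of AUC60 over
retained voxels. If the retained fraction falls below `min_fraction` the
tumor is flagged "excluded"; the default 0.05 mirrors the source analysis,
which dropped a tumor retaining only 3% of voxels but stated no threshold.

## Synthetic phantom

The phantom exists so that every stage has a recoverable answer without any
data download. It emulates: SPGR signal formation at the protocol's flip
angles and TR; a gamma-variate AIF
C(t) = A ((t-t0)/tau)^k exp(k(1 - (t-t0)/tau)) peaking at t0 + tau (defaults:
A = 6 mmol/L, t0 = 22 s, k = 3, tau = 8 s, peak at 30 s); tumor tissue curves
as delayed, amplitude-scaled copies of the AIF with exponential washout
(mean amplitude fraction 0.25, +-50% uniform per-voxel spread, 5 s delay,
0.005 s^-1 washout), chosen deliberately simple because AUC60 is model-free
and no pharmacokinetic model is implied — the resulting AUC60 values
(roughly 5-30 mmol.s/L) sit in the range reported for these tumors; Gaussian
noise added on signal intensity, where acquisition noise lives; and
edge-artifact voxels (spikes or drops at random frames in a seeded subset of
tumor-boundary voxels) emulating residual motion at air/cartilage borders.
The default grid is 24 x 24 x 12 voxels x 24 frames at 4.95 s — small enough
that the full pipeline runs in seconds, large enough for ~500 tumor voxels.

Ground truth carries the true T1/M0 maps, the true sampled concentration,
and the true AUC60 map defined as the exact integral of the piecewise-linear
interpolant of the sampled curves over the true window — i.e. the quantity a
perfect pipeline would compute from the sampled data. The closed-form
integral of the *continuous* tissue curve (an incomplete-gamma expression)
is kept as an independent oracle and agrees with the sampled integral to
<0.5% at this frame spacing; it is deliberately not used as the roundtrip
target because the O(dt^2) discretisation gap would swamp the 1e-6 recovery
check that validates the inversion chain itself.

What the phantom does **not** emulate: k-space/coil effects, motion fields
(artifacts are injected directly in voxel signals), B1 inhomogeneity, T2*
decay, partial-volume mixing, or the 1.5 T arm of the protocol. Passing the
recovery tests therefore demonstrates the correctness of the numerical
chain, not robustness to every physical confound of real acquisitions.

## Synthetic survival cohorts

Cohorts draw exponential event times from a proportional-hazards model
h = h0 exp(beta 1[marker > cut] + sum(beta_j x_j)), with exponential
loss-to-follow-up censoring and an administrative cap at the follow-up
horizon (event = false at the cap). Defaults emulate the study population
the package targets: n = 89, marker ~ Normal(40, 12) mmol.s/L, protective
high-perfusion effect beta = -1.4 (hazard ratio ~0.25), baseline hazard
0.0094/month (five-year survival ~57% in the low group), 60-month horizon.
The multi-endpoint generator shares one marker/covariate draw across
endpoints (baseline hazards 0.0035/0.0059/0.0094 per month for local
control, disease control, overall survival, matching five-year rates of
roughly 81/70/57%) but draws event times independently per endpoint — real
endpoints are correlated beyond the shared covariates, so multivariate
event dependence is a known simplification. Seeds are mandatory fields; no
global random state is touched, and identical specs with identical seeds
are bit-identical.

## Survival analysis

Continuous markers are dichotomised at the maximally selected log-rank
cutpoint: every midpoint between adjacent distinct marker values leaving at
least `min_prop` (default 0.10, the convention of the R `surv_cutpoint`
function) of subjects on each side is scored by the standardized log-rank
statistic |O - E|/sqrt(V), and the earliest maximiser wins. The scan uses a
hand-written statistic so that tests can validate it against an independent
per-split log-rank oracle. One cutoff per marker is learned (on the overall
survival endpoint by default) and reused across endpoints, matching how a
single published cutoff per marker is normally reported; a per-endpoint
option exists. Because the scan maximises over many candidate thresholds,
the naive post-selection log-rank p is anticonservative — a property test
demonstrates the inflation under the null — which is why the analysis layer
applies a Bonferroni threshold alpha/m across the m univariable risk factors
(reported both as the exact value and the 3-decimal display form, e.g.
0.05/14 -> .004).

Kaplan-Meier estimation, the log-rank test and the Cox partial-likelihood
fit delegate to lifelines; ties are handled by the Efron approximation
(lifelines' default, and the usual recommendation when tie counts are
modest). Wald confidence intervals and p-values are reported per design
column; categorical covariates are dummy-coded against explicit reference
levels (T1 tumor stage, N0, radiotherapy-only, "clear" cartilage in the
intended application). Fits with fewer than 10 events per coefficient warn;
fewer events than coefficients is an error; monotone-likelihood warnings are
surfaced as diagnostics on the fit object rather than silenced.

Backward elimination drops, at each step, the covariate with the largest
block-level Wald p above the threshold (a categorical covariate leaves as a
whole block, scored by the chi-square form b' V^-1 b with df = block size),
refits, and repeats; the full trace is returned, and an empty model is a
legal outcome. Multicollinearity is screened with the generalized variance
inflation factor, GVIF_j = det(R_jj) det(R_-j) / det(R) over the correlation
matrix of the centred design; the df-adjusted GVIF^(1/(2 df)) is compared to
a sqrt(5) threshold (configurable — only "high GVIF" is conventionally
defined) and flagged covariates are excluded from the multivariable models,
mirroring the removal of a collinear anatomical covariate in the source
analysis. Competing events censor the local-control and disease-control
endpoints at the competing time; Fine-Gray competing-risk modelling is out
of scope and this censoring convention is the documented simplification.

## Pipeline and reproducibility

Every tolerance, percentile, threshold and seed lives in `RunConfig` and is
serialized into each report, so a run is reproducible bit for bit from its
config. Two multivariable models are first-class run modes: covariates named
in `anatomical_covariates` form an anatomical model fitted on the full
cohort, while the dichotomised perfusion marker plus the remaining clinical
covariates form the DCE model fitted on the post-exclusion subset — the
pairing used when an imaging biomarker is only available for part of a
cohort. Exclusion flags (short DCE acquisition, missing tumor delineation,
incomplete T1 imaging, low retained-voxel fraction) are resolved in a fixed
order into a ledger whose per-reason counts sum exactly to input minus
analysis-set size. Masks must share the series grid exactly; resampling and
registration are upstream concerns (the intended inputs are pre-registered
series), and DICOM ingestion is out of scope (NIfTI in, NIfTI/CSV/JSON out).

Problem sizes used by the test suite and the acceptance script — 32^3 voxel
phantoms with 24 frames, cohorts of 200-2000, 100-200 simulation replicates
— were chosen so each check runs in seconds while keeping Monte-Carlo error
well inside the asserted margins.

## Known limitations

- Two-angle VFA T1 is exactly identified but noise-sensitive; no B1
  correction means field inhomogeneity would bias real T1 maps.
- The percentile filter's reference population is ambiguous in the source
  description; both readings are implemented, and on amplitude-ordered
  tumors the per-frame default removes a fixed ~4% of voxels by
  construction.
- AUC60 is model-free: it tracks perfusion but has no direct physiological
  unit interpretation, and no pharmacokinetic parameters are estimated.
- The cutpoint learned by maximal selection is biased toward optimistic
  separation; downstream hazard ratios at the learned cutoff inherit that
  optimism. The Bonferroni layer controls the univariable type-I error, not
  the selection bias of the cutoff location itself.
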