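# Methods

## Imaging biomarker definitions

A tumor is an ordered stack of binary slices. On each slice the solid image
`A` holds the radio-dense pixels; the mask `B` is `A` with every interior
hole filled, using 4-connected background (equivalently 8-connected
foreground), so a lucent region is any background component that cannot
reach the slice border through edge-adjacent background steps. The lucent
pixels of a slice are `B & ~A`, and lucent connected components are labeled
with the same 4-connectivity as the background they are.

Averaging conventions differ by biomarker family. The composition scores
(RDC, RLC, AT_R) average their per-slice pixel ratios over every slice with
a nonempty mask. The cavity-geometry score LoCA averages the per-slice mean
inner diameter over slices that actually contain a lucent region, because a
hole-free slice contributes no inner diameter; LoSA takes a maximum over
lucency-bearing slices. Hole-free volumes return 0 for LoSA and LoCA so
that fully solid controls flow through the pipeline rather than erroring.

Geometric choices that the definitions leave open:

- **Boundary vertices** are centers of mask pixels adjacent (4-neighborhood)
  to background or to the image edge; coordinates are 0-based pixel centers.
- **Span** is a single per-volume scalar — the maximum over slices of the
  per-slice max Feret diameter of `B`'s boundary — so LoSA_R and LoCA_R
  share one denominator.
- **LoSA** is the directed boundary distance: for the largest lucent region
  of a slice, each of its boundary vertices is matched to its nearest mask
  boundary vertex, and the largest such distance (the thickest wall) is
  kept; the volume value is the max over slices. A literal
  max-over-all-vertex-pairs variant is available via `losa(...,
  method="max_pair")`; it is not a wall thickness (it can exceed Span) and
  is retained only for comparison.
- **Inner diameter** of a lucent region is the area-equivalent circle
  diameter `2·sqrt(area/π)`, which is well defined down to single-pixel
  holes; multiple regions on a slice are averaged.
- **Solidity** uses the active pixels of `A` over the axis-aligned bounding
  box of `B`, averaged per slice — the quantity usually called *extent*.
- Distances are in pixel units multiplied by the in-plane spacing (mm) when
  one is known; anisotropic in-plane spacing is averaged with a warning.

Exact algebraic consequences used as test invariants: `RDC + RLC = 1`,
`DoC = |2·RDC − 1|`, and on single-slice volumes `AT_R = RLC/RDC` (since
`P_(B∩A) = P_A`). Span and LoSA are verified exactly against an O(n²)
brute-force search over boundary-vertex pairs.

## Clinical encoding

Nine covariates enter the clinical pool: gender, age (years), weight
(lbs), smoking years, histology, T/N/M stage and tumor size (mm). Nominal
pairs map to {0, 1} in listed order (Male = 0, Female = 1; Squamous = 0,
Non-Squamous = 1). T, N and M stages map each category to its cohort
proportion (count/size), which keeps the design matrix dense; the mapping
is recomputed from the analysis cohort after exclusions, and a frozen
mapping can be supplied for reproduction runs. Continuous covariates pass
through unchanged. Subjects missing any covariate are excluded with a
logged reason. The binary 5-year endpoint is death within 5.0 years of
surgery; subjects censored earlier without an event get a missing label and
are excluded from classification but retained for time-to-event analysis.

## Dominance grouping

Ratio-type biomarkers (RDC, RLC, DoC, LoSA_R, LoCA_R, Solidity) are
thresholded raw at 0.6; unbounded biomarkers (AT_R, LoSA, LoCA) first pass
through the empirical-CDF mid-rank transform `v → (rank(v) − 0.5)/n` with
average ranks on ties, which is order-preserving and maps into (0, 1).
Biomarkers quantifying the dense portion (RDC, DoC, LoSA, LoSA_R,
Solidity) send values ≥ 0.6 to SD; lucent-portion biomarkers (RLC, AT_R,
LoCA, LoCA_R) send values ≥ 0.6 to NSD. The boundary value belongs to the
dominant side. Note the RDC and RLC partitions differ for subjects with
RDC strictly between 0.4 and 0.6; setting `rlc_as_complement=True` groups
RLC through 1 − RLC, making the two partitions identical.

## Classifier evaluation

Folds are drawn once per comparison — subjects are assigned uniformly at
random to k folds within each outcome stratum, so per-fold class counts
deviate from proportionality by at most one — and shared across predictor
pools and classifier families, making pool contrasts paired. Features are
standardized on the training folds only. Hyperparameters are fixed
defaults: L2 logistic regression; a 500-tree random forest; an RBF-kernel
SVM with sigmoid probability calibration; a 16-unit single-hidden-layer
network with early stopping. Out-of-fold probabilities are pooled and the
ROC/AUC computed in one sweep (the trapezoidal AUC equals the Mann–Whitney
statistic with half credit for ties).

IDI between two pools is the change in discrimination slope,
`(mean_new|event − mean_new|nonevent) − (mean_old|event − mean_old|nonevent)`,
with a z statistic dividing IDI by the combined standard error of the
per-subject probability differences within each outcome group and a
two-tailed normal p. This normal approximation assumes a fixed pair of risk
models scored on independent data. Applied to pooled cross-validated
probabilities it is anti-conservative: refitting on the labels being
evaluated adds variance the standard error does not see (we measure a null
z standard deviation near 1.3 at n = 400 with the logistic family), while
with probability vectors held fixed and labels permuted the z is standard
normal. Significance claims from CV probabilities should therefore be read
with that caveat; the package keeps the standard definition.

## Survival analysis

Kaplan–Meier estimation, the two-group log-rank test and Cox
proportional-hazards models are delegated to lifelines; ties use the Efron
approximation. The reported mean survival is the restricted mean to the
largest observed time, integrated from the KM step function, with the
standard Greenwood-type variance (cross-checked against R's `survival`).
The median is the earliest time with S(t) ≤ 0.5, with a log-log Greenwood
interval, and is reported as not reached (infinite) when the curve never
crosses 0.5. Multivariable models start from the univariable screen
(entry at p < 0.10, since published covariate pools commonly include
borderline univariable effects) and drop the largest-p covariate while any
Wald p ≥ 0.05.

## Synthetic study conditions

The generator is the package's test bed and defines its default study:
68 subjects; 3–8 slices per tumor with a lens-shaped radius profile and
base radius 8–20 px; per-subject lucent-fraction targets from an equal
mixture of Normal(0.10, 0.05) and Normal(0.50, 0.08) clipped to [0, 0.9],
so both sides of the 0.6 dominance threshold are populated; morphologies
cavity / multi-cyst / reticular, carved pixel-exactly into the mask
interior (never touching the rim, so hole-filling reconstructs the mask)
until the slice hits its target fraction — the realized volume-level
lucent composition lands within ±0.02 of the target, with per-slice caps
redistributed across slices and a bounded radius-growing retry when a
target exceeds the interior capacity. Outcomes follow an exponential
proportional-hazards model: baseline hazard 0.16/yr (solid-dominant median
near 4.3 years), NSD-vs-SD log hazard ratio log(2.2), independent uniform
censoring calibrated by root-finding to a 30% rate — together giving
roughly two thirds of subjects expiring within five years. Clinical
covariates are drawn from surgical-NSCLC-like marginals (71% male, mean
age ~69, 15% squamous, T/N/M compositions of an early-stage surgical
cohort) and are independent of imaging, so the clinical pool carries no
signal unless explicitly wired.

An alternative outcome wiring ties the hazard to composition continuously,
`h = 0.04 · exp(5 · (1 − RDC))`, calibrated so the imaging pool's
cross-validated AUC sits in the high-0.8s — the discrimination level
reported for imaging-biomarker models in this setting — at a 5-year
prevalence near 0.6. This is the scenario used by the discrimination-boost
check and the acceptance script.

What the generator does not emulate: CT intensity texture, partial-volume
and reconstruction effects, segmentation error, inter-slice (3D) cavity
connectivity, and correlation between clinical covariates and tumor
morphology. Passing tests therefore demonstrate correctness of the
measurement and inference chain under known geometry and hazards, not
performance on real CT cohorts.

## Problem sizes and numerics

Test and script workloads are scaled for a desk run: recovery of the
reference hazard ratio uses 200 replicates of n = 300; the
discrimination-boost property 50 replicates of n = 400; null calibration
200 outcome replicates over one fixed 400-subject cohort (feature noise is
irrelevant under the null, so volumes are generated once). All randomness
descends from explicit integer seeds; identical seeds give byte-identical
outputs. Degenerate inputs error with named reasons: empty slices, volumes
without tumor pixels, single-pixel masks for ratio denominators
(`span = 0`), all-lucent slices for AT_R, single-class labels for
ROC/IDI, no events for KM, and more events than covariates for Cox fits.
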