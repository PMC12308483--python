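# Methods

This note describes the models and procedures `madwt` implements, the
synthetic data they are exercised on, and the numerical and design choices a
maintainer would want to know about. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## The biomarker

On the AHA 16-segment left-ventricular model (6 basal, 6 mid, 4 apical
angular sectors referenced to the anterior RV insertion, apical cap
excluded), let `w_s` be the maximal end-diastolic wall thickness of segment
`s` in mm. Over the `n ≥ 12` valid segments:

- `MeanWT = mean(w_s)`
- `MaxWT  = max(w_s)`
- `MadWT  = mean(|w_s − MeanWT|)` — the heterogeneity biomarker: zero for a
  uniformly thick ventricle, large when thickening is regional.

MadWT is invariant to segment permutation and to adding a constant to all
segments, and scales linearly with a common factor; subjects with fewer than
12 valid segments are excluded (indices NaN).

## Segmental measurement (geometry)

Input is a short-axis label volume (cavity / myocardium / optional RV) with
voxel spacing, ordered base→apex (a flag records the stored order). Slices
are allocated to basal/mid/apical thirds as equally as possible, remainders
to basal then mid (10 → 4/3/3, 11 → 4/4/3). On each myocardium-bearing
slice, rays are cast from the cavity area centroid at a 1° step (sector
maxima are insensitive to steps ≤ 2° on phantoms; the step is configurable).
Ray angles are offset by half a step from the sector boundaries, where the
interpolated label field is ambiguous.

Per ray, the binary myocardium indicator is smoothed with a small Gaussian
(σ = 0.7 voxels) and sampled by bilinear interpolation at spacing/4
intervals. The first contiguous myocardial run is located by the 0.5-level
crossings (endocardial entry, epicardial exit) and the thickness is the
partial-volume mass of the smoothed indicator integrated over that run
extended by 0.75 voxels each side. Rationale: each AHA segment reports the
MAXIMUM over its rays, an order statistic that converts the ±half-voxel
wiggle of a pure level-crossing estimate into a systematic positive bias;
for a straight or gently curved boundary the 0.5-level of the smoothed
rasterized mask lies on the true boundary, and mass integration averages the
residual reconstruction noise along the ray. On stepped-annulus phantoms at
0.5 mm spacing this keeps every segment within 0.5 mm of design (measured in
the tests); a distance-transform operator was rejected because the
per-segment maximum of nearest-boundary distances under-reports oblique
walls, and a centerline-chord operator is left as an extension point.

Angular convention: 0° at the image "up" direction, increasing
counter-clockwise as displayed (the AHA bull's-eye convention viewed from
the apex); segment 1/7/13 starts at the anterior RV insertion. The insertion
is detected as the most counter-clockwise myocardial voxel 4-adjacent to the
RV label (robust to wrap-around via offsets about the junction arc's
circular mean); without an RV label the angle must be supplied in metadata.

## Quality control

Within each subject, segmental values strictly above `Q3 + 3·IQR` of that
subject's measured segments are removed (quantiles by linear interpolation
between order statistics). Low values are never removed; with degenerate
IQR = 0 only values strictly above Q3 go. The filter is one-pass — the fence
is not recomputed after removal, and a profile already carrying the QC flag
passes through unchanged, making the operation idempotent. A per-cohort
fence is available behind `SegmentOutlierFilter(scope="cohort")` but the
per-subject rule is the default: the rule reads as within-scan cleaning of
segmentation failures. The upper-fence direction follows the "above the 75th
percentile" reading of the otherwise self-contradictory source convention.

Caveat: on a profile whose measured segments are nearly constant the fence
collapses onto Q3, so an isolated genuinely thick segment is
indistinguishable from a segmentation failure and is removed. This is
inherent to a within-subject spread-based rule, matters only for
near-uniform ventricles with a single thick segment, and is the reason QC
can be disabled (`wt_indices_frame(..., qc=False)`, `indices --no-qc`).

## Activity and volumetric indices

Questionnaire MET-minutes: `TPA = 3.3·walk_min·walk_days +
4.0·moderate_min·moderate_days + 8.0·vigorous_min·vigorous_days`
(MET-min/week); the vigorous term is also reported alone. Accelerometer mean
vector (milli-g) is used only for subjects with ≥ 72 h calibrated wear.
Body surface area uses Du Bois (`0.007184·height^0.725·weight^0.425`, m²;
Mosteller available), giving `LVMi = LVM/BSA`, `LVEDVi = LVEDV/BSA`,
`LVMVR = LVM/LVEDV`.

## Risk-factor model

MadWT given covariates is modelled by a maximum-likelihood Gamma GLM with an
identity link: effects are additive in mm (per SD of each standardized
continuous predictor) while the outcome stays strictly positive and
right-skewed. The identity link does not respect the Gamma domain, so the
fit verifies that all fitted means are positive and fails loudly otherwise;
non-convergence raises with the iteration trace.

## Prognosis models

Cox proportional hazards (partial likelihood, Efron ties — the ecosystem
default, via lifelines) fitted stepwise on identical complete-case rows:
Model 1 biomarker only; Model 2 + cardiovascular risk factors (age, sex,
ethnicity, BMI, smoking, hyperlipidaemia, hypertension, diabetes); Model 3
+ LVEDVi and LVEF; Model 4 + LVMi. Nesting is asserted at run time. Effects
are reported per mm or per analysis-sample SD (SD computed after exclusions,
before modelling); the SD map makes the scales interconvert exactly,
`HR_SD = HR_unit^SD`.

Discrimination is Harrell's C over usable pairs (event–event with distinct
times, event–censored with the censoring later; risk ties count 0.5).
ΔC between nested models fitted on the same rows is tested by a paired
bootstrap over subjects (default 1000 resamples, seeded): the p-value is a
two-sided normal test of ΔC against zero with the bootstrap SE. In-sample ΔC
of a noise augmentation is centred on zero only when the reference model has
real discrimination; against a no-signal reference the C-index sits at its
0.5 floor and any fitted column can only look like a gain, so the null ΔC
experiment uses an age-only reference while the signal experiment adds the
full true linear predictor to a noise-only reference.

Diagnostics: VIF per predictor from auxiliary OLS regressions of each design
column on the others (collinear columns report ∞; the guideline threshold is
VIF < 5), and a proportional-hazards check regressing each predictor's
Schoenfeld residuals on event time (slope p).

## Matched hypertension comparisons

Propensity for hypertension is a logistic regression on age, sex, ethnicity,
height, BMI, smoking, hyperlipidaemia and diabetes. Confounders the MLE
cannot identify — constant columns, or binary columns with an empty
treated-by-level cell (quasi-separation; routine for 97%-prevalence
ethnicity in ~300-subject strata) — are dropped with a log entry. Matching
is greedy 1:1 nearest-neighbour on |score difference| without replacement,
treated processed in descending score order, ties broken by id order, no
caliper; greedy order and the absence of a caliper are documented choices,
configurable, and deliberately NOT optimal matching. Balance is reported as
standardized mean differences before and after matching.

Activity strata take rows at or above the (1 − fraction) quantile of TPA,
vigorous MET-min/week, or (wear-valid subjects only) the accelerometer mean
vector; ties at the threshold are all included. Matching is performed within
the stratum (match-then-stratify is available by stratifying the matched
frame instead).

Biomarker contrasts between matched groups use the two-sided Mann-Whitney U
test — exact for groups ≤ 20, otherwise the tie-corrected normal
approximation with continuity correction — with percentile-bootstrap 95% CIs
for each group median (default 2000 resamples, seeded) and a Bonferroni flag
at 0.05 / family, the family defaulting to the number of biomarkers compared
(9, giving 0.0056).

## Synthetic data

**Phantoms.** Each slice is an annulus centred on the grid: cavity inside
the endocardial radius (default 20 mm), myocardium out to a per-angle
epicardial radius stepped across the AHA sectors of the slice's level, so
every segment has an exactly known design thickness. Voxels are labelled by
centre position. An optional RV wedge is painted outside the epicardium with
its counter-clockwise edge at the nominal insertion angle, to exercise
insertion detection. Phantoms emulate end-diastolic segmentation masks only:
no image intensities, papillary muscles, outflow tract, motion, or
through-plane obliquity — so passing tests demonstrate the measurement
operator's geometric accuracy, not robustness to segmentation error.

**Cohorts.** Covariates follow a population-imaging profile: age
N(64.6, 7.7²) y, male 48.1%, white 97.1%, current smoker 3.5%, height
N(170, 9.4²) cm, BMI N(26.5, 4.4²) kg/m², hyperlipidaemia 31.8%, diabetes
6.1%. Hypertension (27.4%) is assigned by a logistic model in standardized
age and BMI (coefficients 0.45 and 0.55; intercept solved by Gauss–Hermite
quadrature to hit the prevalence), which supplies the confounding the
matching stage needs; other binaries are independent, as no correlation
targets were available — a documented guess, configurable.

Wall-thickness biomarkers come from identity-link Gamma models whose means
are linear in standardized covariates: MeanWT (marginal mean 7.15 mm, shape
45) and MadWT (mean 0.97 mm, shape 10 — shapes chosen so the marginal
quartiles match the reference medians/IQRs of ≈7.1 (6.4, 7.8) and ≈0.94
(0.76, 1.15) mm), with hypertension adding +0.30 and +0.12 mm respectively.
In the default segment-level mode the generator draws a subject mean and a
subject heterogeneity target, builds 16 segmental values as
`mean + target·d` with `d` a zero-mean pattern normalized to unit mean
absolute deviation, and derives all indices through the same QC + index code
the measurement pipeline uses; a direct mode draws the indices from the
Gamma models and sets `MaxWT = MeanWT + MadWT·(2.2 + noise)`, exact for
estimator-recovery studies. A `htn_shift` hook adds a constant to named
biomarker columns post-construction so experiments can shift a single
biomarker without propagating through the structural links. Auxiliary
biomarkers (LVMi, LVEDVi, LVEF, GLS, native T1) are log-normal/normal with
medians matched to the same reference table; LVMVR = LVMi/LVEDVi by
construction.

Activity: log-normal minutes × binomial days per week per intensity,
calibrated once so median TPA ≈ 2000 MET-min/week; 41% of subjects are in
the accelerometer sub-study and 5% of those fail the 72-h wear requirement.

**Survival.** Event times are Weibull proportional hazards (shape 1.3;
chosen for closed-form inverse-transform sampling under PH — the baseline
family is otherwise unconstrained by the reference setting) with linear
predictor `Σ β_k·z_k` over standardized biomarkers; defaults give MadWT a
per-SD log hazard ratio of 0.25 for a MACE-like endpoint, with endpoint
event fractions 1.7% (MACE), 0.6% (HF), 2.5% (arrhythmia), 1.5% (death)
under administrative censoring at 7.5 y minus a U(0, 3.2) y entry jitter
(median follow-up ≈ 5.9 y; the upper follow-up quartile is mildly lighter
than the reference cohort's 7.1 y — a known approximation). The Weibull
scale is calibrated deterministically to the target fraction by integrating
the event probability over the censoring distribution and a normal
approximation of the linear predictor (Gauss–Hermite), so the baseline is
fixed in the config and event fractions remain monotone in each log-HR.
Every cohort ships with a ground-truth record (coefficients, baselines,
per-subject latent linear predictors) that fitting code never reads.

## Problem sizes and known limitations

The replication experiments run at: 3 stepped phantoms + 1 uniform phantom
at 0.5 mm spacing; CI coverage 100 cohorts of n = 37 080; null Wald
calibration 1000 cohorts of n = 5 000; ΔC at n = 10 000 (1000-resample
bootstrap; 10 null replicates at 300); matching balance at n = 20 000;
matched-comparison power 200 replicates of 160 pairs.

The matched-comparison power experiment sits near its threshold by
construction: with MadWT sd ≈ 0.32 mm, a +0.13 mm shift at 160 pairs has
Mann–Whitney power ≈ 0.82 at the 0.05/9 level, and the joint requirement
(MadWT flagged, all eight null biomarkers unflagged) has success probability
≈ 0.81 — single-seed runs land on either side of 80%.

Known limitations: no competing risks, time-varying covariates or effects in
the simulator's truth (except the designed PH-violation test); biomarker–
covariate correlations beyond those modelled are absent; phantom geometry is
convex and centred, so centroid ray-casting cannot probe strongly concave
ventricles; the Mann–Whitney asymptotic p is approximate for heavy ties.
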