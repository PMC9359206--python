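# Methods

`dfcvar` analyzes how unstable the functional coupling between brain
regions is over the course of a resting-state fMRI scan, and how that
instability changes under treatment in a longitudinal two-group design.
This note describes the statistical machinery, the synthetic cohort that
stands in for patient data, the numerical choices, and the limits of what
the simulations can show.

## The temporal-variability statistic

For two BOLD time courses the series is segmented into sliding windows of
`L` TR advanced by `step` TR (defaults L = 50, step = 1, giving
m = ⌊(T − L)/step⌋ + 1 windows; 201 windows for T = 250). Within window k
the Pearson correlation r_k is computed on the raw (untapered) samples.
The temporal variability of the pair is the mean squared successive
difference

    I = 1/(m−1) · Σ_{k=2..m} (r_k − r_{k−1})²,

computed on raw correlations without a Fisher transform. I = 0 for a
perfectly stationary coupling; since |r_k − r_{k−1}| ≤ 2, I ≤ 4. The
window length respects the slowest retained frequency: a window shorter
than 1/f_min cannot resolve it, so `min_window_length(f_min, TR)` =
⌈(1/f_min)/TR⌉ (50 TR at f_min = 0.01 Hz, TR = 2 s).

Two estimator forms are provided: region-pair matrices
(`roi_variability_matrix`, with the companion `mean_fc_matrix` holding the
window-mean correlation) and a seed-to-voxel map
(`seed_variability_map`). The seed time course is the unweighted mean of
the seed voxel and its six face-adjacent neighbors on the 3 mm grid;
neighbors outside the image or brain mask are dropped, not zero-filled, so
edge seeds stay unbiased. Voxel maps are computed in fixed-size flat
blocks of voxels using prefix-sum window moments, so memory stays bounded
and block boundaries cannot change results (asserted bit-exactly in the
tests). Windows with zero variance abort the pair/voxel rather than
imputing r = 0, which would bias I downward; aborted voxels are counted
and masked out of the map.

## Preprocessing

The pipeline consumes already-normalized volumes or region time series and
applies only temporal steps: a zero-phase band-pass (order-4 Butterworth,
0.01–0.08 Hz, forward–backward so no phase distortion enters the windowed
correlations), then least-squares removal of white-matter, CSF, linear
trend, and 12 motion parameters (6 rigid-body + backward differences,
first row 0). The global mean signal is never regressed: global-signal
removal can distort between-group comparisons of inter-regional
correlation in clinical samples. Filtering precedes confound regression;
the two do not commute, and this order (filter first) is kept even though
regressing filtered confounds from filtered data is the more conservative
common practice — the order is a documented pipeline convention, not a
statistical necessity at these parameters.

Motion QC excludes a session when the maximum absolute translation on any
axis exceeds 3.0 mm or the maximum rotation exceeds 3.0° (rotations are
stored in radians and converted for the threshold; "maximum" is relative
to the reference volume, not frame-to-frame). Framewise displacement uses
the Power convention, FD_t = Σ|Δtrans| + 50 mm · Σ|Δrot|, with FD_1 = 0.
FD is reported, not used for frame censoring.

A note on repeated filtering: an order-4 Butterworth passed twice loses a
further ~2% of the filtered signal's energy in the transition bands; the
difference carries under 1% of the *input* signal's energy, which is the
sense in which the operation is idempotent.

## Group statistics

With exactly two timepoints, the repeated-measures ANCOVA interaction
(group × time, adjusting for age, sex, illness duration, education, and
antipsychotic dose) is algebraically a change-score GLM: regress
d_i = outcome_t2 − outcome_t1 on group plus the between-subject
covariates; the 1-df F on the group term is the interaction F. This is
exact, fully specifiable, and verified in the tests against the two-sample
t on change scores in the covariate-free case (F = t²). Sex is coded 0/1;
covariates enter untransformed; an unadjusted variant is available.

Post-hoc contrasts are paired t within group — reported for t1 vs t2, so a
*decrease* in variability yields a *positive* t — and two-sample t between
groups at each timepoint and against a healthy reference sample.
Region-pair (matrix-entry) tests use uncorrected p < 0.005.

Clinical change is the remission ratio RR = (score_t1 − score_t2)/score_t1
per PANSS subscale, and the relative variability change
(I_t2 − I_t1)/I_t1; both are scale-invariant and undefined at a
non-positive baseline. Brain–behavior association uses partial Spearman
correlation: rank-transform both variables, residualize the ranks on an
intercept plus covariates, Pearson-correlate the residuals, t-based p on
n − k − 2 df. The variability–FC coupling check correlates group-mean I
with group-mean windowed FC across the upper-triangle region pairs.

## Cluster-extent correction

Voxel-wise statistic maps are corrected by Gaussian random-field theory:
the map is converted to z through its p-values, thresholded at z(height_p)
(one-sided, default height_p = 0.005), and 26-connected suprathreshold
clusters are labeled. Field smoothness (FWHM per axis, voxels) is
estimated from the spatial forward differences of residual images
normalized to unit sum of squares per voxel: λ_i = mean squared
derivative, FWHM_i = √(4 ln 2 / λ_i), clamped at 1 voxel with a warning.
The search region is summarized by Worsley's discrete resel counts
R0..R3 (voxel, edge, face, and cube counting — boundary terms matter at
this height threshold; the volume-only term alone is ~40% conservative on
the extent threshold). The expected cluster count is the expected Euler
characteristic E[m] = Σ_d R_d ρ_d(u); the cluster-size tail uses the
exponential approximation P(n ≥ k) = exp(−β k^{2/3}) with
β = (Γ(5/2)·E[m]/E[N])^{2/3}, and a cluster's family-wise corrected p is
1 − exp(−E[m]·P(n ≥ k)). A permutation-style empirical threshold — the
(1−α) quantile of the maximum cluster extent over null maps — is provided
as an independent oracle and fallback; on simulated stationary fields
(20³ voxels, FWHM 8 mm / 2.67 voxels) the analytic extent threshold sits
within ~25% of the empirical one and the realized family-wise error rate
at nominal 0.05 is ~0.02 (GRF is conservative at moderate smoothness).
A fixed minimum-extent rule (e.g. 600 mm³ = 23 voxels at 3 mm, ceiling)
is exposed as an optional additional filter.

## Treatment-response prediction

Baseline (t1) variability values on the selected region pairs predict the
remission ratio of each PANSS subscale via epsilon-SVR (RBF kernel;
epsilon = 0.1; linear kernel optional). For every (C, γ) point on
log-spaced grids (C ∈ 10⁻²…10⁴, γ ∈ 10⁻⁴…10¹) a full leave-one-out loop
is run, z-scoring features with training-fold statistics only; the grid
point with the smallest held-out MSE wins, ties preferring smaller C then
smaller γ (the smoother model). The reported predictions, MSE, and
r(predicted, actual) belong to the winning point, so prediction i never
saw subject i. Target outliers beyond 2 sample SD (single pass, mean/SD
from the full vector) are excluded before fitting.

Two caveats are inherent to this (deliberately replicated) single-loop
design and are documented rather than "fixed":

* the grid is selected on the same LOOCV loop that is reported, so the
  MSE is optimistic;
* under a weak or absent signal, held-out LOO predictions anti-correlate
  with the held-out values (each prediction tracks the training mean,
  which moves opposite to the left-out observation), so the null
  distribution of r(predicted, actual) is strongly *negatively* biased
  (mean ≈ −0.5 at n = 20 with grid selection). A negative "significant"
  r from this estimator is an artifact, not a finding. The leakage check
  is therefore one-sided: under permuted targets the estimator must show
  no *positive* optimism (it does not), while a genuinely planted link is
  recovered as a positive, significant r.

The feature pairs are selected by group-level tests that use both
timepoints, then prediction runs from t1 features — a circularity of the
replicated design worth keeping in mind when reading absolute r values.

## The synthetic cohort

No patient data ship with the package; every downstream stage is
exercised on a generator whose ground truth is exact.

**Signal model.** Regions come in disjoint two-region blocks (regions 2k,
2k+1). Each block's inter-regional correlation toggles between a low and
a high level under a hidden chain; cross-block correlations are zero, so
the instantaneous covariance is block-diagonal and positive definite by
construction, and each pair's variability is controlled solely by its own
switching rate. Samples are drawn per TR from the active state's
correlation matrix, white noise (sd 0.2) is added, the series is band-pass
filtered (0.01–0.08 Hz) and standardized. Scans are 255 volumes at
TR = 2 s; the first five are discarded before analysis (250 points, 201
windows).

**Dwell times.** Level dwells are Erlang(shape = 8): each level is a
cycle of 8 Markov sub-states sharing the level's covariance, giving mean
dwell 1/p TR with coefficient of variation 1/√8 instead of the geometric
chain's 1. A 250-TR scan realizes only a handful of dwells; with
geometric dwells the realized switch count is so dispersed that
between-subject variance of I swamps any plausible treatment effect
(pilot power ≈ 0.2–0.3 at the design sizes). Regularized dwells keep the
generator's planted effects commensurate with the sample sizes a real
study of this kind uses. A plain two-state chain is retained as the
elementary model (`two_state_pair_model`).

**Defaults as study conditions.** Two patient groups of 20 (plus 12
baseline-only healthy controls), base switch probability 0.012/TR — on
the rising limb of the I-vs-rate response; above ~0.02/TR window
averaging saturates the statistic — with a per-subject lognormal rate
multiplier m_i (σ = 0.35). The three "responsive" blocks swing between
anticorrelated and strongly correlated states (−0.8 ↔ 0.9 and similar);
the other three hold high mean correlation with small swings. This makes
mean FC and I decouple *negatively* across pairs, for two reasons: the
sampling variance of a windowed correlation scales as (1 − ρ²)², so
near-zero-FC pairs have the noisiest r_k paths, and the high-FC blocks
are the most stable by design.

**Treatment effect and clinical link.** Treated subjects at t2 switch at
rate p·m_i·δ_i on responsive blocks, with per-subject responsiveness
δ_i = effect_delta^(m_i³): subjects with abnormally high baseline
switching normalize the most. This is what makes baseline features
predictive of response by construction, and it is null-safe
(effect_delta = 1 ⇒ δ_i = 1, nothing planted). The negative-subscale
remission ratio is linear in the *planted* relative drop,
RR = 0.34·(1 − δ_i) + N(0, 0.03²); other subscales and the drug-only
group receive group-level baseline remission rates (means drawn to match
typical chronic-schizophrenia trajectories) without a brain link. PANSS
scores are integer-valued and clipped to instrument ranges
(positive/negative 7–49, general 16–112; total = sum). Motion traces are
smooth random walks scaled inside the QC limits, with an optional planted
fraction of gross failures (abrupt 4 mm shift).

**What passing tests do and do not show.** On this generator the default
pipeline recovers the planted responsive pairs at p < 0.005 with mean
sensitivity ≈ 0.9 and false-discovery proportion ≈ 0.15, recovered pairs
show the decrease direction in ~100% of cases, the variability–FC
coupling is negative in ~100% of replicates, and the SVR link is detected
in ≈ 80–86% of replicates (this last property has little margin; single
batches of a dozen replicates can dip below 0.8). These are statements
about a block-structured, stationary-noise, motion-free-signal world with
an exactly linear clinical link. Real BOLD has hemodynamic convolution,
physiological noise, scanner drift, spatially correlated noise, and
non-block covariance — none of which are emulated — so the recovery rates
bound what the code does, not what any real study would find.

## Numerical choices

* Windowed moments via prefix sums; O(T·R²) for all pairs at any overlap.
  Correlations are clipped to [−1, 1] against roundoff.
* MNI→voxel conversion rounds half away from zero (deterministic;
  −0.5 → −1).
* Confound designs are checked for rank on the column-normalized matrix
  (tolerance 1e-8); collinear designs raise rather than project.
* Degenerate windows are detected by a variance threshold relative to the
  window's sum of squares (1e-12), robust to the scale of the data.
* The pipeline derives every per-subject stream from one master seed via
  `numpy` SeedSequence spawning; identical config + seed reproduce
  byte-identical outputs (checksummed in the run manifest).
* Small pipeline runs (fewer than 8 treated subjects) drop the covariate
  adjustment in the brain–behavior correlation, with a logged warning,
  because the partial correlation needs n > k + 2.
* Simulation sizes in the shipped acceptance checks (1000 null maps for
  the cluster calibration, 50 cohort replicates for recovery properties,
  500–1000 univariate replicates for type-I calibration) were chosen so
  the whole suite completes in a few minutes on one CPU; the acceptance
  script uses 12 cohort replicates and 500 maps for the same reason.

## Known limitations

* ROI definitions are coordinate tables only; no atlas-image parsing, no
  surface formats, no DICOM.
* The voxel-wise path assumes the volumes fit in memory; only the
  correlation workspace is blocked.
* GRF correction assumes a stationary, sufficiently smooth Gaussian
  field; at FWHM near 1 voxel the analytic threshold is unreliable (the
  smoothness estimate is clamped and a warning issued) — use the
  permutation threshold there.
* The change-score interaction test is exact only for the two-timepoint
  design; more timepoints would need a genuine mixed model.
* LOOCV r has the null-bias described above; compare models by held-out
  MSE, and treat negative r as null.
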