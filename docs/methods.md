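# Methods

## Model

The core model is a two-boundary Wiener diffusion with stimulus-dependent
drift. On a trial showing morph s ∈ {1, …, 15}, evidence X(t) evolves as
dX = v(s) dt + σ dW from X(0) = z ∈ (0, a), and the response is "angry" if
X reaches a first, "happy" if it reaches 0; RT is the first-passage time
plus the non-decision time t₀. The drift is linear in the morph index,
v(s) = v_int + s·v_slope, so each observer is summarised by

* sensitivity v_slope (evidence/s per morph step), and
* perceptual bias s_indiff = −v_int/v_slope (morph units), the point where
  drift vanishes. s_indiff is real-valued; fits flag, never clip, values
  outside [1, 15].

Conventions. Only two of (v, a, σ) are identifiable, so σ is fixed at 1;
all drift and boundary values are stated in that scale (some traditions use
σ = 0.1; all derived quantities — choice probabilities, s_indiff, parameter
orderings — are invariant to the convention, which the test suite checks
explicitly). The upper boundary codes "angry" because s increases toward
angry, making v_slope positive for typical observers. Morphs are indexed
1-based with the ambiguous middle at s = 8, so group indifference points
around 7.5–8.5 straddle the midpoint. RTs are stored in seconds; readers
accept a millisecond column via a flag.

Assumptions: no across-trial variability parameters (sv, st₀, sz of the full
Ratcliff model), no lapse/contaminant process, parameters stationary across
runs. These are deliberate non-goals; the model is the minimal one that
separates perceptual sensitivity and bias from caution, response bias and
motor time.

## Likelihood and its numerics

The trial likelihood is the defective Wiener first-passage-time density.
After rescaling to unit diffusion and unit boundary, the lower-boundary
density factorises into exp(−v·a·w − v²t/2)/a² times a drift-free density
f₀(t/a²; w), which has two classical series representations. We evaluate
whichever converges faster at each point — the small-time sum over mirrored
start positions (w + 2k) or the large-time sine series — with truncation
orders chosen from the standard error bounds so each evaluation is accurate
to 1e−7 (term counts capped at 64; the two branches agree to ~1e−10 where
both are usable). The upper-boundary density is the lower-boundary density
under the reflection v → −v, w → 1 − w. Density values at t ≤ t₀ are exactly
zero, and a trial with rt ≤ t₀ makes the joint negative log-likelihood +∞
(represented by a large finite penalty inside the optimiser, whose t₀ bound
prevents the region from being visited).

The analytic absorption probability
P(angry) = (1 − e^{−2vz/σ²})/(1 − e^{−2va/σ²}) is evaluated with `expm1`
and, for negative drift, the complementary identity, so it is stable from
v = 0 (limit zᵣ) through |v·a| ≫ 1. Tests confirm that the density
integrates to its boundary's absorption probability and that the two
boundaries' densities integrate to 1 (quadrature tolerance 1e−5).

## Simulation

Trials are simulated by Euler–Maruyama with step dt = 1e−4 s (configurable).
Discrete monitoring systematically misses within-step boundary excursions,
biasing choice fractions and inflating passage times by O(√dt); we apply the
standard continuity correction for discretely monitored barriers, moving both
boundaries inward by 0.5826·σ·√dt, which reduces the bias to O(dt) —
negligible against Monte-Carlo error at the sample sizes used here. Paths not
absorbed within 20 s (probability ≪ 1e−10 at realistic parameters) are
forcibly absorbed at the nearer boundary with a warning. Simulation is a pure
function of (parameters, schedule, seed).

## Per-participant estimation

Parameters (v_int, v_slope, a, zᵣ, t₀) are estimated by full maximum
likelihood on the joint (choice, RT) data — chosen for statistical
efficiency; fit quality is reported via quantile-probability summaries
(choice proportions and the conventional .1/.3/.5/.7/.9 RT quantiles per
morph and response, with cells under 5 responses flagged rather than
estimated). The optimiser is bounded L-BFGS-B with box constraints
(a ∈ [0.2, 5], zᵣ ∈ [0.02, 0.98], 0 < t₀ < min observed RT) from 5 starts:
one moment-style heuristic (drift line from a logit regression of per-morph
angry proportions, t₀ from the minimum RT, in the spirit of EZ-diffusion
mappings) plus jittered perturbations. zᵣ is estimated freely per
participant. Degenerate data (a single response type throughout) and
all-starts-failed cases return flagged fits with absent metrics. On
well-posed 450-trial synthetic data, refitting with a different start seed
changes the best NLL by < 1e−3.

Recovery properties measured by the test suite: with observers spanning
s_indiff ∈ [6.5, 9.5] and sensitivity ∈ [0.18, 0.35] on a 450-trial session,
the median absolute indifference-point error is < 0.3 morph units and the
rank correlation of true vs recovered sensitivity exceeds 0.95; error shrinks
from 150- to 450-trial sessions. Recovery precision degrades roughly in
proportion to 1/v_slope — shallow observers pin the zero-crossing of a
nearly flat drift line.

## Quality control

Trials with rt < 150 ms are removed first (strict inequality: exactly 150 ms
is kept). Participant inclusion then requires ≥ 80% correct on the two most
extreme morphs, where correct means happy at s = 1 and angry at s = 15,
pooled over both extremes (the weaker, more inclusive reading; a per-morph
minimum mode is available by config). A participant with no extreme-morph
trials is flagged indeterminate, never silently passed. Counts always
reconcile (kept + removed = input) and the RT filter is idempotent.

## Group psychometrics (4PL)

The group curve is the mean over participants of per-participant
proportion-angry per morph, fitted with a 4-parameter logistic
p(s) = γ + (λ−γ)/(1 + e^{−β(s−x₀)}); the free lower and upper asymptotes
implement the inflection's adjustment for the maximum probability of either
judgment. Fitting is least squares with a 7-point multi-start grid on x₀;
the default is unweighted on the group means, with binomial weighting by
trial counts available. Standard errors come from the Gauss-Newton
covariance (JᵀJ)⁻¹·RSS/(n−4); note this assumes homoscedastic residuals —
under binomial noise, whose variance peaks exactly at the inflection, the
x₀ SE can understate the sampling SD, so group comparisons should use
curves with comparable designs. Two group inflections are compared by Wald
t = (x₀_A − x₀_B)/√(se_A² + se_B²); the reference degrees of freedom for the
p-value are a reporting convention not derivable from the group sizes and
default to 50, exposed in configuration.

## Group statistics

Correlations are Pearson on pairwise-complete observations; the Bonferroni
family for the metric-by-clinical-measure table is the full set of emitted
cells (2 metrics × 4 measures = 8 by default) and the family size is always
reported next to p_adj, since the appropriate family is a reporting choice.
The diagnostic analysis is a classical one-way ANOVA (between/within
decomposition, df = k−1, N−k; listwise deletion) with pooled-SD post hoc
pairwise t tests (common MSW, df = N−k; Welch mode available), Bonferroni
corrected over the k(k−1)/2 pairs. Groups of size 1 raise an error naming
the group. The age–sensitivity replication correlates age with fitted
sensitivity after excluding healthy participants, reporting the retained n.

## ROI morph contrasts

Valence and ambiguity are coded by a linear contrast proportional to s − 8
and a quadratic contrast proportional to (s−8)² minus its mean. Centering the
quadratic orthogonalises it to the linear term so the two coefficients are
separately interpretable; both are normalised to unit sum of squares so
coefficients are comparable across ROIs (only sign and centering are
externally fixed; the normalisation is this package's convention). Per
participant, the 15-beta profile is projected onto the two contrasts plus an
intercept; residuals are orthogonal to both regressors to 1e−10. The linear
coefficient is associated with a symptom score by Pearson correlation, with
median-split group means emitted for plotting (ties at the median go high).
Voxelwise mixed-effects modelling, covariates and cluster correction are
out of scope; this module operates on ROI summaries only.

## Synthetic-data generator

The generator defines the conditions under which everything above is tested.

**Schedules.** 15 morphs × 30 presentations plus 90 fixation-only events
(540 events) over 4 runs, split 113/113/112/112 stimuli and 23/23/22/22
fixations (the per-run split is not externally fixed; this one balances run
lengths). Each event occupies a 0.4 s slot (150 ms face + 250 ms mask);
ITIs are 0.5 s + Exponential, with the exponential mean set per run so the
expected run duration, including 10 s lead-in and lead-out fixation, is
421 s. Only the 500 ms floor and the ~421 s run length constrain the decay
parameter; the calibration above is the package's choice.

**Observers.** True s_indiff ~ N(group mean, group SD) with the DMDD
(7.52, 0.95) and healthy-control (8.48, 1.40) moments; ADHD, anxiety and ODD
groups have no reported moments and default to intermediate invented values
(8.20, 1.20). v_int is then −s_indiff·v_slope. Nuisance parameters:
v_slope ~ LogNormal(median 0.25, sdlog 0.2), a ~ N(1.2, 0.2) truncated to
[0.6, 2.5], zᵣ ~ N(0.5, 0.05) clipped to [0.2, 0.8], t₀ ~ N(0.25, 0.05) s
clipped to [0.1, 0.5]. The sensitivity scale was set so that generated
observers are consistent with the cohort the QC rules admit: at the default
a, an observer needs a·|v(1)| ≳ 1.4 (v_slope ≳ 0.17) for ≥ 80% extreme-morph
accuracy, so a median of 0.25 puts typical extreme accuracy near 0.89;
markedly shallower defaults would generate cohorts the pipeline's own
inclusion rule rejects. All distributions are exposed in `GroupSpec`.

**Clinical cohorts.** Child and parent SCARED (41 items) and ARI (6 items),
items scored 0/1/2 — inferred from the instruments' printed maxima
(41×2 = 82, 6×2 = 12) — by thresholding latent normals at equal-mass
(tercile) cutpoints. Each scale's items load λ = 0.9 on a scale-level latent
trait (matching the instruments' published internal consistencies of
α ≈ 0.9); the four traits are jointly Gaussian. Discretisation attenuates
correlations, so the latent correlations are de-attenuated analytically:
the item-mean function m(θ) is expanded in probabilists' Hermite
polynomials (odd orders only, by symmetry of the tercile cutpoints), giving
closed-form total-score variances and cross-covariances as power series in
the latent correlation, which are inverted per pair by root finding. The
achieved total-score correlations at n = 10⁴ sit within ±0.01 of the
targets (0.58 anxiety cross-informant, 0.56 irritability cross-informant,
0.46/0.50 cross-measure within informant). The two
cross-informant-cross-measure cells have no reported values and default to
0.35. Targets with |r| above the post-discretisation ceiling, or producing
a non-PSD latent matrix, raise before any sampling. Ages are uniform on
[8, 22]; diagnoses are drawn from the reported sample proportions
(27:23:19:2:24). Clinical scores are generated independently of the DDM
parameters — the null configuration, matching the absence of reliable
metric–symptom associations; couplings can be added downstream.

**ROI betas.** profile = intercept + (base_slope + coupling·z_symptom)·linear
+ base_quad·quadratic + N(0, noise_sd) on the unit-norm contrasts.
`coupling_for_target_r` converts a desired coefficient–symptom correlation
into the coupling (expected r = c/√(c² + noise_sd²)).

**What the generator does not emulate** — hence what passing tests do and do
not show about real data: no trial-to-trial parameter variability, lapses,
omissions or contaminant RTs; no session effects (fatigue, learning); no
dependence of questionnaire scores on diagnosis or on behavioral parameters;
ROI noise is iid Gaussian rather than spatially/temporally structured fMRI
noise. Recovery results therefore demonstrate correctness of the estimation
machinery under the model, not robustness to model misspecification.

## Problem sizes and reproducibility

The recovery benchmarks use cohorts of 27 (DMDD-like) and 24 (control-like)
observers at 450 trials each, a 50-observer precision suite, 4PL fits at
27×30 and 24×30 presentations per morph, and a 10⁴-row clinical cohort —
the study-scale designs for the behavioral analyses. All generators,
simulators and fitters are pure functions of explicit seeds; the pipeline
derives per-stage and per-participant substreams from one master seed by
hashing, stamps every artifact with the config hash and seed, and writes
numeric tables with a fixed float format so identical (config, seed) runs
are byte-identical.

## Known limitations

* Maximum-likelihood DDM fits are sensitive to fast outliers; with the
  150 ms trial filter as the only guard, contaminated real data may need an
  explicit contaminant mixture, which is not implemented.
* The indifference point is poorly identified for near-flat drift lines
  (shallow sensitivity); its estimator is unbiased but heavy-tailed there.
* The 4PL x₀ standard error assumes homoscedastic residuals (see above).
* No hierarchical shrinkage: per-participant fits are independent, so
  group-level dispersion of fitted metrics overstates true dispersion by
  the recovery-error variance.
* The Euler simulator, even corrected, is a discretisation; tests budget a
  small residual bias term (0.004 at dt = 1e−3) on top of Monte-Carlo error.
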