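# Methods

`ctsyn` re-implements, as a tested library, the analysis chain used to
characterize corticothalamic (CT) synaptic transmission and visual attention
in VGluT1-hemizygous mice: quantal variance–mean analysis, short-term
plasticity model fitting, spontaneous/asynchronous EPSC statistics, 5CSRTT
behavioral scoring with TVA model fitting, rotation-null image
colocalization, and EM point-pattern morphometrics.  Because the raw
recordings behind the study's group results are not available, every
analysis stage is paired with a seeded synthetic generator that emulates its
input, and correctness is established by exact algebraic identities,
noiseless round-trip fits, and parameter-recovery experiments against the
generators.

## The release model (`synth`)

The simulator draws vesicle release from `N` independent sites, each with
initial release probability `p0`.  Facilitation is additive with two
components: after every pulse, state variables `f1`, `f2` gain fixed
increments `a1`, `a2` and decay exponentially between pulses with time
constants `tau1 = 99 ms` and `tau2 = 1.0 s` (the paired-pulse decay
constants).  The per-pulse release probability is `min(1, p0 * (1 + f1 + f2))`.
The increments are calibrated so that the pre-pulse steady state of each
component at 20 Hz equals the train-buildup amplitudes of the wild-type
fits (`B1 = 5.11`, `B2 = 2.42`): for inter-stimulus interval `D`,
`a_k = B_k (1 - x) / x` with `x = exp(-D/tau_k)`.  The per-pulse
micro-dynamics behind the fitted buildup envelope are not constrained by the
data; this additive-decay scheme is one standard choice that reproduces the
envelope's steady-state logic (`1 + B1 + B2`).

Depression has three ingredients:

* **site reoccupancy** — a site that released becomes empty and is
  reoccupied after an exponential delay (`refill_tau`, default 150 ms);
* **transmitter refilling** — a newly docked *recycled* vesicle fills with
  transmitter along `1 - exp(-t/transmitter_fill_tau)` (default 500 ms for
  wild type);
* **a finite reserve of full vesicles** (`pool_size`, default 600) —
  reoccupying sites draw full vesicles from the reserve, in order of
  reoccupancy, until it is exhausted; only afterwards do recycled,
  still-filling vesicles reach the sites.

The reserve is the package's own modeling choice: with site reoccupancy and
refilling alone, fill-state depression appears within a few vesicle turnover
times (hundreds of ms), whereas the phenomenon being emulated — depression
appearing seconds into a 20-Hz train, earlier in hemizygotes — requires an
initially full pool that drains at the release rate.  Because release rates
are higher in the hemizygous preset (higher `p0`) and refilling slower, the
same genotype-independent pool (consistent with the unchanged vesicle counts
seen ultrastructurally) produces earlier and deeper depression there.

Two depression modes implement the two mechanistic hypotheses for
under-filled vesicles: `partial_fill` (default) releases them with
proportionally smaller quantal amplitude; `reluctant` makes them
release-incompetent until fill reaches 0.95.

Quantal amplitudes are gamma distributed with shape `q_shape = 13.5`
(CV ~ 0.27, matching the fitted amplitude histograms) and mean
`q_mean = 5 pA`; `q_shape=None` disables quantal variability for analytic
binomial tests.  Quantal sums are convolved with a difference-of-exponentials
EPSC kernel (0.5 ms rise / 5 ms decay, peak-normalized — generic relay-cell
kinetics) and white Gaussian noise is added.  Setting `refill_tau`,
`transmitter_fill_tau` to zero disables depression entirely; then
`mean(EPSC_n)/mean(EPSC_1)` converges to the deterministic facilitation
sequence returned by `expected_facilitation`, and per-pulse means and
variances follow the binomial moments exactly.

**Presets.**  `wt`: `p0 = 0.051`.  `hemi`: `p0` scaled by the measured
release-probability ratio (×1.92 → 0.098), the slow facilitation increment
scaled by the measured slow-component ratio (×0.25), and the transmitter
refilling rate scaled to 71.1% (the measured 28.9% transporter reduction).
These presets reproduce the genotype contrast *directionally* (lower
steady-state and final facilitation, earlier 20-Hz depression, ~1.9× first
EPSC); the printed group means themselves depend on unavailable raw data and
are not quantitative targets.

**Seeding.**  Every generator takes one seed; repeats are seeded from
spawned `SeedSequence` children, so extending `n_repeats` never perturbs
earlier repeats, and all outputs are bit-reproducible.

## Membrane tests and stability screening (`traceio`)

Access resistance is `ΔV / I_peak` (peak baseline-subtracted capacitive
transient), input resistance `ΔV / I_ss` (baseline-subtracted steady-state
current over the last quarter of the step); the baseline is the mean of the
2 ms before the step.  Stability screening scans every consecutive window of
20–25 membrane tests, keeps windows whose access resistances all lie within
±15% (configurable; the emulated workflow states the criterion only as "stable") of
the window median, and returns the qualifying window with the smallest
coefficient of variation (ties: earliest, then longest).  The tolerance is
recorded with the result.

## EPSC amplitudes and plasticity fits (`stp`)

Amplitudes are the trace extremum in a 1–10 ms post-stimulus window
(truncated at the next stimulus and flagged) minus either the 2-ms pre-pulse
baseline or, for trains at ≥ 10 Hz, the exponential extrapolation of the
preceding EPSC's decay.  Facilitation is `EPSC_n / EPSC_m1` with `EPSC_m1`
the mean first-EPSC amplitude across the protocol's conditions, making the
series invariant under uniform amplitude scaling.

`fit_ppf_decay` fits `F(PPI) = 1 + Σ A_i exp(-PPI/τ_i)` with bounded
multi-start least squares (8 log-spaced τ starts, fixed jitter RNG) and
selects one vs. two components by corrected AIC, requiring ΔAICc > 2 to
prefer the larger model; on noiseless curves the residual is floored at a
relative 1e-9 scale so the comparison stays finite.  `fit_train_buildup`
fits `F(t) = 1 + B1(1-e^{-t/τ1}) + B2(1-e^{-t/τ2})` over the first 2.5 s
with both time constants fixed (99 ms, 1.0 s); the model is linear in
(B1, B2), so the bounded fit is non-negative least squares, with parameter
SDs from the linear covariance.

`train_metrics` reduces a 20-s train to: *steady-state facilitation* — mean
F over the plateau, located as the longest run of pulses whose lightly
smoothed F lies within 10% of the highest level sustained for ≥ 5
consecutive pulses (the maximum of the rolling 5-pulse minimum).  Anchoring
on the sustained level rather than the single global maximum keeps a noise
spike or a 1–2 pulse early transient from displacing the plateau; the
smoothing window is ~1/40 of the train (3–9 pulses).  *Depression latency*
is the time of the first pulse of the final excursion below steady state
(`None` if F never ends below it); *final facilitation* is the mean of the
last 10 values.  How the emulated workflow chose its plateau region is not
specified; this rule is deterministic and re-assertable.

## Variance–mean analysis (`quantal`)

Per-pulse means and unbiased variances across 20–25 stability-screened
five-pulse trains are fitted with the origin-constrained parabola
`σ² = Q·I − I²/N`, which is linear in `(Q, 1/N)`; `P_R = I₁/(N·Q)`.
Amplitudes are handled as magnitudes internally; `N` is continuous; no
intrasite quantal-variance correction is applied by default (an optional
`quantal_cv` mode divides Q by `1 + CV²`).  Degenerate data are flagged, not
raised: all-zero variances (deterministic-release limit, `P_R → 1`) and
super-Poissonian curvature (`N ≤ 0`).

Two measurement conventions matter at realistic trial counts:

* amplitudes for the variance–mean table are read at a **fixed peak
  latency** located once on the across-train average, rather than by
  per-train extremum picking; extremum picking adds an extreme-value bias of
  order the noise SD to the small first-pulse amplitudes that anchor the
  parabola.
* the default fit is unweighted (mean-unbiased but high-variance at 25
  trains); the optional `n/σ⁴` weighting is markedly more efficient at
  25-train protocol sizes and is used in the recovery experiments, at the
  cost of a modest (~10%) downward finite-sample bias in Q.  Individual-cell
  estimates at 25 trains are intrinsically noisy and right-skewed — the
  first pulse releases ~1 vesicle on average, so its sample variance is far
  from chi-square — and medians across cells inherit a low bias of roughly
  10–20% (unweighted) or 5–15% (weighted).  This mirrors the precision
  attainable from the real protocol, not an implementation defect.

## Event detection and amplitude statistics (`events`)

Detection slides a difference-of-exponentials template (0.5/5 ms) along the
trace, fitting scale, offset, and a linear baseline slope at every offset;
the criterion is scale / residual SD, thresholded at 4 with a 2-ms
refractory.  The slope term keeps events riding on a preceding EPSC's decay
detectable, and a short template (one decay constant) keeps the criterion
impulsive enough to split close doublets; the normal matrix of the
three-term regression is constant, so the sliding fit reduces to three
convolutions.  Amplitudes are re-estimated at each detected onset by a
fixed-offset fit with the full-length template, because taking the scale at
the criterion maximum selects upward noise excursions (~ +15% bias at
SNR ~ 9).  Recall is merge-limited at high rates: events closer than the
refractory period are indistinguishable in principle.

Asynchronous-EPSC inclusion implements the stated rules: events during the
train or ≤ 100 ms after it, outside synchronous/artifact windows, magnitude
≤ 20 pA, single rising phase.  Multiple rising phases are declared when the
negative derivative has ≥ 2 local maxima above 4× the derivative-noise SD
(robust MAD estimate) separated by > 1 ms.  Gamma fits of amplitude
magnitudes use maximum likelihood with location fixed at zero (the estimator
of record); the reported goodness of fit is the least-squares residual
against the density-normalized histogram (1-pA bins, 0–25 pA), mirroring the
histogram-based statistic of the emulated workflow, whose exact definition is unstated and
not treated as reproducible.

## Behavioral scoring and the TVA model (`behavior`)

Scoring follows the task's formulas exactly — `% accuracy = C/(C+I)`,
`% omission = O/(O+C+I)`, `mean score = C/(C+I+O)` — grouped by stimulus
duration, with premature trials (which trigger trial repeats) tallied per
distractor condition and excluded from all denominators.

The TVA fit estimates `(t0, v, b, s_max)` by simultaneous least squares on
mean score and correct-response latency versus duration.  The exact curve
forms of the attention model's reference implementation are not reproduced in the
source text, so the default model gives the parameters exactly their stated
semantics: encoding is an exponential race at rate `v` starting after `t0`,
hence `MS(d) = s_max(1 − e^{−v(d−t0)})` for `d > t0` (else 0) and
`L(d) = b + t0 + E[X | X ≤ d−t0]` with `X ~ Exp(v)` (closed form
`1/v − w e^{−vw}/(1−e^{−vw})`).  Residuals of each curve are divided by that
curve's observed SD before stacking; multi-start over
`t0 ∈ {0, 0.1, 0.3}` × `v ∈ {0.5, 1, 2}`.  Note the truncated-exponential
latency is monotone in `d`, so the model cannot produce the elevated
latencies observed at the shortest (guess-dominated) duration; the model
family is pluggable and the default is recorded in the fit result.  The
generator inverts this model (correct iff encoded before offset, latency
`b + t0 + X` plus 50-ms motor noise); its optional `lapse` parameter adds
random-window touches, which the fitted family does not model, so recovery
experiments use `lapse = 0` and lapse runs probe robustness only.

## Colocalization (`imaging`)

Processing is per plane: rolling-ball background subtraction (radius 50 px),
thresholding (Otsu by default — the emulated workflow does not state its threshold method;
fixed override available and the method is recorded), one binary erosion
with a 3×3 cross (removing sub-single-pixel particles) then one dilation
(restoring a 1-px border), 8-connected labeling.  The colocalization
statistic is the mean partner-channel intensity inside the mask, compared
with the mean over the mask rotated 90°/180°/270° about the center of the
largest centered square crop — exact pixel permutations, no interpolation,
so a uniform channel gives null = masked mean bit-exactly.  The image
generator places Gaussian puncta (σ = 1.5 px at 0.156 µm/px, a
diffraction-limited punctum) at a controllable overlap fraction between
channels; at the emulated punctum density (83.4 × 10³/mm²) ~5–8% of puncta
merge under segmentation, so recovered densities sit slightly below truth.

## Ultrastructure (`ultrastructure`)

Annotations are continuous nm coordinates (membrane polygon, vesicle/gold
points, active-zone polyline on the membrane).  Area is the shoelace value
(via shapely, validity-checked); the maximum Feret diameter is the maximum
pairwise distance over convex-hull vertices (hull-attained, so non-convex
membranes are handled); point densities count boundary points as inside.
The active-zone distance profile takes, per point, the minimum perpendicular
distance over segments whose orthogonal foot lies within the segment —
points with no valid foot on any segment are excluded, distances are
magnitudes, and normalization divides by active-zone length.
Nearest-segment projection is adopted; whether the emulated workflow used a single
global projection axis is not fully specified.  Distribution comparisons are
standard two-sample KS (and Mann–Whitney in tests) via scipy.

The terminal generator uses perturbed ellipses (aspect 0.7, ≤ 3% low-order
radial perturbation) rescaled to a target Feret diameter (677 nm, 2%
lognormal jitter), Poisson point counts at fixed densities (defaults:
vesicles 150/µm², gold 40/µm² — plausible profile densities for tightly
packed CT terminals; the emulated study reports densities only
graphically), and an active zone covering 12% of the perimeter (≈ 219 nm).

## What the synthetic data do and do not show

The generators reproduce the statistical structure each analysis assumes:
binomial release with deterministic facilitation, Poisson event times with
gamma amplitudes, exponential-race trial outcomes, Gaussian puncta with
controlled overlap, uniform point patterns in simple polygons.  Real
recordings add what they deliberately omit: electrode/series-resistance
artifacts and drift, correlated (non-white) noise, mixed retinal/cortical
event populations, manual curation of events and annotations, optics beyond
a Gaussian PSF, and non-uniform vesicle clustering.  Passing recovery tests
therefore demonstrates correctness of the estimators under each method's own
assumptions, not robustness to every pathology of real data.

## Problem sizes

Recovery experiments run at the study's protocol sizes: 40 virtual cells ×
25 trains (variance–mean), 7 durations × 200 trials × 20 seeds (TVA), 60-s
traces at 8.3/12.4 Hz (detection), 123 vs 181 terminals (EM contrast),
images calibrated to 83.4 × 10³ puncta/mm² on 256-px frames, and 48-repeat
20-s trains for the genotype direction checks.  The full test suite and the
acceptance script each complete in about a minute.
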