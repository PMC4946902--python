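# Methods

This note documents the models implemented in `reachunc`, the defaults of
the synthetic-session generator, and the numerical and design choices a
user should know before trusting (or extending) the pipeline.

## Conventions

Angles are degrees on the canonical range (−180, 180] at every interface
(`wrap_deg`), radians internally. Concentrations are von Mises κ
(dimensionless); κ = 0 is the uniform circle. Rates are spikes/s; epoch
windows are half-open `[start, end)` in ms, aligned either to target onset
or movement onset. Spike times are stored once, relative to target onset;
movement-aligned analyses subtract the per-trial latency.

"Angular dispersion" is not uniquely defined in the field; here it is the
circular standard deviation `sqrt(−2 ln R)` in degrees, where R is the mean
resultant length. The circular variance `1 − R` is exposed separately. Both
are monotone in R, so cross-session correlations are insensitive to the
choice. The mean direction is flagged undefined when R < 1e−9 (antipodal
cancellation would otherwise yield a noise-driven direction).

## Behavioral model

The observer combines a von Mises prior over target direction (mean μ₁,
concentration k₁) with a von Mises likelihood centered on the displayed cue
centroid (μ₂, k₂). The product of the two kernels is again a von Mises
kernel whose resultant vector is the sum of the component vectors, so the
posterior mean is exactly

    μ₃ = μ₁ + atan2(k₂ sin(μ₂ − μ₁), k₁ + k₂ cos(μ₂ − μ₁))

The fit minimizes the sum of squared *wrapped* residuals between μ₃ and the
observed reaches over the ratio r = k₁/k₂, with the experimenter-known cue
centroid substituted for μ₂ and the true prior mean for μ₁ (any systematic
internal bias folds into residual dispersion). Predictions always use the
exact product-mean form; the linear slope w = k₂/(k₁+k₂) = 1/(1+r) is
reported as the summary metric. The linearization agrees with the exact
form within 1° for |μ₂ − μ₁| ≤ 45° and w ∈ [0.2, 0.8] (regression-tested).

Numerics: the objective is evaluated on a 1,000-point grid over
log r ∈ [−6, 6] (w ∈ [0.0025, 0.9975]) and refined by golden-section
search. The 1-D grid is cheap, avoids local minima, and bounds the
infinite-ratio degeneracies; fits pinned at a bound are flagged
(`at_bound`), as are unidentifiable fits (all centroids equal). At a bound
the residuals contain (1 − w) ≈ 0.25% of each centroid offset, so the SSE
of a "perfect" cue-follower is small but not zero.

Session metrics: Δcue weighting = w_high − w_low;
Δbehavioral uncertainty = dispersion_high − dispersion_low (degrees).

## Tuning model

Counts per trial in an epoch follow a Poisson GLM with log link and the log
epoch duration as exposure offset, linear predictor
α + b₁ cos θ + b₂ sin θ; β = hypot(b₁, b₂), θ* = atan2(b₂, b₁). α is in
log spikes/s so epochs of different lengths are commensurable. The
log-likelihood is concave; a damped Newton solve (backtracking line search,
gradient tolerance 1e−8) is used rather than an external GLM library
because bootstrap significance needs ~10⁴–10⁵ refits, which are run as a
batched Newton across resamples; a statsmodels GLM cross-check is in the
test suite. β < 1e−6 marks the PD unstable (untuned neuron).

Significance: trial-resampling bootstrap (with replacement, same n,
unstratified by direction; default n_boot = 1,000, 100 minimum). A neuron
is tuned when ≥ 95% of bootstrap PDs lie within `criterion_deg` (default
45°, relaxable to 90° for low-count datasets) of the circular mean of the
bootstrap sample. Refit failure above 10% of resamples flags the neuron
unfit. PDs are computed per epoch on the zero-uncertainty center-out block
and used epoch-matched downstream; neurons without significant tuning in
the analyzed epoch are excluded from that epoch's analyses.

## Population analysis

Groups are assigned per trial from offset = wrap(PD − reach): SD for
[−45°, 45°), OD for [135°, 180°] ∪ [−180°, −135°), ORTH otherwise —
half-open boundaries make the labels tile the circle (90/180/90 over
integer offsets). Baseline is the [−300, 0) ms pre-target rate. Group rate
deltas average, per neuron, the baseline-subtracted window rate over the
trials where the neuron is in the group, per condition; the session delta
is the group mean of (high − low), with a trial-resampling bootstrap 95%
CI. Baseline subtraction is the default throughout (config-switchable).

The cross-session regression is unweighted OLS of the group delta on
Δbehavioral uncertainty (slope in spikes/s per degree, two-sided p for
slope ≠ 0); the headline window is 500–700 ms after target onset, and a
sliding variant covers the visual window plus 100 ms steps through delay
and movement with epoch-matched PDs. The subsampling analysis computes the
three pairwise correlations (ΔOD vs Δuncertainty, ΔOD vs Δweighting,
Δuncertainty vs Δweighting) over unique random session subsets; extreme
subsets that maximize/minimize the metric-metric correlation are found by
greedy swap search from random starts (the selection method is otherwise
underdetermined). Spatiotemporal maps default to 16 offset bins × 20 ms
time bins, unsmoothed.

## Decoder

Neurons are assigned by center-out PD to sixteen 22.5° bins. Per trial, the
baseline-subtracted rates are averaged within bins; empty bins are excluded
rather than imputed, and ≥ 8 occupied bins are required. A cosine
a + b cos(φ − φ₀) is least-squares fit over the occupied bin centers; φ₀ is
the decoded direction (undefined when the fitted amplitude < 1e−9).
Performance = 1 − circular variance of the decode errors = the mean
resultant length of the error sample (identity asserted in tests). The four
analysis windows are three consecutive 200 ms target-aligned windows plus a
movement-aligned [0, 200) ms window (exact edges are a package default, not
an experimental given). A session is `included` in cross-session
comparisons only if its low-uncertainty performance exceeds 0.5 in every
window; condition effects are paired t-tests on low-minus-high performance.

## Synthetic generator: what it emulates, and what it does not

A session = 80 center-out trials (8 targets × 10) plus 150 low- and 150
high-uncertainty trials by default. Timeline per trial: recording from
300 ms before target onset; go cue 700–1,000 ms after the target
(instructed delay); reaction time ≈ 250 ± 30 ms (+10 ms under high
uncertainty); recording ends 300 ms after movement onset. Peak speed
carries a small (+0.3 cm/s) high-uncertainty shift so the kinematic
controls have something to reverse.

Behavior: targets ~ vM(prior mean, κ = 2); cue lines (5 per trial) ~
vM(target, κ_low = 10 / κ_high = 2). The observer aims at the product mean
of its internal prior (κ = 3) and a likelihood on the cue centroid whose
effective concentration folds in the line count (k₂ = n_lines ×
subjective per-line κ). Two noise sources disperse the reaches:

- **decision noise** — the reach is sampled around μ₃ with the posterior
  concentration k₁ + k₂ (probability matching). This is what makes residual
  dispersion condition-dependent: a less reliable cue widens the posterior
  and the reach scatter. Without it the fit residuals would be pure motor
  noise and the high/low dispersion difference would vanish identically.
- **motor noise** — fixed vM(κ = 100, ≈ 5.7° SD).

The residual resultant length is the product of the two component resultant
lengths, giving a closed-form expected dispersion per condition (used for
ground truth and for solving generator parameters).

Spiking: piecewise-constant inhomogeneous Poisson rates per trial —
baseline (3–15 spikes/s) before the target and during a 50 ms visual
latency; epoch rates baseline × exp(β cos(reach − PD)) with per-epoch β
(visual 0.5–1.5, delay 0.5–1.5, movement 0.8–2.0); PDs uniform. In
high-uncertainty trials, premotor-like neurons add
od_gain × (1 − cos(PD − reach))/2 spikes/s from 250 ms after target onset
through the movement segment: zero at the reach direction, maximal opposite
it, and strictly additive (uncertainty only ever increases rates).
Motor-cortex-like neurons get no gain. The early visual-burst suppression
seen under high uncertainty in the real data is *not* modeled, so
visual-window properties are asserted only as "no planted gain".

Studies: each session draws a target Δbehavioral uncertainty uniformly from
2–30° (the feasible ceiling given its prior/motor draws caps it) and the
subjective high-condition cue κ is solved numerically to produce it.
Subjective prior κ ~ U(1.5, 5), subjective low-condition per-line κ ~
log-U(1.5, 10) and motor κ ~ U(60, 150) also vary per session; the
low-condition variation matters because it keeps Δcue weighting only
moderately correlated with Δuncertainty across sessions (|r| ≈ 0.7 rather
than ≈ 1), which is the premise of the metric-subsampling analysis.
The planted gain law is linear in the *OD-wedge average* of the gain:
mean OD gain = max(0, a × Δuncertainty + ε), ε ~ N(0, 0.8 spikes/s),
default a = 0.15 spikes/s per degree. The 180°-offset amplitude is
therefore mean gain / 0.9502 (the wedge average of (1 − cos)/2); defining
the law on the wedge-average scale makes the generating slope of the
cross-session OD regression equal a, which is what the recovery tests
check. Prior means alternate 0°/90° across sessions so the
shared-prior-direction control has two groups.

What a green recovery test establishes: that the estimator chain (tuning →
grouping → rate deltas → regression) is unbiased and calibrated *under the
generator's assumptions* — cosine tuning, Poisson spiking, additive
(1 − cos)/2 gain, stationary rates within segments. Real data violate all
of these to some degree (non-Poisson variability, non-cosine tuning,
rate drift, correlated noise across neurons); green tests say nothing about
those failure modes.

## Known limitations

- The OLS regression ignores measurement error in Δbehavioral uncertainty
  (~2° SE at 150 trials/condition), so recovered slopes carry a small
  (~5–7%) attenuation; the recovery criterion absorbs this within its CI.
- Decision noise is a modeling addition (probability matching), not an
  experimentally measured quantity; alternative noise models (e.g. internal
  misperception of individual cue lines) would produce different
  dispersion–concentration relationships.
- Sessions are independent; neuron identity is never tracked across
  sessions, and neurons shared across same-day blocks would be treated as
  independent samples.
- No within-trial dynamics: the planted gain is static after onset, so the
  pipeline cannot distinguish maintained from transient uncertainty codes.
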