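# Methods

This note records the models the package implements, the defaults it
ships, the numerical choices behind them, and what the synthetic-data
studies in the test suite do and do not establish.

## The design and its nonparametric signatures

The stimulus space crosses three levels of lip height (x, bottom face
half) with three levels of eye separation (y, top half). The target
category is the conjunction x ∈ {x1, x2} AND y ∈ {y1, y2}; the remaining
five stimuli form the disjunctive contrast category (redundant x0y0,
interior x1y0/x0y1, exterior x2y0/x0y2). Within the target category the
distance of each level from the decision bound manipulates
discriminability (L = near, H = far), giving the 2 × 2 double-factorial
cells LL, LH, HL, HH.

The mean interaction contrast (MIC) is the double difference of correct
mean RTs over those cells; the survivor interaction contrast (SIC) is the
same double difference applied to the empirical survivor functions
S(t) = P(T > t). Because the empirical survivor functions are step
functions with jumps exactly at the sample points, the package evaluates
the SIC on the pooled unique RTs prefixed with 0, where the
piecewise-constant integral equals the MIC identically (the test suite
asserts agreement within 1% of the RT range on random datasets; observed
agreement is at machine precision).

Statistical machinery around the SIC:

* **Stochastic dominance** is checked with the eight directional
  two-sample Kolmogorov–Smirnov tests in the canonical order (the four
  expected orderings, then their reversals); the verdict requires the
  first four significant and the last four not, at a configurable α
  (default .05).
* **Deflection tests.** D+ = max SIC(t), D− = |min SIC(t)|. Their null
  distribution is generated by permuting the H/L labels independently
  within each dimension across trials (marginal sample sizes preserved),
  which destroys the factorial structure while keeping the pooled RT
  distribution fixed. 2000 permutations by default; p-values use the
  add-one convention.
* **Bootstrap bands** on the SIC resample each item's RTs with
  replacement (default 1000 replicates, pointwise 95% percentile
  envelopes, seeded).
* **Classification** maps (SIC shape, MIC significance, interior-vs-
  exterior pattern) to architecture labels by a deterministic rule table,
  emitting multiple labels where the evidence is ambiguous. Shape tokens
  are computed from the deflection tests: "positive" if only D+ is
  significant, "mostly-negative" if only D−, otherwise "s-shaped"
  (suffixed "-mostly-positive" when positive area exceeds twice the
  negative area); an S shape with *both* deflections significant is
  flagged and classified as Coactive/Serial ST, the ambiguous reading.

Correct trials only enter the MIC/SIC/ANOVA/contrast tests; error RTs are
handled by the parametric models. RT trimming is single-pass: drop
RT < 200 ms, then drop RTs strictly above mean + 3 SD computed per
(participant, stimulus) cell on the floored data. The fence is not
iterated; pooling correct and error trials in a cell avoids emptying
sparse error cells.

## The logical-rule models

Perception of each dimension is a Gaussian with mean fixed at the
stimulus's psychological coordinate (fixing the means identifies the
drift rates) and a free per-dimension SD. The mass of the perceptual
distribution on each side of a free decision bound supplies the drift
rates of a two-accumulator linear ballistic accumulator race: start point
∼ Uniform(0, A), rate ∼ Normal(v, s), finishing time (b − start)/rate,
the faster accumulator determining the response and decision time, plus a
non-decision time t0. Target and contrast accumulators share thresholds
across channels (one b_target, one b_contrast). Trials on which both
sampled rates are non-positive redraw the rates, conditioning the race on
at least one finishing accumulator.

Compositions: serial self-terminating (first channel — lips with
probability p_x — stops processing on contrast evidence, otherwise the
second channel decides and channel times sum); parallel self-terminating
(contrast at the earliest contrast resolution, target when both channels
resolve target, at the slower channel's time); coactive (a single race
whose target drift is the bivariate-normal mass in the conjunctive
region); a trial-level Bernoulli(p_serial) serial/parallel mixture whose
parallel component carries its own start range A_parallel and inflated
perceptual SDs m·σ; serial and parallel contaminant mixtures (probability
p0 of a uniform RT over the condition's observed range with a fair-coin
response — the response rule for contaminants is a modelling choice, as
only the RT distribution is constrained); and a free-drift model with one
drift per stimulus and no perceptual front end.

### Default parameterization

The packaged defaults place the three levels of each dimension at
coordinates (0, 1.25, 2.5) with unit perceptual SD and bounds at 0.5, so
the standardized distances of the target levels from the bound are 0.75
(L) and 2.0 (H) — the regime of a threshold-calibrated design — and
A = 300, b = 1500 (both thresholds), s = 0.1, t0 = 250 ms.

Two regime effects are worth recording because they shape what the
architecture signatures look like in finite samples:

* **Drift-rate noise and the mean RT.** Because LBA finishing times are
  (b − start)/rate, sampled rates near zero produce arbitrarily long
  trials; once s is large enough that both accumulators' rates are
  simultaneously near zero with non-negligible probability, the mean RT
  of the slow cells is dominated by tail draws and the MIC becomes
  unstable (and, under the task's 5000 ms response deadline, censoring
  biases the serial MIC negative). The default s = 0.1 keeps the race out
  of that regime while producing item error rates (≈1–12%) inside the
  empirically observed range.
* **Selection by correct responses.** Conditioning on correct responses
  preferentially discards slow trials in cells with competitive error
  accumulators. In the coactive model this selection *reverses* the
  positive-MIC signature once error rates grow past roughly 15–20%; the
  signature analyses therefore presuppose moderate error rates, which the
  defaults provide.
* **Deflection power.** A clean generator at 400 trials per item has the
  power to detect the serial SIC's genuinely nonzero deflections (the S
  shape has real positive and negative extrema; only its *integral* is
  zero) and the coactive SIC's real early dip. Non-significant
  deflections for those architectures in empirical work reflect
  human-scale noise, not a property of the statistics; the tests
  therefore assert the regime-stable patterns (serial: equal areas and
  MIC ≈ 0; parallel: only D− significant; coactive: D+ significant).

## Simulation-based inference

The PDA likelihood simulates n_sim (response, RT) pairs per stimulus,
splits them by response, and forms defective densities: the class
proportion times a Gaussian KDE of the class RTs (Silverman bandwidth,
512-bin binned evaluation padded by four bandwidths, linear
interpolation, density floor 1e-10). Fresh simulation noise is drawn at
every evaluation, making the sampler pseudo-marginal; at the reference
size n_sim = 50,000 the estimator's SD on a 3600-trial dataset is below 2
log-units.

DE-MCMC proposes θ* = θ_i + γ(θ_j − θ_k) + ε with γ = 2.38/√(2d) and
ε ∼ U(−0.001, 0.001), Metropolis-accepted under uniform priors (σ:
(0.01, 5); bounds: coordinate span ± 2; A, A_parallel: (0, 3000); b:
(1, 5000); s: (0.05, 1); t0: (50, 1000) ms; probabilities: (0, 1); m:
(0.1, 10); ν: (0, 1)). With a noisy likelihood the sampler optionally
re-estimates the current chain's likelihood alongside each proposal
("refresh", on by default in the model interface), which prevents chains
from sticking to lucky overestimates at twice the evaluations.

**Initialization.** The posterior landscape has a strong ridge between
the perceptual SDs and bound positions (drifts depend on them only
through the standardized distances) and a mimicry mode in which a pure
serial model with a wide start-point range imitates the serial–parallel
mixture. Chains started from diffuse prior draws do not reach the
dominant mode in any tractable number of iterations. `fit()` therefore
initializes at an approximate maximum-likelihood point: the simulation
seed is frozen (common random numbers make the PDA surface
deterministic), the perceptual parameters are searched in
standardized-distance coordinates, and a multistart L-BFGS-B pass from
moment-informed starting points (t0 below the fastest RT, thresholds near
the implied mean decision time, free drifts near observed response
proportions) is polished by Powell; chains start from a log-normal cloud
around the result. This is data-driven initialization only — the
posterior is still sampled by DE-MCMC under the stated priors.

Model comparison uses DIC = D̄ + 2 p_D with p_D = D̄ − D(θ̄), θ̄ the
posterior mean, and weights w_i ∝ exp(−ΔDIC_i/2). The pseudo-marginal
noise inflates D̄ (and hence p_D) by a roughly model-independent amount
at matched n_sim, so DIC *differences* remain meaningful at scaled-down
settings while absolute p_D values overstate complexity.

### Problem sizes used by the packaged studies

The recovery and selection studies in the test suite run at deliberately
scaled-down sizes chosen as a point on the accuracy/runtime curve:
400 trials per item per synthetic participant; PDA with n_sim = 4000
(recovery) or 2000 (selection); 24 (recovery) or 16 (selection) chains
for 90–150 iterations after MAP initialization with 4–10 starts. At
these sizes a mixed serial–parallel fit takes on the order of a minute on
one CPU; reference-scale fits (n_sim = 50,000, thousands of iterations)
estimate the same quantities with tighter posteriors. The acceptance
script's architecture signatures use 50,000 trials per item.

## Confirmatory MDS

Ratings (1–8) map to dissimilarities as 9 − rating, the simplest
order-reversing transform; the per-participant INDSCAL weight absorbs
scale. The model distance is w_p · (Σ_dim |Δ|^r)^(1/r) with shared
coordinates: free-monotone (16 parameters, first stimulus anchored at the
origin, coordinates increasing with physical level within every row and
column, enforced by exponential-increment reparameterization) or
constrained-grid (4 parameters). Weights are constrained to geometric
mean 1 so the coordinate scale is identified, but one parameter per
participant is still counted in k. Free metric exponents live in [1, 5]
via a scaled logistic. The SSD is minimized by multi-start L-BFGS-B
(default 20 restarts, tolerance 1e-8); BIC = n·ln(SSD/n) + n(1 + ln 2π) +
k·ln n from the concentrated Gaussian likelihood — comparable only within
a dataset.

The synthetic rating generator is a stand-in (no generative model of
human similarity ratings is implied): clamp(round(9 − slope·w_p·d + ε)).
Its defaults make the map the exact inverse of the analysis transform and
keep expected ratings inside the scale, because end-of-scale clamping
censors long distances and biases the apparent metric exponent upward —
with heavy censoring a Euclidean generator is best fit by r ≈ 2.5.

## Signal detection

Equal-variance Gaussian SDT with "different" as signal: d′ = z(H) − z(F),
c = −(z(H) + z(F))/2, extreme rates pulled in by 1/(2N). The generator
places the response threshold at d′/2 + c so the indices recover the
generating parameters exactly in expectation, and a liberal shift toward
"different" yields negative criteria. The 2 × 2 repeated-measures ANOVA
is computed from the classical within-subject contrast decomposition
(each effect tested against its participant-by-effect term), which stays
exact on degenerate inputs where general-purpose RM-ANOVA routines return
0/0 artifacts; it is cross-checked against statsmodels' AnovaRM on
non-degenerate data in the tests.

## What the synthetic studies do and do not show

The generators emulate the designs' structure (stimulus grid, trial
counts, sessions 2–8, rating scale, congruency × alignment cells) with
clean, stationary observers: no fatigue or learning beyond an optional
linear session effect, no lapses unless a contaminant architecture is
chosen, no inter-participant parameter variability unless supplied.
Passing tests establish that the statistics and fits recover the
properties of data generated by the models they assume, at the stated
sizes — not that human data satisfy those assumptions. Session indices
are assigned uniformly at random, so session is noise in the target
ANOVA unless the session slope is enabled.

## Known limitations

* The serial/parallel channel logic resolves "target" or "contrast" per
  channel from race outcomes, so a channel can self-terminate on an
  erroneous contrast resolution; idealized textbook predictions that
  assume noise-free channel outcomes (e.g., exact interior/exterior
  equivalences) hold only approximately.
* DIC's effective-parameter term is inflated under pseudo-marginal noise
  (see above); use matched n_sim when comparing models.
* The MAP initialization is a heuristic; on badly misspecified data the
  search can land in a local mode, and longer chains from multiple
  initializations are the remedy.
* Absolute BIC values from the MDS module depend on the concentrated
  Gaussian convention and are not comparable across datasets.
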