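# Methods

This note records the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Dive parsing and kinematic features

Dives are maximal runs of samples at or below the surfacing threshold
(0.5 m) whose depth exceeds 1 m, extended by one sample on each side to
the bounding surface samples; runs shorter than 4 s or starting within the
300-s post-tagging exclusion window are discarded. Ties at the boundary
resolve toward the longer dive (the boundary sample is shared when two
dives touch). The bottom phase is the contiguous span from the first to
the last sample at ≥ 70 % of maximum dive depth — deliberately *not* the
union of all supra-threshold samples, so every dive has exactly three
contiguous phases and a V-shaped dive has a single-sample bottom.

Jerk is the Euclidean norm of the first difference of triaxial
acceleration multiplied by the sampling rate (m/s³), timestamped at the
leading sample. The jerk peak feature is a **ratio**: phase maximum over
the deployment-wide median (surface periods included, since the median is
a deployment-level normalizer). A ratio rather than a difference keeps
the feature scale-free across tags sampling at 50–250 Hz; the alternative
subtraction form is a one-line change in `phase_features` if ever needed.
Roll at jerk peak is |roll| at the sample opening the interval that
attains the maximum. Circular variance is 1 − R̄ with R̄ the mean
resultant length; all phase samples are used (no decimation).

## Acoustic classes and time budgets

Clicks are classed by the interval to the preceding click: buzz < 11 ms,
fast 11–100 ms inclusive on both edges, slow > 100 ms (band edges carry a
1-ns float tolerance). The inclusive-fast choice for exact 11/100-ms
intervals is a convention; real ICIs are continuous and never sit on the
boundary. A train breaks at gaps > 2 s so silences between bouts are not
read as slow clicking; the first click of a train inherits its successor's
class, and an isolated click is slow (its neighbors are farther away than
any slow ICI). Searching time sums dives containing slow clicks and
nothing else — a clickless dive is not searching, and no smoothing across
adjacent dives is applied. Travel/rest time sums silent non-capture dives
shallower than 30 m. Surface-period clicks are retained but enter no
dive-level budget.

## Capture calibration

Acoustic confirmation requires buzz **and** handling sounds (buzzes alone
occur in unsuccessful pursuits); `require_handling=False` relaxes this.
Thresholds are the componentwise minima over confirmed dives' best-phase
triples, where the best phase is the one with the largest jerk peak.
Componentwise minima are the unique maximal thresholds guaranteeing 100 %
sensitivity on the confirmed set; the false-positive rate is then a
*measured property* of the data, reported but never tuned toward any
particular value. Calibration statistics use only dives ≥ 50 m, where
acoustic confirmation is reliable; classification applies to every dive.
A dive is a capture when *some* phase passes all three thresholds
(inclusive comparisons). Requiring the three features to co-occur within
one named phase across dives was the plausible alternative; the any-phase
rule was chosen because a capture can fall in any phase, and the best
phase is identified per dive anyway.

## Track reconstruction

Dead reckoning advances the position by speed · cos(pitch) · Δt along the
heading each sample, on a local equirectangular tangent plane (deployment
extents of a few km make great-circle machinery unnecessary), decimated
to 1 Hz. The speed model is a constant 1.5 m/s default, optionally
overridden per sample by |depth rate| / |sin(pitch)| where |pitch| > 30°
(`speed_from_depth_rate`). GPS forcing distributes each inter-fix
residual linearly in time; the corrected track's grid includes the fix
times themselves, so it is exact (< 1e-9°) at every fix even under later
interpolation, with constant offsets applied before the first and after
the last fix. Bathymetry lookup is nearest-cell (no bilinear
interpolation: the source grids' 15-arc-second cells exceed the residual
track error), with exact cell-boundary coordinates assigned to the
lower-index cell.

## Mixed models

Families: Poisson; NB1 with Var = μ(1+α) (α estimated jointly by ML);
beta with logit link and precision φ, optionally log-linear in a
dispersion factor; Gaussian. Offsets (log duration for deployment-hour
exposure; √cumulative searching time where searching is the exposure)
enter the linear predictor with coefficient 1 as stated — the √ scale is
unusual but kept for fidelity to the modeled protocol. Boundary
proportions are squeezed by y′ = (y(n−1)+0.5)/n before beta fitting.

Non-Gaussian families with one random intercept are fitted by maximum
likelihood with **adaptive Gauss–Hermite quadrature** (15 nodes default):
per group, a damped Newton search finds the posterior mode of the
intercept, and the integral is evaluated on mode-centered scaled nodes in
log space. The marginal likelihood was validated against brute-force
`scipy.integrate.quad` marginalization (agreement ~1e-9) and the fits
against lme4 (nAGQ 15, agreement ~1e-5 in coefficients) and glmmTMB
(~1e-3, the residual being its Laplace approximation). The likelihood is
stable in the node count (|Δlog L| < 1e-4 between 9 and 15 nodes at
cohort size). σ → 0 is handled explicitly: below 1e-8 the likelihood is
the plain GLM likelihood, the boundary variance is reported as 0, and no
curvature in σ is inverted. Note that lme4's printed `logLik` for Poisson
GLMMs differs from the true marginal log-likelihood by a data-dependent
constant; AIC values here use the full likelihood and are comparable only
within the package.

Gaussian responses use statsmodels `MixedLM`: REML for reported fits,
with one grouped intercept or two crossed intercepts via variance
components; likelihood-ratio comparisons always refit by ML (REML
likelihoods are not comparable across fixed structures).

Standard errors come from the observed information (central finite
differences of the negative log-likelihood at the MLE); Wald z and normal
p-values are reported for non-Gaussian families, t-based values for
Gaussian. AIC = 2k − 2 log L with k counting fixed effects, variance
components, and dispersion parameters.

Random-structure selection fits the candidates by ML and, among those
within ΔAIC ≤ 2 of the minimum, keeps the fewest-parameter model (ties:
fewer random factors, then listed order). Single-term deletion removes,
at each round, the least significant droppable term with LRT p ≥ 0.05,
never dropping a main effect while its interaction stands (marginality).
Pairwise contrasts are differences of estimated marginal means on the
link scale over the full factorial reference grid (numeric covariates at
their means; offsets cancel), with single-step familywise adjustment
computed from a seeded 200 000-draw Monte-Carlo sample of the joint
normal of the contrasts — equivalent to the studentized multivariate-
normal adjustment to ~2e-3, and verified against multcomp::glht. The
overdispersion check simulates the fitted model (random intercepts
redrawn), recomputes the posterior modes for each simulated response, and
compares Pearson dispersions conditionally — simulations are conditioned
exactly like the observed data, otherwise shrinkage biases the ratio.

## Synthetic deployments

The generator emulates the *signal structure* the pipeline consumes, not
hydrodynamics: trapezoidal dives (constant-rate descent/ascent at a 60°
pitch and 1.5 m/s swim speed, flat noisy bottom), surfacings near 0 m
with 0.1-m depth noise (so the 0.5-m criterion is unambiguous), and four
dive types — capture, search (slow clicks only), travel/rest (< 30 m,
silent), and other deep silent dives. Dive counts are Poisson at the
configured rate with capture dives as a Binomial thinning, so capture
counts are Poisson(rate × duration); schedules that overflow the
deployment are truncated, and configurations whose *expected* dive time
exceeds 90 % of the deployment are rejected outright. Default group
capture rates are the observed 3.29 / 2.12 / 1.23 / 3.10 per hour for
NRKW F / NRKW M / SRKW F / SRKW M.

Capture dives carry the full signature: a jerk transient of configured
amplitude (default 60 m/s³ against 0.02 m/s² accelerometer noise), a
roll plateau (default 90°), a sustained heading sweep during the pursuit
window, a fast→buzz click sequence, and handling sounds with probability
0.9. The lunge samples themselves are stereotyped — the strike dominates
sensor noise there — so the signature is deterministic at the jerk peak
and every capture in a deployment attains the same peak feature triple.
This is a deliberate modeling choice: with fully continuous feature
noise, componentwise-minimum calibration must miss unconfirmed captures
at a rate ~1/(K+1) per feature (an order-statistics fact independent of
signal-to-noise), which would contradict the sensitivity-1 design of the
filter rather than test it. Click trains are renewal processes with ICIs
uniform within each class band — only class membership matters
downstream. The true track integrates the simulated heading and pitch
with a slowly wandering true speed (~15 % on a minute scale), so a
constant-speed dead reckoner drifts realistically; GPS fixes are the true
track at surfacings every 5 min plus 5-m isotropic noise.

What the generator does **not** emulate — and hence what passing tests do
not establish about field data: sub-4-s surfacing excursions (real
deployments log ~90 "dives" per hour, most of them such hops; the default
18 dives/h covers only behaviorally meaningful dives), conspecific and
vessel noise in the audio, tag slips, magnetometer calibration error,
ocean currents, and any covariance between dive shape and behavior beyond
the four types.

## Problem sizes in tests

Cohort-level checks run on the packaged 52-deployment table. Simulation
checks use 10-Hz, 0.5–1-h deployments (the signal structure is rate-
independent; 10 Hz keeps every depth/jerk computation identical in form
to 50-Hz data) — 200 deployments for end-to-end recovery and 200
replicates per family at n = 48, 8 groups for parameter recovery. These
sizes were chosen as the smallest at which the Monte-Carlo tolerances in
the tests are meaningful.

## Known limitations

- The adult-female Poisson model refit on the packaged table yields a
  population coefficient of −2.50 (s.e. 0.49); this value is robust
  across independent fitters and week-numbering conventions, and the
  package reports it as computed.
- "Week of the year" is implemented as ISO-8601 week numbering; the
  original labeling convention is not recorded anywhere recoverable, and
  alternative conventions shift deployment-level coefficients noticeably
  at n = 15.
- Beta-family second derivatives in the inner Newton step use a central
  difference of the analytic score; this is accurate to ~1e-6 and only
  affects mode-finding, not the likelihood itself.
- Non-Gaussian models support one random intercept (the deployment-level
  models need only week-year); crossed non-Gaussian intercepts would need
  a different integration strategy and are out of scope.
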