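# orcaforage

Bio-logging analysis of individual foraging behavior in resident killer
whales (*Orcinus orca*). The package implements the full analysis chain
for suction-cup archival tag (DTAG) deployments on the Northern and
Southern Resident populations (NRKW / SRKW): dive detection and phase
partitioning from the depth trace, inter-click-interval classification of
echolocation, kinematic prey-capture classification calibrated against
acoustically confirmed captures, dead-reckoned track reconstruction forced
through surfacing GPS fixes with bathymetry lookup, per-deployment foraging
metrics, and the mixed-effects models used to compare populations, sexes
and demographic groups. A synthetic deployment generator with ground-truth
labels makes every stage testable without field data.

It is written for movement ecologists and biostatisticians who work with
high-resolution tag data and want a scripted, reproducible version of this
analysis rather than a chain of interactive toolbox steps.

## The analysis

**Dives and phases.** A dive is a depth excursion > 1 m bounded by
surfacings < 0.5 m; dives shorter than 4 s and dives starting in the first
5 min after tagging are discarded. Each dive splits into descent, bottom
(the contiguous span at ≥ 70 % of maximum dive depth) and ascent.

**Capture classification.** For each phase, three kinematic features are
computed: the jerk peak max‖Δa‖·f_s normalized by the deployment median
jerk, |roll| at the jerk peak, and the circular variance of heading
1 − R̄. Dives whose audio contains both a terminal buzz (inter-click
interval < 11 ms) and prey-handling sounds are confirmed captures; per
population, thresholds are the componentwise minima of the confirmed
dives' best-phase feature triples — the unique maximal thresholds with
100 % sensitivity on the confirmed set — and any dive with a phase
passing all three thresholds is classified a capture.

**Metrics.** Capture rate = capture dives per hour of deployment;
foraging efficiency = capture dives per hour of searching (dives with
slow clicks, ICI > 100 ms, and nothing else); plus time-budget
proportions and capture depths/bathymetries.

**Models.** Deployment-level counts y_i are modeled as
y_i ~ Poisson(μ_i) or NB1 (Var = μ(1+α)) with
log μ_i = x_iᵀβ + log(d_i) + b_{w(i)}, b_w ~ N(0, σ²_w),
where d_i is deployment duration and w(i) the ISO week-year of the
deployment (a random intercept absorbing shared environmental variation,
salmon availability above all). Proportions use logit-link beta
regression with optional log-linear dispersion covariates; log-depths use
Gaussian LMMs with crossed week-year and deployment intercepts.
Non-Gaussian mixed likelihoods are maximized with adaptive Gauss–Hermite
quadrature over the random effect; the surrounding protocol (AIC delta-2
selection of the random structure, likelihood-ratio single-term deletion,
Tukey-style single-step contrasts, simulation-based overdispersion
checks) is included.

The summary table of the 52 analyzed deployments (2009–2014) ships with
the package (`load_deployment_fixture()`); per-dive sensor data were never
published, so dive-level claims are exercised on synthetic deployments.

## Worked example

```python
import orcaforage as of

records = of.load_deployment_fixture()
metrics = of.metrics_from_table(records)
for g in of.group_means(metrics, records, "population_sex", "capture_rate"):
    print(g.key, round(g.mean, 2), g.n)
```

prints

```
('NRKW', 'F') 3.29 11
('NRKW', 'M') 2.12 18
('SRKW', 'F') 1.23 10
('SRKW', 'M') 3.1 12
```

— the mean prey-capture rates (capture dives per hour) by population and
sex: NRKW females out-capture NRKW males by 55 %, while SRKW males
out-capture SRKW females by 152 %; the two populations show opposite sex
biases in individual foraging. The `examples/` scripts walk through each
capability end to end: `cohort_summary.py` (group means and percent
differences), `simulate_and_detect.py` (synthetic deployment → dive
detection → calibrated capture classification vs ground truth),
`track_reconstruction.py` (dead reckoning, GPS forcing, bathymetry), and
`demographic_models.py` (the calf and living-mother GLMMs with contrasts
and dispersion checks), e.g.

```
$ python examples/demographic_models.py
adult females (n=15), Poisson GLMM, ML (adaptive GH quadrature, 15 nodes)
  (Intercept)              2.7671 (se 0.5037, p 0.0000)
  population[SRKW]        -2.5044 (se 0.4856, p 0.0000)
  calf                    -2.2954 (se 0.6543, p 0.0005)
  week-year variance: 0.908, AIC 78.6
```

— SRKW adult females capture prey at a lower rate than NRKW females, and
the presence of a dependent calf (≤ 3 years) depresses capture further.

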