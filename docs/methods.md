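# Methods

This note documents the models implemented in `dualcontrol`, the choices
made where the design was genuinely open, and what the synthetic-data
generator does and does not emulate.

## Task simulator

Each simulated subject is a latent profile: ex-Gaussian go-finish-time
parameters (mu, sigma, tau; ms), a deterministic stop-process latency
`ssrt_true`, omission and choice-error probabilities, and three additive
proactive effects — `beta_context` (ms added to the go finish time on
uncertain-cue CSST trials), `beta_pes` (ms added on trials immediately
following an unsuccessful stop), and `beta_antic` (ms per unit of stop
expectation). Trial composition, staircase (start 200 ms, ±50 ms,
clamped to [0, 900] ms — the clamp bounds are our choice; only the start
and step are prescribed by the task design) and run lengths follow the
task descriptions exactly: SST runs of 96 trials (64 go / 32 stop), CSST
runs of 80 (32 certain-go / 32 uncertain-go / 16 stop). Stop positions
are a uniform seeded permutation; no adjacency constraints are imposed.
Inter-trial intervals are not simulated; they enter no computed measure.

The subject's internal stop expectation is produced by the same dynamic
belief model used in analysis, with the subject's own forgetting
parameter `alpha_gen` (default 0.3). Anticipatory slowing is applied as

    beta_antic * (p_stop − pm),

i.e. relative to the task's baseline stop rate pm = 1/3. The centering
matters: an uncentered `beta_antic * p_stop` term adds a large constant
(~beta_antic/3) to every cued trial that certain-go CSST trials do not
share, which would inflate the simulated context effect several-fold
beyond its intended magnitude and shift the staircase equilibrium. With
centering, the preset go-RT mean is the observed mean RT, and the
context effect equals `beta_context` in expectation.

On stop trials a response occurs iff the go finish time beats
SSD + `ssrt_true` (independent race) and the trial is not an omission.
The stop latency is deterministic by default (a variance knob exists,
default 0) so the true SSRT is exactly recoverable by the integration
method — the property the estimator-validation tests rely on.

Group presets (TD / ADHD) set go-RT mean 497/547 ms (between-subject SD
61/79), within-subject SD 107/138, SSRT 282/314 (SD 42/57), context
31/26 ms, post-error 42/13 ms, anticipation gain 500/250 ms per unit
p_stop, and omission/choice-error rates giving ~94%/90% go accuracy.
The ex-Gaussian is parameterised as tau = 0.7·s, sigma = √(s²−tau²),
mu = m − tau, a conventional split giving realistic right skew. SWAN
scores are noisy linear functions of (ssrt_true, beta_pes, beta_antic)
with loadings chosen so group means separate in the direction and
approximate magnitude of the reported clinical scores; shorter SSRT and
larger proactive adjustments map to higher (more normal) scores.

What the generator does **not** emulate: trigger failures and stop-
latency variance, fatigue or drift across runs, response-hand effects,
RT autocorrelation beyond the modeled history effects, non-Gaussian
symptom-score structure, and any fMRI context. Passing recovery tests
therefore certifies the estimators under race-model-faithful data, not
robustness to violations of the race model itself.

Note one deliberate coupling: because the post-error state and high
stop expectation co-occur (both follow stop trials), the *measured*
post-error slowing of a simulated subject is `beta_pes` plus an
anticipation contribution (≈ beta_antic · Δp_stop, with Δp_stop ≈ 0.1
between post-stop and post-go trials at α = 0.3). Recovery tests that
target `beta_pes` alone therefore switch anticipation off.

## SSRT (integration method)

T is the ⌈p·N⌉-th order statistic of the go-RT distribution — the exact
inverse of the empirical CDF, no interpolation (the convention is not
prescribed anywhere; this is the simplest one and is property-tested
against a brute-force CDF oracle on all small instances). A 1e−9 relief
inside the ceiling guards against p·N floating a few ulps above an
integer. Go omissions are replaced by the maximum observed go RT before
integrating (consensus practice); choice-error go trials keep their RTs
(the race concerns responding at all). For the CSST, only uncertain-go
RTs enter the distribution, with all stop trials. Estimates from fewer
than 10 go trials, or with stop responding at 0 or 1, are flagged rather
than dropped. Pooling across a subject's runs (per task) is assumed for
the performance-criterion filter (go accuracy > 50%, stop accuracy
25–75% inclusive).

## Trial-history labels and model-free proactive measures

Labels are assigned within run only (the first trial of each run is
`other`): a predecessor that is a responded stop yields GoPUS/StopPUS; a
predecessor that is a responded, correct go-class trial yields
GoPSG/StopPSG. A GoPUS trial that is itself a correct go may serve as
the successful-go predecessor of the next trial (no exclusivity rule).
Both correct and choice-error responded go trials contribute RTs to the
GoPUS/GoPSG means — the conditions are defined by the *preceding* trial.
Minimum-trial thresholds (3/3 for PES, 2/2 for the stop-accuracy effect,
5 per cue class for the context effect) produce flagged missing values,
not silent drops.

## Dynamic belief model

The filter is a fixed grid over r ∈ (0,1) (default 1000 cells; the
simulator uses 500 for speed). Cell masses of the Beta prior are exact
CDF differences and each cell is represented by its prior-conditional
mean of r (Beta first-moment identity) rather than its midpoint — for
singular Beta shapes (a or b < 1) midpoints lose several digits, and the
conditional-mean variant keeps the α = 1 filter within 1e−6 of the
conjugate beta-binomial closed form at grid 4000. Prediction at trial k
happens before observing trial k; the first prediction is the prior
mean. The belief restarts at the prior for each run (runs are separated
in time). For the CSST, only uncertain-cue trials enter the sequence —
certain-go cues rule stops out and do not advance the belief.

Prior defaults pm = 1/3 (the true stop rate) and scale = 2 are
config-exposed decisions, not reported values.

### α calibration

For each α in {0.2, 0.25, …, 0.7}, responded go trials are pooled
across subjects, binned into 20 equal-count bins by p_stop, and the
Pearson correlation of bin means is computed; the selected α maximises
this curve (ties toward the smaller α — "saturation" is not an
operational rule, argmax is the implemented proxy). Two estimator-design
choices proved essential and are deliberate deviations from a naive
pooled correlation:

1. **Post-error exclusion.** Go trials immediately following an
   unsuccessful stop are excluded. Post-error slowing elevates RT
   exactly where recent history predicts a stop, and a small-α filter
   weights recent history most; with those trials included the sweep
   selects the smallest candidate α *asymptotically* (verified on
   400-subject cohorts), regardless of the generative forgetting rate.
2. **Within-subject centering.** RTs are mean-centred per subject before
   pooling; between-subject baseline differences otherwise act as bin
   noise that tilts the (very flat) selection curve toward small α at
   realistic sample sizes.

Even so, the curve differs by < 0.005 between neighbouring α values
around the optimum, so single-cohort selection is noisy: at a
38-subject calibration cohort the selection is roughly centred on the
generative value but has about a two-step spread. The recovery study in
the acceptance suite therefore uses 150-subject single-group cohorts
per replication (20 replications), where selection lands within one
grid step of the generative α = 0.3 in a clear majority. Per-subject
anticipation correlations are computed on SST trials (CSST support sits
behind a flag).

## Drift-diffusion model

Two-boundary Wiener diffusion, unit diffusion coefficient, start point
fixed at a/2, no inter-trial variability parameters. The first-passage
density uses the classical short-time (image) and long-time (spectral)
series, switching to whichever needs fewer terms for ~1e−10 normalized
accuracy; total boundary masses agree with the closed-form choice
probability 1/(1 + e^(−v·a)) to 1e−4 under quadrature. Fitting is
maximum likelihood (accuracy coding: correct → upper boundary) with five
seeded L-BFGS-B starts in the box a ∈ (0.2, 4), v ∈ (−8, 8),
t0 ∈ (0.05, min RT); RTs are converted to seconds; go omissions are
excluded. All-correct samples and fits on fewer than 10 trials are
flagged (drift is weakly identified without errors). Two samplers exist:
an inverse-CDF sampler built on the density (used for recovery studies)
and an independent Euler–Maruyama path simulator used as an oracle for
choice probabilities and RT moments.

Realistic sessions yield only ~30 GoPUS trials per subject, so
single-subject deltas are noisy; correctness is certified at large
simulated n (bias < 5% per parameter at n = 5000) and the pipeline
propagates flags rather than implying precision. Fitting per-subject
DDMs is therefore off by default in the pipeline (`with_ddm=True`
enables it); the DDM deltas are not prediction features.

## Statistics and prediction

Welch t with Satterthwaite df; Cohen's d uses the pooled SD (it tracks
conventional reporting better than a Welch-based d). Fisher-Z compares
independent correlations with z = Δatanh(r)/√(1/(n₁−3)+1/(n₂−3)); the
one-sided p on |z| is the default reporting, two-sided also returned.
Confidence intervals are plain t-intervals on summary statistics.
"Stop accuracy between 25% and 75%" is inclusive; "go accuracy above
50%" is strict. Gender enters regressions as a 0/1 indicator.
Shapiro–Wilk and Levene checks are reported, never gating.

LOOCV prediction standardises features with training-fold statistics
only (leakage hygiene), fits OLS per fold, and correlates out-of-fold
predictions with observations over the pooled cohort (both groups; the
analysis is dimensional). The full feature set is {SSRT from the SST,
context effect, post-error slowing, anticipation correlation}; the
reduced model is SSRT-only. Full vs reduced performance is compared
with the Pearson–Filon statistic for dependent overlapping correlations
(one-sided for full > reduced; Hotelling–Williams available by flag).
Its type-I error is Monte-Carlo calibrated at the nominal 5% (±1 pp over
5000 null replications at n = 80) in the acceptance suite.

## Numerical and reproducibility notes

- A single cohort seed fans out through `numpy` `SeedSequence.spawn`,
  one child stream per subject, so per-subject data are reproducible in
  isolation.
- Ties in the α sweep resolve to the smaller α; ties in order statistics
  are inherent to the empirical CDF inverse.
- Degenerate inputs (no responded trials, zero-variance samples,
  stop responding at 0/1, rank-deficient folds) raise descriptive errors
  or return flagged values; nothing is silently imputed.
- Problem sizes used by the test suites: 50 subjects for SSRT/PES
  recovery, 20 × 150-subject cohorts for α recovery, n = 5000 × 10 seeds
  for DDM recovery, 5000 replications for type-I calibrations, 20 ×
  80-subject cohorts for prediction — chosen to bound Monte-Carlo error
  well below each assertion's tolerance.

## Known limitations

- The race model here has no stop-latency variance or trigger failures;
  integration-method bias under those violations is out of scope.
- The DDM fitter estimates three parameters only; data generated with
  inter-trial variabilities would bias t0 and v estimates.
- The α selection curve is intrinsically flat; reported per-cohort
  optima should be treated as ±1 grid step.
- Measured post-error slowing conflates `beta_pes` with anticipation
  coupling (see above) — a real feature of history-driven designs, not
  an implementation artifact.
- Symptom prediction in the simulator is linear-Gaussian by
  construction; predictive r values on synthetic cohorts say nothing
  about effect sizes attainable on real children.
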