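# Methods

## The task being emulated

A participant prepares a 20° wrist extension and releases it on a visual
go-signal that follows a variable 2500–3000 ms foreperiod.  On a subset of
trials an irrelevant auditory prepulse is played before the go-signal —
either at −1000 ms ("early") or −300 ms ("late") — at one of several
intensities.  Loud prepulses may (a) elicit a startle reflex, visible as a
short-latency (20–120 ms) EMG burst in the sternocleidomastoid (SCM), and
(b) involuntarily trigger the prepared response, visible as an agonist
(ECR) burst *before* the go-signal.  The analysis asks how intensity and
preparation level shape both probabilities, and how well SCM presence
predicts triggering.

Two designs are built in: `exp1` blocks contain 16 visual-only trials plus
2 trials of each of 80/100/110/120 dB × early/late (32 trials, 50%
auditory); `exp2` blocks contain 24 visual-only plus 3 of each of
114/120 dB at −300 ms (30 trials, 20% auditory).  Pseudorandom orderings
respect the constraint that the loudest stimuli (`exp1`: 110/120 dB;
`exp2`: any auditory trial) never occupy a block's first two positions nor
two consecutive positions; orders are redrawn under a bounded retry budget
and failure raises rather than silently violating the constraint.

## Synthetic-signal model

Each trial is a 4-channel record (ECR, FCR, SCM, wrist position) on
[−2000, +2000] ms around the go-signal at 4000 Hz.

* **Baseline EMG** is Gaussian white noise band-passed to 20–450 Hz (the
  acquisition band) and scaled to a per-channel RMS (default 1.0, arbitrary
  units).  What matters downstream is the burst-to-baseline ratio, not the
  absolute scale.
* **Bursts** are additional band-passed noise with a trapezoidal amplitude
  profile: 20 ms linear rise, plateau, 20 ms fall.  The 20 ms rise is a
  physiologically typical surface-EMG burst rise time; together with the
  zero-phase 25 Hz envelope filter it makes threshold-crossing onset
  estimates approximately unbiased (a sharper rise biases detected onsets
  early, because zero-phase filtering smears burst energy backwards).
  Default gains: 10× baseline RMS (ECR, SCM), 6× (FCR); durations 150 /
  75 / 100 ms for ECR / SCM / FCR.
* **Events.**  On auditory trials an SCM burst is drawn with probability
  `p_scm(intensity, offset)`; its latency is Normal(75, 15) ms truncated to
  [20, 120].  Triggering is drawn with `p_trigger_given_scm_plus/minus`.
  Triggered responses draw their RT (from the stimulus) from a
  shifted-lognormal; visual responses draw theirs from the go-signal.
  Default RT distributions are calibrated to means of ≈103 ms (triggered,
  SCM+), ≈143 ms (triggered, SCM−) and ≈200 ms (visual) — calibration
  targets for realistic simulation, not empirical claims.  The FCR burst
  follows the ECR by 60 ms, and the position trace ramps 20° (cosine
  profile, 150 ms) starting 40 ms after ECR onset (a fixed
  electromechanical delay; nothing downstream analyses FCR or kinematics).
* **Error trials.**  With small probabilities a trial is an anticipation
  (response 5–45 ms after the initiating stimulus), a slow response
  (visual RT 410–560 ms, or a 310–600 ms post-stimulus response on early
  auditory trials, exercising the dead zone described below), or a
  movement error, which is a pass-through flag on the trial record — it is
  not detected from kinematics.
* **Between-subject heterogeneity** is one shared logit-normal deviate per
  participant (SD 0.5 on the logit scale) added to every condition's
  `p_scm`, so the ≥50% SCM+ participant screen has realistic variation to
  act on.
* **Default probabilities** (`exp1`: p_scm rising 0.08→0.85 with intensity
  and lateness, trigger 0.55–0.85 given SCM+ and 0.05–0.30 given SCM−;
  `exp2`: p_scm 0.71/0.83, trigger 0.92 / 0.55) mirror the reported
  condition-wise proportions of the study designs being emulated.
* **Reproducibility.**  All randomness flows through a `SeedSequence`
  tree: master seed → participant → trial → (event draws, waveform noise).
  Event-level ground truth is therefore identical whether or not waveforms
  are rendered, and identical seeds give byte-identical cohorts.

What the generator does **not** emulate: acoustic waveforms (intensity is
a label), prepulse inhibition and habituation across trials (trials are
exchangeable within condition), electrode artifacts, and EMG
non-stationarity.  Passing tests on synthetic cohorts therefore validate
the *pipeline logic and estimators*, not detector performance on real
surface EMG, where onset accuracy is typically worse and manual review is
common practice.

## Envelope and onset detection

The envelope is `clip0(lowpass(|x − mean(x)|))`: DC-correct, full-wave
rectify, low-pass filter, clip small negative ringing to zero.  The filter
is an order-2 elliptic low-pass at 25 Hz (0.5 dB passband ripple, 40 dB
stopband attenuation), normalised to unit DC gain — even-order elliptic
designs otherwise sit at −ripple dB at DC, which would scale the whole
envelope by 0.94 (detection is scale-invariant, but calibrated amplitudes
make the envelope interpretable).  It is applied forward–backward
(zero-phase) by default so onsets are not systematically delayed; a causal
single-pass mode is available.

Baseline statistics (mean, population SD; the divisor is configurable) are
computed on the envelope over [−1500, −1000) ms — the 500 ms immediately
before the earliest possible auditory stimulus.  A burst onset is the
earliest sample *t* in the search window with envelope strictly above
`mean + 2·SD` at every sample of [t, t + 25 ms] (both endpoints
inclusive; a `sustain_fraction < 1` relaxes the every-sample rule).  The
sustain interval may extend past the search window but not past the
recording.

Search windows: SCM is searched only on auditory trials over
[stimulus + 20, stimulus + 120] ms, the upper bound inclusive at the onset
sample.  ECR is searched from the initiating stimulus (auditory stimulus
if present, else the go-signal) to go + 600 ms.  The 600 ms ceiling is
deliberately *beyond* the 400 ms slow-visual cut-off: the RT error
filters, not the search window, enforce the 300/400 ms rules, and slow
responses must remain detectable to be discarded with the correct reason
instead of vanishing as "no response".  For the same reason the search
floor is the initiating stimulus itself, so anticipations (RT < 50 ms) are
visible to the anticipation filter.  Responses occurring before the
initiating stimulus are not detectable; the generator does not produce
them.

The manual visually-confirm-and-correct step used with real data is not
implemented; tests instead score the raw algorithm against generator
ground truth.

## Classification rules

* **SCM status**: SCM+ iff a found SCM onset lies in [stimulus + 20,
  stimulus + 120] ms (120 inclusive); visual-only trials are
  `not_applicable`.
* **Response class**: on auditory trials, an ECR onset before the
  go-signal is a candidate *triggered* response with RT measured from the
  auditory stimulus; onsets at/after go are *visual* with RT from go.  The
  premotor RT and the initiating-stimulus-adjusted RT coincide under this
  scheme and both are reported.
* **Filters** (strict inequalities; boundary values 50/300/400 are kept):
  adjusted RT < 50 ms → anticipation; triggered RT > 300 ms →
  slow-auditory; visual RT > 400 ms → slow-visual; plus the pass-through
  movement-error flag.  On early (−1000 ms) trials this creates an
  explicit *dead zone*: responses between stimulus + 300 and the go-signal
  are classified triggered but discarded as slow-auditory — the only
  reading consistent with both the "triggered within 300 ms" definition
  and the slow-RT filter.
* **Participant screen**: included iff the SCM+ proportion on the loudest,
  latest condition is ≥ 0.5 (configurable to strict >, since the screen is
  described both ways in different places).
* **Confusion categories** treat SCM presence as a predictor of
  triggering on kept auditory trials: TP = SCM+ triggered, FP = SCM+ not
  triggered, TN = SCM− not triggered, FN = SCM− triggered; accuracy =
  (TP + TN)/kept.
* **Proportion tables** report per-participant cell proportions (used for
  ANOVA/t-tests) and trial-pooled composites (Σ numerators / Σ
  denominators — the "grand mean" used for descriptive figures; with
  unbalanced cells this is *not* the mean of subject proportions).  Empty
  cells are absent, never zero.  RT histograms use half-open 10 ms bins.

## Statistical machinery

* **Proportions** are arcsine-square-root transformed (asin√p) before
  inference.  The 2×4 repeated-measures ANOVA uses the standard
  within-subject decomposition, testing each effect against its own
  subject-by-effect interaction error term; partial η² =
  SS_effect/(SS_effect + SS_error).  Missing cells raise (no imputation).
  Tukey post-hocs use the studentized range on the effect's own error
  term.  The two-intensity design uses a paired *t* with Cohen's
  *d* = mean(diff)/SD(diff) = *t*/√n.
* **Premotor RT** uses a linear mixed model fitted by maximum likelihood
  (statsmodels MixedLM; REML behind a flag), with a subject random
  intercept and an optional SCM random slope that is *uncorrelated* with
  the intercept (diagonal covariance) — simpler than a correlated-slope
  model and sufficient here; singular slope fits are automatically
  refitted intercept-only and flagged.  Fixed effects are tested with
  Wald F statistics on residual degrees of freedom; Satterthwaite /
  Kenward–Roger adjustments are out of scope, so p-values for small-n
  random-effect-heavy designs are mildly anti-conservative.  Estimated
  marginal means average the linear predictor over a balanced grid of the
  other factors with asymptotic normal CIs.  A `re_var_fixed=0` option
  pins the intercept variance at zero, in which case the ML solution is
  computed directly from the least-squares normal equations (statsmodels'
  profiling degenerates at that boundary).
* **Triggering** is modelled by a binomial GLMM with a subject random
  intercept, written in-package: the marginal likelihood integrates the
  intercept out by adaptive Gauss–Hermite quadrature (per-subject Newton
  mode-finding, curvature-scaled nodes; 10 nodes by default, 1 node =
  Laplace), and BFGS maximises it over (β, log σ) from an IRLS logistic
  start.  Standard errors come from a central-difference observed-information
  Hessian; if the variance sits at its boundary the fixed-effect block is
  inverted on its own.  Estimates agree with lme4's `glmer` (nAGQ = 10) to
  ~1e-6 on test data.  Categorical predictors use treatment coding with
  references 80 dB / SCM− / early (falling back to the lowest present
  level when a reference is absent, as in the two-intensity design); RT
  enters in ms, uncentred, so intercepts read at RT = 0.  AICc =
  AIC + 2k(k+1)/(n−k−1) with n = number of trials and k counting fixed
  coefficients plus the variance parameter; models are ranked ascending
  with ties broken toward fewer parameters.  Predicted probabilities are
  population-level (random intercept at 0) with logistic-transformed Wald
  intervals; level contrasts use single-step Tukey adjustment of the
  asymptotic z statistics (studentized range with infinite df).
* **Candidate ladder**: null; each single predictor (time, intensity,
  SCM, RT); each independent×dependent interaction pair; and the full
  model with SCM×RT interacting plus intensity and time additive.

## Numerical choices and degenerate inputs

* Windows are half-open [start, end) in ms relative to the go-signal;
  sample *i* sits at −2000 + i/4 ms; the single deliberate exception is
  the inclusive 120 ms SCM bound.
* The GLMM's log σ is clamped to [−8, 5]: below e⁻⁸ the model is
  numerically a plain logistic regression, and the clamp keeps the
  objective finite when separation collapses the variance.  Runaway
  coefficients (|β| > 15) raise a separation warning on the returned fit.
* `paired_t` on identical samples returns the degenerate t = 0, d = 0;
  zero difference variance with a nonzero mean is an error, not ±∞.
* Filter input shorter than the filtfilt warm-up, non-finite samples,
  baseline windows outside the recording, search windows shorter than the
  sustain interval, missing ANOVA cells, single-subject mixed models and
  rank-deficient designs all raise explicit errors.

## Problem sizes in tests and the acceptance script

Simulation studies run at sizes chosen to give stable Monte-Carlo answers
on a single CPU: detector-oracle equivalence on 1000 random envelopes;
label recovery on a 5-participant × 2-block signal cohort (320 trials);
GLMM recovery over 100 replicates of 100 subjects × 40 trials; ANOVA
type-I calibration over 2000 null replicates of a 12-subject 2×4 design;
LMM gap recovery over 100 replicates of 12 subjects × 40 trials; and AICc
model selection over 50 (tests) or 30 (acceptance script) cohorts of 11
subjects × 64 auditory trials generated from the full-model structure.

## Known limitations

* Onset detection accuracy is quoted for high-SNR synthetic bursts;
  real-EMG SNR, baseline non-stationarity and motion artifacts will
  degrade it, and no artifact rejection is implemented beyond the
  baseline/threshold rule itself.
* The GLMM supports a single scalar random intercept only — no crossed or
  nested random effects and no random slopes (matching the analysis it
  implements, which specified participants as a random intercept).
* LMM inference uses residual-df Wald tests rather than Satterthwaite
  fractional df; EMM intervals are asymptotic.
* The RT-based and SCM-based predictors of triggering are partially
  confounded in the generator by construction (triggered responses are
  drawn from faster distributions), so on synthetic cohorts RT-only
  models can rank very well; this mirrors the real diagnostic overlap the
  analysis is about rather than a defect of the ranking.
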