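# Methods

`tgtacs` re-implements, as a reusable and tested pipeline, the behavioral
analysis of a multi-session theta–gamma tACS working-memory intervention:
16 stimulation sessions, each pairing 20 minutes of stimulation with
concurrent 1-back ("speed match", SM) and 2-back ("memory match", MM)
n-back training, in two parallel arms (active vs. sham, 38/39
participants, ages 55–85). Because the trial's raw data are not publicly
deposited, the pipeline ships a synthetic-cohort generator that
reproduces the data's statistical structure; every stage of the analysis
is exercised against it.

## Stimulation waveform

The active stimulus is a phase-amplitude-coupled composite: a 6 Hz theta
sinusoid carrying an 80 Hz gamma component gated on during the positive
theta half-cycle (peak coupling; trough coupling mirrors the gate). We
model the gate as a continuous 80 Hz carrier multiplied by the indicator
`sin(phi_theta) > gate_threshold` (threshold 0 by default) rather than as
phase-reset bursts: the gated-carrier form has no phase discontinuities
and its spectrum is a clean 80 Hz line plus sidebands at 80 ± 6k Hz. The
theta:gamma pre-normalisation amplitude split is 1:1 and exposed in
config, since the protocol fixes only the composite amplitude.

Normalisation is exact by construction: the raw composite is rescaled so
that its plateau (the portion between the 15 s fade-in and fade-out)
spans exactly the configured 2 mA peak-to-peak, and fades (linear by
default, raised-cosine by flag) are applied afterwards, so they only
attenuate. Sampling is 10 kHz (125 samples per gamma cycle), making
peak-to-peak and periodogram measurements quantisation-stable.

The sham protocol places one 90 s active phase (15 s ramp, 60 s plateau,
15 s ramp) at each end of the 20-minute window and fills the interim with
an 85 Hz, 50 µA peak-to-peak impedance-control sinusoid.

Waveform validation measures everything from the sampled signal, not the
construction: peak-to-peak as max − min per labelled segment, dominant
frequencies as periodogram argmax in the 0.5–40 and 40–120 Hz bands, and
phase–amplitude coupling as a Tort-style modulation index (gamma-band
Hilbert envelope binned into 18 theta-phase bins, normalised entropy).
Two numerical points matter here. First, band-pass filters are built in
second-order-section form; transfer-function (b, a) Butterworth filters
are numerically singular for a 3–12 Hz band at a 10 kHz rate. Second, the
preferred coupling phase is reported as the envelope-weighted circular
mean rather than the argmax bin: the burst envelope is flat-topped with
symmetric filter ripple, so an argmax is tie-broken by floating-point
noise, while the circular mean recovers the gate centre (+π/2 for peak
coupling, −π/2 for trough) exactly. Because the MI is scale-invariant, an
amplitude band containing no real signal power would otherwise report
coupling from phase-locked filter leakage; a band-power floor (10⁻⁶ of
total power) guards against this. Peak- and trough-coupled waveforms give
equal MIs only up to estimator error (~10⁻⁴ on 30 s windows): the two
signals are not exact time-shifts of one another because the gamma
carrier phase is not periodic in half a theta cycle.

## Synthetic cohort

The generator's latent model is equal-variance Gaussian signal detection.
For gameplay index g (1–96 SM, 1–160 MM), sensitivity and criterion
follow quadratic learning curves with a group main effect and a
group-by-gameplay interaction,

    d'(g) = b0 + b_g·g + b_g2·g² + (b_group + b_gxg·g)·[active]

and analogously for c(g). Per-trial response probabilities are then

    P(hit) = Φ(d'/2 − c),    P(false alarm) = Φ(−d'/2 − c),

with hits and false alarms binomial in the per-gameplay target and
non-target counts. This mapping is the exact inverse of the d'/C
estimators in the signal-detection module, which is what makes exact
round-trip tests and parameter-recovery studies possible.

Default coefficient sets are per task and equal the trial's published
final-model estimates for the 2-back condition (d′: 4.74e-3·g −
1.55e-5·g² + 0.04·A + 4.47e-4·g·A; criterion and log-RT analogous), with
a flat, near-ceiling 1-back. Reaction times are gamma: per-response RTs
have mean exp(linear predictor in g, group, centred age and MoCA) and
shape 20 (≈22% per-trial CV); the gameplay mean of n iid gamma draws is
itself gamma with shape n·20, and is drawn directly from that exact
distribution. Per-participant normal intercept shifts (sd 0.25 on d′,
0.15 on c, 0.08 on log RT) add between-subject heterogeneity. Trials per
gameplay (SM 30, MM 20) follow from the 45 s / 60 s gameplay durations at
1.5–3 s per trial, and the target fraction is 0.3; both are unpublished
app internals, exposed in config and flagged as placeholders. The 2-back
convention that the first two stimuli cannot be answered is modelled by
the reduced MM trial count, not by simulating unanswered stimuli.

Randomness is a single seed; per-participant substreams are spawned from
(seed, row index), so a participant's records are reproducible
independent of table ordering. Contaminant injection (dropouts truncated
after session 8, excess gameplays past the schedule totals, no-response
gameplays, one constant-"yes" 1-back responder) returns a manifest that
filtering tests compare against exactly. No-response injection avoids
first gameplays, which the practice-effect filter would remove before the
no-response stage could be credited.

What the generator does **not** emulate: trial-by-trial stimulus
sequences (lure structure), fatigue or circadian drift, serial
correlation of performance within a session beyond the latent curves, and
any real electrode-skin physics. Tests passing on this generator
therefore validate the pipeline's arithmetic and statistical calibration
under its stated model, not the trial's substantive findings.

## Filtering cascade

General filters, applied in order and logged per stage: dropout
participants (records stop before session 16); the first gameplay of each
game per participant over the whole study (the singular "initial round"
reading; a per-session variant is exposed); gameplays indexed beyond the
schedule totals (SM > 96, MM > 160); gameplays with no response; and
degenerate responders, generalised to "identical response to every trial
of a task" and removed from that task entirely (the observed instance is
a constant yes).

The cascade then branches. The signal-detection branch flags extreme
outliers with Tukey fences at 3×IQR on hit rates and false-alarm rates
separately (per task) and removes the union. Quartiles use linear
interpolation between order statistics — the convention is fixed and
documented because fence membership depends on it. The RT branch removes
gameplays whose mean RT lies outside mean ± 3 sd of the task's
gameplay-level mean RTs, pooled across groups and participants (the
least-parameterised reading; a per-participant variant is exposed);
bounds are computed once on the input (single pass), and sd = 0 removes
nothing. Removal percentages are reported per task relative to the
post-general-filter record count, the same way the original analysis
quotes its 5.8%/0.9%/3.5%/1.9% figures; those printed percentages depend
on the unreleased raw data and are not reproduction targets.

## Signal detection

Individual hit/false-alarm rates are averaged per (group, task, gameplay
index) before the probit transform — the aggregation the original
analysis adopted because individual gameplays frequently sit at rate 1 or
0. A residual boundary mean rate is pulled into the open interval by the
1/(2N) rule with N = trials per gameplay × contributing participants;
this clip is this package's choice of boundary handling, not something
the source analysis specifies. d′ and C are then the standard
equal-variance probit forms.

## Modeling

d′ and C series are fitted by OLS; RTs by a gamma GLM with log link
(IRLS, Wald CIs, dispersion = Pearson χ²/df; ML shape estimation is
deliberately not the default). Formulas use a small dialect in which
`x^2` expands to `I(x**2)`; gameplay enters on its raw 1-based index and
its square is the square of the raw index (no orthogonal polynomials);
collinearity is surfaced via rank checks rather than reparameterisation.
Group is treatment-coded with sham as reference.

Standardized betas come from refitting on scaled variables: every
continuous design column is divided by its sd, the response too for LMs
(so a simple LM's std beta equals the Pearson correlation); intercept and
0/1 contrast columns are untouched, and GLMs scale predictors only. Note
this standardizes design columns (including interaction and square
columns by their own sds), which is one of the two conventions in
circulation. Nagelkerke's R² is the max-rescaled Cox–Snell form. Model
selection fits all candidates on identical rows, ranks by AIC with ties
broken toward fewer terms, and reports likelihood-ratio p-values for
pairs nested with the winner.

A calibration fact worth recording: adding one pure-noise covariate
changes AIC by 2 − χ²₁ for that fit, so the expected change is **+1**
(simulation: +1.08 ± 0.06 over 500 replicates), not +2; +2 is the penalty
term alone, before the expected log-likelihood gain of a free parameter.
At the generator's default effect sizes the fitted group×gameplay
interaction on 2-back d′ has mean std beta ≈ 0.135 and mean t ≈ 1.6;
consequently AIC retains that single term only ~54% of the time if a
candidate differing only by it is offered. Model-ladder tests therefore
follow the stepwise sequence the original analysis used (main effects →
crossing → + quadratic), where selection is driven by the strong
quadratic term.

## Post hoc contrasts

For session-wise questions the session enters as a 16-level factor
crossed with group. EMMs are model predictions on the reference grid with
continuous covariates at their sample means (verified against the R
`emmeans` package on fixtures); contrast SEs come from the coefficient
covariance; p-values are t-based on the residual df with Bonferroni
k = 16 (one contrast per session). Cohen's d divides the EMM difference
by the model residual SD by default — the original analysis does not name
its denominator, so the choice is logged and an observed pooled
per-session SD variant is available; with group-mean-aggregated series
the residual SD is small, which is how session-wise |d| values far above
1 arise. d CIs use the normal approximation with the standard two-sample
SE at the session's per-group counts. Size classes are very small < 0.2 ≤
small < 0.5 ≤ moderate < 0.8 ≤ large, with boundary values assigned to
the larger class (the source's strict inequalities leave boundaries
unassigned). For log-link models, contrasts are computed on the link
scale and also reported back-transformed as ratios.

## Problem sizes and tolerances

Simulation studies in the test suite run at trial scale (38/39
participants, 160 two-back gameplays): 100 replicates for CI coverage
(band 90–99%), type-I error (band 2–9%), and model-ladder selection
(≥90%); 500 replicates for the noise-covariate AIC expectation (+1 ±
0.5). Waveform unit tests use shortened durations (60–400 s); the
acceptance checks regenerate the full 20-minute protocol signals.
Quantile-oracle agreement is asserted to 1e-6, the generator round-trip
to 1e-9, and EMM identities to 1e-8 or better.

## Known limitations

- The published regression coefficients, session-wise Cohen's d values
  and removal percentages derive from the unreleased raw data; the
  pipeline reproduces the procedures and their calibration, not those
  numbers.
- The exact stimulator firmware behaviour (gamma phase reset per theta
  cycle, theta/gamma amplitude partition) is unpublished; the gated
  continuous carrier is one consistent realisation.
- Education-years baseline p recomputes to 0.92 from the printed rounded
  summaries; the printed 0.89 presumably reflects unrounded raw data.
- Gamma GLM inference is Wald/IRLS; no profile likelihood, no
  mixed-effects structure (the source analysis also fits fixed-effect
  models on aggregated series).
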