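# Methods

This note documents the generative model, the analysis conventions, the
defaults and why they were chosen, and the limits of what the synthetic
test-bed can show about real recordings.

## Task model

A session presents two 7-s cues. The laser-predictive cue triggers, 2 s
after cue onset, a 5-s optogenetic stimulation train (20 Hz, 10 ms pulses;
terminal-stimulation experiments use 100 pulses at the same rate). The
non-laser cue is followed by nothing. Inter-trial intervals (cue offset to
next cue onset, and the lead-in before the first cue) are uniform on
[45, 75] s. A training session contains exactly 30 laser-paired and 30
non-laser cues; an omission session keeps 30 presentations of the
laser-predictive cue but withholds the laser on 10 of them (plus the 30
non-laser cues). Trial-type counts are allocated exactly and the order is
rejection-shuffled until no type occurs more than 3 times consecutively,
with a retry cap so an infeasible configuration fails rather than loops.
When only one trial type is present (stimulation-only sessions) the
run-length constraint is vacuous and skipped: it exists to interleave the
two cues.

## Signal model

The dimensionless biological signal is

    s(t) = tonic + Σ_e A_e · k(t − t_e),   k(t) = (1 − e^(−t/τ_r)) e^(−t/τ_d)

The kernel's analytic peak time τ_r · ln(1 + τ_d/τ_r) and closed-form
windowed integral serve as oracles throughout the tests. Events per trial:

- laser-paired: a cue response at cue onset whose amplitude follows the
  saturating learning curve A(s) = A_max (1 − e^(−s/λ)) across sessions,
  plus a fixed-amplitude response at laser onset;
- non-laser: a small constant cue response;
- omission: **only** a negative-amplitude dip kernel at the expected laser
  onset. The dip models the net negative deviation of the signal around the
  withheld stimulation. Keeping the learned cue transient off omission
  trials makes the dip measurement unbiased under the default windows: with
  a cue transient present, its decay between the baseline window and the
  analysis window would register as a spurious "dip" even at dip amplitude
  0, destroying the null calibration the recovery studies verify.

Region presets order the decay constants as
τ_d(LH dopamine) = 0.8 s < τ_d(NAc dopamine) = 1.5 s < τ_d(LH orexin,
GCaMP6s) = 4.0 s (rises 0.15 / 0.25 / 0.8 s). The ordering — hypothalamic
dopamine clears fastest, the slow calcium indicator slowest — is the
modeled claim; the absolute values are generator defaults, not measured
constants.

Both channels share a double-exponential bleaching term B(t) (fast
τ = 120 s, 10 % weight; slow τ = 5000 s; floor 0.6) and a band-limited
(0.1–1 Hz) Gaussian motion term m(t), and receive independent iid Gaussian
sensor noise:

    F_470 = g_s · B · (1 + m) · (1 + s) + ε_s,   F_405 = g_c · B · (1 + m) + ε_c

Simulation fails explicitly if fluorescence would go non-positive (a dip
deeper than the tonic + baseline level). The manifest records every true
event time and amplitude plus all generator parameters, so any analyzed
value can be compared to ground truth programmatically.

### Amplitude defaults

The source experiments report no numeric baseline variance or transient
amplitudes, so the defaults are chosen once at values typical for
fluorescent neuromodulator/calcium sensors in vivo: asymptotic cue response
A_max = 4 % ΔF/F with learning constant λ = 3 sessions; non-laser cue
response 0.5 %; stimulation response 8 %; omission dip −2 % against a tonic
level of 5 % (the dip must stay above −tonic: extracellular dopamine cannot
fall below zero); per-channel sensor noise ≈ 0.5–0.8 % of mean fluorescence
per sample; motion sd 0.5 %; subject-to-subject amplitude variability
lognormal with σ = 0.1. Condition scale factors: vehicle 1.0, D1 antagonist
(SCH 23390) 1.0 — the modeled finding is that D1 blockade leaves the
stimulation-evoked response unchanged — and D2 antagonist (raclopride) 0.3,
a strong but incomplete attenuation; anesthetized and freely-moving both
1.0 (no locomotion dependence).

## Preprocessing

The isosbestic correction is a single OLS line fitted over the whole
recording, mapping the 405 nm control onto the 470 nm signal; the fitted
control is F₀ in ΔF/F₀ = (F − F₀)/F₀. A constant control channel is a
degenerate-fit error; a non-positive fitted F₀ anywhere aborts with the
offending time range. Because the fit absorbs the session-mean response
level, recovered ΔF/F₀ equals the true s(t) up to one global scale factor
(≈ 1/(1 + mean response)); per-trial baselining removes the constant part,
and all downstream claims are about signs, orderings, and within-design
contrasts, which the scale factor cannot affect. The optional low-pass is a
second-order Butterworth applied forward–backward: zero-phase filtering
preserves the event latencies the kinetics analysis depends on, whereas the
hardware filter's realization is unknown anyway. No detrending beyond the
isosbestic fit is applied.

## Peri-event analysis

Alignment windows are half-open [lo, hi) on a shared relative-time grid at
the trace's sampling rate; each trial's segment (linear interpolation of
the uniformly sampled trace) is baselined by its own pre-event mean
(default window [−2, 0) s). Omission trials are aligned to the *expected*
laser onset, cue onset + 2 s. AUC is the trapezoidal integral over the
samples inside the closed analysis window, in ΔF/F·s; whether baselined or
raw ΔF/F enters is determined by the tensor handed in (the pipeline uses
baselined rows throughout). Defaults: cue AUC window [0, 1.5] s, omission
window [0, 2] s (surfaced in output metadata — the source analyses state
that region-specific windows were used without printing them), stimulation
windows [0, 5] and [0, 20] s. Aggregation is trials → subject mean →
group test, matching n = 4-subject designs.

## Kinetics

The mean peri-event trace (subject level, not per trial) is smoothed with a
centered moving average — default 0.5 s, forced to an odd sample count so
the window introduces no phase shift — then differentiated with central
finite differences (one-sided at the edges). Point A is the first strict
+ → − sign change of the derivative after the reference time, point B the
first subsequent − → + change; exact-zero samples between the bracketing
non-zero samples are bridged, and the crossing position is linearly
interpolated between them. A derivative that never turns is a no-crossing
result, not an error; subjects without a crossing are excluded from group
comparisons with a warning. The moving-average estimator was chosen because
its bias is analyzable: for noiseless kernels the crossing bias stays below
half the smoothing window (asserted in tests), and the window is recorded
in every output.

## Statistics

All tests are two-sided at α = 0.05. t tests are Student's (pooled variance
when unpaired); zero-variance inputs are flagged as degenerate
(infinite-t) rather than silently propagated. Repeated-measures ANOVA is
computed from the closed-form balanced sums of squares, each
within-subject effect tested against its own effect × subject interaction:
df = (levels − 1, (levels − 1)(n − 1)) per factor. No sphericity correction
is applied, matching the uncorrected df convention of the small-cohort
analyses this layer mirrors; with 2-level factors the correction is moot,
but for the 10-level session factor the uncorrected test can be liberal
under non-sphericity — a documented limitation. The closed-form
implementation is cross-checked against statsmodels' AnovaRM in the unit
tests and exists because the type-I calibration study runs thousands of
replicates. Tukey HSD uses the studentized-range distribution with the
repeated-measures error mean square and df (pairwise q = |mean difference|
/ √(MS_error/n)); the independent-groups Tukey of common libraries does not
match a within-subject design. The pharmacology comparison is implemented
as one-way repeated-measures ANOVA: the printed df pattern of such
analyses, e.g. F(3, 6), is only consistent with a within-subject error term.

## Recovery studies and problem sizes

`optopav.studies` repeats the full simulate → preprocess → align → test
chain over seeds: region ordering of point A (100 seeds × 2 regions × 4
subjects, 20-trial stimulation sessions), omission dip detection and its
dip-amplitude-0 null (100 seeds × 4 subjects, full omission sessions),
learning-curve interaction detection (100 seeds × 4 subjects × 10
sessions), and type-I calibration of every test (2,000 null replicates
against 99 % binomial bounds around 0.05). The studies sample at 20 Hz with
the low-pass stage disabled — the coarsest grid resolving the fastest
kernel — so hundreds of full sessions stay cheap; single-recording analyses
default to 50 Hz with a 12 Hz zero-phase low-pass.

## What passing tests do and do not show

The generator reproduces the *statistical structure* the analyses assume:
shared multiplicative artifacts, kernel-shaped transients on a tonic
baseline, growing cue responses, omission dips, condition scaling. It does
not emulate hemodynamic contamination, sensor nonlinearity or saturation,
state-dependent tonic drift, lock-in demodulation artifacts, or behavioral
covariates (locomotion, licking). Passing recovery studies therefore show
that the analysis chain is correct and calibrated *given* the assumed data
model — not that the model captures every failure mode of real photometry.
Reported headline statistics from 3–4-subject experiments are not
reproduction targets: at that n they are dominated by biological
between-animal variability the generator only caricatures.
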