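# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `saccadapt`.

## The task being modelled

A participant follows a target around a clockwise hexagonal path (six
vertices, 10 dva apart). Sessions have four blocks of 48/96/96/48 trials:
two baselines flanking two adaptation blocks. During adaptation, the target
is displaced while the eye is in flight — either 3.3 dva further along the
saccade trajectory (gain-up) or 2.5 dva back towards the origin
(gain-down). In relative-gain units (post-displacement gain minus one) the
perturbations are +0.33 and −0.25, chosen so the two directions demand
equal relative gain changes (10/13.3 ≈ 7.5/10). Saccades are either
*reactive* (a single target jumps; latencies ≈ 195 ms) or *scanning* (all
six targets stay visible and the next one is selected internally;
latencies ≈ 305 ms).

## Dual-state model

Adaptation is decomposed into a fast process (learns and forgets quickly;
associated with explicit learning) and a slow process (learns and forgets
slowly; implicit learning):

    state_fast(i) = α_f·ε(i) + β_f·state_fast(i−1)
    state_slow(i) = α_s·ε(i) + β_s·state_slow(i−1)
    adaptation(i) = γ_fast·state_fast(i) + γ_slow·state_slow(i)

Rates are fixed at the canonical values α_f = 0.21, β_f = 0.59, α_s = 0.02,
β_s = 0.992; only the process gains γ_fast, γ_slow ≥ 0 are fitted. Fixing
the rates avoids the well-known trade-off between learning/retention rates
and gains; a free-rate variant is deliberately not part of the analysis
surface.

**Error signal.** The error is computed closed-loop by default,
ε(i) = p(i) − adaptation(i−1), where adaptation is the model's own
γ-weighted output. This keeps simulation self-contained and is the
canonical multi-rate formulation. An observed-error mode
(ε(i) = p(i) − (measured gain(i−1) − 1)) is available via
`error_mode="observed"`; which mode the original analyses used is not
documented, so both exist and closed-loop is the default. Note that under
the closed-loop definition the state trajectories depend on γ, making the
fit a genuinely nonlinear least-squares problem.

**Fitting.** `DualStateModel.fit()` runs bounded nonlinear least squares
(γ ≥ 0) with multi-start over three initial points and reports the
condition number of the Jacobian at the optimum as an identifiability
diagnostic (the fast- and slow-only basis responses are far from
collinear; typical condition numbers are ≈ 4). Invalid trials are excluded
from the loss but the state recursion advances on every trial. The
derived *slow ratio* γ_s/(γ_f+γ_s) is the slow process's share of total
fitted gain; it is undefined (NaN, with a warning) when both gains are 0.

At the synthetic noise level (trial sd 0.05, 96 trials) the least-squares
estimator is essentially efficient: its per-cell error matches a
linearised Cramér–Rao computation. γ_fast is intrinsically harder to
recover than γ_slow (its basis response is smaller late in the block), and
recovery is better under gain-up (larger |p|, better signal-to-noise) than
gain-down.

## Exponential timescale model

The first adaptation block is also summarised by
fit(t) = 1 − α·(1 − e^(−t/β)): the curve equals 1 at t = 0 and approaches
1 − α, with α the asymptotic gain-change magnitude (negative for gain-up)
and β the timescale in trials. An algebraic variant
(1 − α)·(e^(−t/β) − 1) + 1, which asymptotes to α instead, is available
behind `printed_form=True`; the default follows the stated property that
the curve approaches 1 − α.

**Fitting.** For fixed β the model is linear in α, so α is profiled out
analytically; the optimisation is a one-dimensional search over β
(log-spaced grid of 60 points over (0, 10·N], then bounded Brent
refinement). The grid plays the multi-start role. Degenerate (flat) series
return α = 0 with `beta_identifiable=False`. Noiseless data are recovered
to |Δα| < 1e-6, |Δβ| < 1e-4.

**Bootstrap.** Condition differences in (α, β) use a paired participant
bootstrap: each fold draws participants with replacement (the same draw
for all conditions), averages their series per condition, and fits the
exponential to each average; p = 2·min(fraction of fold differences below
0, above 0), floored at 2/n_folds. The default is 10^5 folds; this is
tractable because the fold fits use a fully vectorised profile fit (SSE
over a log-β grid for all folds at once, with per-fold parabolic
refinement in log β). Tests and the acceptance script use 10^3–2·10^3
folds.

Calibration: under a null with identical generating parameters and
12 heterogeneous participants, the measured false-positive rate at the
0.05 level is ≈ 0.09 — the tail-fraction bootstrap is slightly
anticonservative at this sample size. Power: reactive-like (β = 8) versus
scanning-like (β = 30) cohorts at trial noise 0.05 are separated with
p < 0.05 in effectively every replicate.

## Saccade detection

The detector is the median-based velocity-threshold algorithm: velocity by
the 5-sample moving-window differentiator
v(i) = (p(i+2)+p(i+1)−p(i−1)−p(i−2))/(6·Δt) per component (edge samples
filled with the nearest interior value), robust spread
σ = sqrt(median(v²) − median(v)²) per component, thresholds η = λ·σ, and
saccades as maximal runs with (v_x/η_x)² + (v_y/η_y)² > 1. Detector
parameters are not documented for this analysis; the package defaults to
standard values λ = 6, minimum duration 6 ms, merge gap 20 ms, all
configurable. Runs closer than the merge gap are merged before the
duration criterion is applied. Detection is never attempted across invalid
(blink) samples, and a zero robust spread raises an explicit error rather
than returning an empty list. Latency is onset minus flash onset (the go
signal) in both saccade-type conditions; negative latencies are returned
but flagged as anticipatory.

## Preprocessing

Trials are rejected, in order (first failing rule wins): (1) blink;
(2) amplitude < 3 dva; (3) amplitude more than 3 two-sided *raw* (unscaled)
median absolute deviations from the block median, the median/MAD computed
over the block's trials passing rules 1–2 and the rule skipped with a
warning below 4 candidates; (4) start point more than 1.5 dva from the
pre-saccadic (fixated) target. When the MAD degenerates to 0 (a majority
of identical amplitudes), the spread is re-estimated from the amplitudes
that differ from the modal value (1.4826-scaled, about their own median)
so duplicate-breaking outliers are still caught.

A consequence worth knowing: inside an adapting block the gain *trend*
itself spreads amplitudes around the block median, so at low trial noise
the MAD rule preferentially rejects the first few adaptation trials
(up to ~30% of the earliest trials at noise sd 0.05 in synthetic
sessions). This censors the transient and inflates fitted fast-process
gains somewhat in synthetic cohorts; the effect is inherent to the stated
rule, not to its implementation, and is weaker at realistic (larger)
amplitude variability.

Amplitudes — and identically peak velocities and durations — are converted
to gains by dividing by the median over valid block-1 trials, per session
and hexagon direction. Invalid trials are carried as missing, never
dropped. Smoothing uses a centred running mean over 6 trials (the
hexagonal period), shrinking at the edges, never crossing block
boundaries. Block-transition change is mean(first 6 trials of the next
block) − mean(last 6 of the previous), over valid trials among those six;
a window with no valid trial makes the participant missing for that
contrast.

## Synthetic-data generator

The generator is first-class, tested code; every downstream stage is
validated against it.

* **Gain series** follow the closed-loop dual-state recursion with
  per-block process-gain truths, plus i.i.d. Gaussian observation noise
  (default sd 0.05 gain units — typical trial-to-trial saccade-gain
  variability). Baseline blocks inherit the neighbouring adaptation
  block's γ (their perturbation is zero, so this only affects washout in
  block 4).
* **Process-gain truths** per saccade type × gain direction are derived
  from an additive decomposition of per-process mean gain (0.576 reactive
  / 0.509 scanning across directions; 0.784 gain-down / 0.301 gain-up
  across types) split by slow-process shares 0.547 (reactive) and 0.749
  (scanning). These truths reproduce the condition contrasts of interest:
  fast gain ≈ 0.27 larger for reactive, slow gain ≈ 0.13 larger for
  scanning. Cohorts add participant-level jitter (γ sd 0.12, clipped at
  0) and participant latency offsets (sd 10 ms).
* **Kinematics** obey a saturating main sequence V(A) = V_max·(1 −
  e^(−A/c)) with standard oculomotor defaults V_max = 500 °/s, c = 14°,
  and a minimum-jerk profile (duration D = 1.875·A/V(A)). Amplitude
  changes are split between peak velocity and duration by a
  velocity-share parameter (0.8 in gain-down blocks, 0.5 in gain-up),
  emulating the finding that gain-down adaptation is carried mainly by
  velocity reductions. The min-jerk identity forces
  vel_gain·dur_gain = amplitude_gain, which real saccades violate
  somewhat; the generator trades that fidelity for internal consistency.
* **Latencies**: N(195, 20) ms reactive, N(305, 20) ms scanning per
  trial, relative to flash onset.
* **Awareness**: 'seen' probability ≈ 0.02 in baselines; in adaptation
  blocks it decays from a start level (0.25, +0.20 for scanning, +0.15
  for gain-down, floor 0.05, time constant 30 trials) as adaptation nulls
  the visible error; 2% of responses are missing.
* **Gaze traces** (optional, 1000 Hz): fixation until flash + latency,
  one main-sequence saccade towards the goal, isotropic positional noise,
  and injectable blinks (invalid/NaN spans).
* **Contaminants**: exact counts of blink trials and amplitude outliers
  (amplitude × 2) can be injected for QC accounting tests.

What the generator does *not* emulate — hence what passing tests do not
show about real data: corrective secondary saccades, pre-saccadic drift
and post-saccadic oscillations, main-sequence deviations after
adaptation, direction-specific baselines, sequential dependencies in
noise, or realistic blink dynamics. Conclusions about detector and QC
behaviour on real recordings should be checked on real recordings.

## Statistics

One-sample and paired t-tests are computed from their closed forms
(p from the t distribution, two-tailed); Cohen's d for paired designs uses
the sd of the differences. Condition summaries report mean, t-based 95% CI
over participants and n, with explicit missingness (no silent drops).
Slow ratios are computed per gain direction and averaged over directions
per participant before testing against 0.5. Repeated-measures ANOVA
machinery is intentionally out of scope; the report carries t-tests,
summaries and bootstrap comparisons.

## Problem sizes used by tests and the acceptance script

Parameter-recovery grids use 25 (γ_fast, γ_slow) cells × both gain
directions × 50–100 replicates of 96 trials; bootstrap calibration uses
300–500 outer replicates of 1000 folds and power 50 replicates of 2000
folds; detector checks use 200 random traces; the cohort analysis uses 12
participants × 4 sessions × 288 trials. These sizes give Monte-Carlo
standard errors comfortably below the asserted tolerances while keeping
the whole suite fast.

## Known limitations

* The closed-loop error definition is an assumption; fits driven by
  observed errors can differ when data are very noisy.
* γ_fast recovery at gain-down/noise-0.05 conditions is at its
  information-theoretic floor (MAE ≈ 0.12); single-participant fast/slow
  decompositions should be interpreted with that uncertainty in mind.
* The participant bootstrap's two-tailed tail-fraction p is slightly
  anticonservative at n = 12 (FPR ≈ 0.09 at nominal 0.05).
* The MAD rejection rule censors adaptation transients at low noise (see
  Preprocessing).
* Online saccade detection (the 1.5 dva polling threshold) exists only in
  the protocol description; offline detection is the analysis path.
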