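# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of the package. It states no
empirical result beyond what the test suite and `scripts/acceptance.py`
compute themselves.

## Task model

The two-step task is parameterized by a 2×2 transition matrix
(rows: first-step options, columns: second-step states) and a length-2
reward-probability vector; defaults are `[[0.8, 0.2], [0.2, 0.8]]` and
`[0.8, 0.2]`, so option S1⁺ commonly (80%) leads to state S2⁺, which pays
reward with probability 0.8. A session has 50 trials; a full course has
60 sessions. Timing defaults: 5 s inter-trial interval, 2 s response
windows, 3 s reward. Synthetic reaction times are uniform on [0.5, 2.0] s
(configurable), which keeps every generated trial above the 0.5 s QC
bound unless a trial is deliberately flagged slow; step-2 peck latencies
are uniform on [0.5, 0.9] s so the 0.5 s pre-peck analysis window falls
inside the 1 s post-transition window. The left/right position of the S1⁺
marker is randomized and recorded but unused downstream.

## SR agent

Values decompose as `Q_S1 = T·R` (row-wise inner product) and `Q_S2 = R`,
where T holds discounted expected transition frequencies and R discounted
expected immediate rewards; with a single intermediate step the horizon
is fixed at one. Choices are softmax in `Q_S1` with inverse temperature
β ≥ 0 (β = 0 is random choice); the implementation subtracts the maximum
logit before exponentiation.

The trial-by-trial estimator for T and R is a design choice of this
package: an exponentially-weighted delta rule with fixed learning rates
α_T = α_R = 0.1 (configurable), with update targets scaled by γ —
`T[c,s] ← (1−α)T[c,s] + αγ` for the observed transition, the chosen row's
other entry decaying by (1−α), and `R[s] ← (1−α)R[s] + αγ·I(reward)` for
the visited state. Rationale: it is the simplest estimator whose
stationary expectation matches the discounted-expectation definitions of
T and R — at γ = 1 the estimates converge to the true contingencies
(checked in tests against an independent running-mean oracle), and γ = 0
forgets all structure. Unchosen options and unvisited states are left
untouched (no counterfactual decay — the minimal assumption).
Initialization is uninformative and γ-scaled: T rows `[0.5, 0.5]·γ`,
R `[0.5, 0.5]·γ`. Note that γ scales both the T and the R targets, so
option values carry γ²; every asymptotic check uses γ = 1 where the
distinction vanishes.

## MAP fitting

The likelihood replays the agent deterministically over the observed
sequence and accumulates the softmax log-probability of each observed
choice. Priors: β ~ Gamma(shape 1.2, scale 5.0) — the shape/scale
parameterization gives a weakly informative prior with mean 6 over the β
range dynamic fits reach — and γ ~ Beta(1.1, 1.1). Optimization is
bounded L-BFGS-B on (γ, β) ∈ [1e-6, 1−1e-6] × [1e-6, 50] with 5 restarts
(one fixed start at (0.5, 3.0), the rest jittered from the priors) and an
objective tolerance of 1e-8; the best restart is returned and a
convergence flag is set if any restart converged. Learning rates are not
fitted.

The dynamic variant splits the sequence into N contiguous, disjoint
windows (default 12 over a 60-session course; configurable) and fits each
window independently. The agent state entering a window is produced by
replaying all earlier trials under the candidate γ being evaluated, which
avoids artificial discontinuities at window edges. Windows under 20
trials are fitted with a warning. Dynamic-vs-static comparison simulates
n_rounds agents (default 50) under each fitted parameterization and
returns session-wise S1⁺ choice-rate curves (mean ± SD) for overlay
against the empirical curve.

## Synthetic LFP generator

The generator emulates a 16-channel, 2 kHz hippocampal recording with
event markers mirroring the behavioral timeline. Nuisance structure, with
default amplitudes in µV chosen to resemble band-limited LFP scales:
per-channel 1/f (pink) background (σ = 20), a shared pink common-mode
component (25) large enough that skipping the re-referencing stage
demonstrably degrades decoding, a 50 Hz line tone (15) with per-channel
random phase, and 20 ms biphasic transients (200, per-channel gains
uniform in [0.5, 1.5]) at every peck.

Planted effects:

- **Value-coupled high-band power.** Each pre-peck second (both steps)
  carries a train of 5 short bursts (20 + 45 Hz carriers, Hann envelopes,
  0.1–0.25 s, uniform random onsets) whose amplitude is
  `a0 + a1·Q` of the current option/state (defaults a0 = 4, a1 = 18).
  Burst spatial gains across channels are lognormal (σ = 0.6), normalized
  to mean 1, and redrawn per occurrence. Two deliberate choices here:
  heterogeneous gains keep the effect from being a pure common mode
  (which the CAR stage would remove), and the random burst timing leaves
  no systematic within-window envelope, so the large S2⁺/S2⁻ amplitude
  difference does not masquerade as a high-band similarity effect
  (cosine similarity is scale-invariant, so incoherent timing averages
  out) while window-mean power still tracks value.
- **Shared low-band pattern.** A 6 Hz component with a trial-specific
  lognormal spatial amplitude pattern (σ = 0.8, mean 1, amplitude 20)
  under Hann envelopes at [−0.7, −0.1] s (step-1 window) and
  [+0.2, +0.8] s (step-2 window) relative to the step-1 peck. On
  common-transition trials past the "learned" boundary the two windows
  share one pattern; otherwise the patterns are independent. The boundary
  defaults to the first trial of the first session whose S1⁺ choice rate
  exceeds 90%.

All planted quantities (amplitudes, per-trial shared flags, artifact
times, the boundary) are returned as ground truth, so every downstream
stage is testable against what was injected. What the generator does
*not* emulate: biophysical LFP forward models, spike contamination,
electrode drift, inter-animal variability, or any coupling beyond the two
planted effects. Passing the end-to-end tests therefore shows that the
analysis chain recovers effects of this structure and size at these trial
counts — not that real recordings contain them.

## Preprocessing

Median downsampling maps each non-overlapping block of fs/1000 input
samples to its median (robust to the brief peck transients). The adaptive
CAR computes per-channel weights proportional to each channel's sliding
1 s correlation with the plain common average (clipped at zero,
renormalized to mean 1), subtracts the weighted average from every
channel, and degrades gracefully to the plain CAR (available as a
fallback). The 50 Hz canceller is a two-weight LMS noise canceller with a
unit-power sine/cosine reference pair; weights update once per 50 ms
block (block LMS), giving a stable range 0 < µ < 2 with default µ = 0.1
(convergence well inside 2 s on a pure tone; equivalent notch bandwidth
≪ 1 Hz, so 45/55 Hz are preserved). QC drops trials with reaction time
strictly below 0.5 s (0.5 s exactly is retained), flagged motion
artifacts, or missed response windows; an RMS-based flagger (epoch RMS
> 5× session median, configurable) can mark gross-motion trials.
Epochs are aligned on the step-1 peck with half-open sample windows:
baseline [−2.5, −2.0) s, choice [−1, 0) s, S2 [0, 1) s, and a single
concatenated [−2.5, 1) s span used for the wavelet transform so analysis
windows are sliced from one transform without seam artifacts.

## Spectral estimation

Morlet wavelets with 7 cycles at all 50 log-spaced frequencies (1–100 Hz)
via MNE's array interface. Because the 1 Hz wavelet (≈11 s at 5 SD) is
longer than the 3.5 s epoch, epochs are reflection-padded (repeated
reflection as needed) to cover the longest wavelet, and power is
decimated to 100 Hz — ample for the 100 ms feature epochs downstream.
Samples within ±50 ms of any peck are masked to missing and excluded from
all averages (never zero-filled); the mask covers the artifact's spectral
smear at high frequencies, while at the lowest frequencies smear beyond
the mask is an accepted limitation of the ±50 ms convention.
Normalization divides each trial's power, per frequency, by the mean
baseline power pooled over electrodes and baseline samples of that trial,
so a constant rescaling of the recording cancels exactly and per-trial
global drift is removed. Bands: δ 1–4, θ 4–8, α 8–12, β 12–30, low-γ
30–60, high-γ 60–100 Hz, with aggregate groups low = 1–12 and
high = 12–100 Hz; band membership is [lo, hi) except the top band, which
includes 100 Hz. Session power dynamics use a centered 5-point moving
average with shrinking windows at the edges.

## Similarity analysis

Feature epochs are 100 ms windows every 20 ms (46 per 1 s window). Power
is averaged per epoch, z-scored per electrode and frequency across all of
the trial's epochs (both windows pooled; SD < 1e-12 guards to z = 0),
then averaged into bands — so band-restricted features are exact subsets
of the full feature set. Per-trial maps hold the cosine similarity of
every S1-epoch × S2-epoch pair; epochs lost to artifact masking propagate
as missing cells. Early/late learning stages are the first/last 100 valid
trials from sessions with S1⁺ rates < 65% / > 90%.

The cluster contrast computes cell-wise two-sample pooled-variance t
statistics (missing-aware), thresholds two-sided at p < 0.05, forms
4-connected supra-threshold clusters separately for positive and negative
signs, scores each by the sum of |t|, and corrects family-wise against
the permutation distribution of the maximum cluster mass under random
reassignment of maps to groups (default 1000 permutations; corrected
p = (1 + #{null ≥ observed}) / (n_perm + 1)). The tROI of a significant
cluster is quantified as the per-trial mean similarity over its cells.

## Choice decoding

Linear-kernel SVM (C = 1, class-weighted) on standardized
electrode × band power features; standardization is fit on the training
split only. Ten repeated stratified 70/30 splits, extended until every
trial has appeared in at least one test set, with per-round accuracy
reported as mean ± SD. Accuracy is *balanced* (mean per-class recall):
late in learning the choice mix approaches 95/5, so plain accuracy would
reward majority guessing and mask the difference between informative and
uninformative feature sets; balanced accuracy keeps chance at 0.5
throughout. The repeated-split scheme is this package's resolution of the
tension between a fixed 70/30 split and exhaustive cross-validation: it
honors the split ratio and still uses every trial for testing.

## Statistical utilities

Two-sample comparisons pass through a Lilliefors normality gate at
α = 0.05: normal data get a (paired) t test, otherwise a Wilcoxon
signed-rank (paired) or rank-sum (independent) test; the gate outcome is
reported alongside the statistic, degrees of freedom where applicable,
and p. Session-wise value regressions are OLS with the regression F test
on (1, n−2) degrees of freedom, fitted per condition and band group with
no multiple-testing correction (none is part of the analysis design).

## Pipeline and reproducibility

A run is fully determined by (config, seed): the root seed spawns one
independent stream per stage, so stages can be re-run in isolation.
Artifacts (trial CSV, HDF5 recording, fit JSON, band-power arrays,
significance masks, summary) are hashed into a manifest; HDF5 files are
written without modification timestamps so identical runs are
byte-identical. The summary reports detection of the four planted
signatures: (1) late > early high-band power for S1⁺/S2⁺, (2) significant
positive high-band power–value regressions, (3) high-band balanced
decoding accuracy exceeding low-band by ≥ 0.1, and (4) a significant
positive low-band common-vs-uncommon similarity cluster late in learning
with no positive high-band counterpart.

## Problem sizes used by the test suite

The suite exercises every property at sizes chosen for a single-CPU run:
parameter recovery uses 1,000 trials × 20 seeds; dynamic-trajectory
recovery 8 windows × 150 trials × 10 seeds; cluster-null calibration
20×20 maps, 24 maps/group, 300 permutations, 200 repetitions; and the
end-to-end signature run 16 sessions × 25 trials (400 trials, 16
channels) with 100-trial stages and 500 permutations. Default
configuration values remain at the full study scale (60 sessions × 50
trials, 1000 permutations).

## Known limitations

- The SR horizon is hard-fixed at one step; the general multi-step
  occupancy sum is out of scope, as are model-free/hybrid learners and
  eligibility traces.
- The estimator behind T/R (delta rule, α = 0.1) is an assumption; fitted
  γ̂ and β̂ are interpretable only relative to it.
- "Adaptive" CAR adapts over channels and time via sliding correlation
  windows; other adaptive re-referencing schemes exist and would give
  slightly different weights.
- The ±50 ms artifact mask does not cover wavelet smear below ~10 Hz;
  low-frequency cells adjacent to pecks inherit some artifact energy.
- Cluster-corrected inference controls the family-wise error within one
  contrast; contrasts are not corrected against each other.
- Synthetic-data results bound what the pipeline can detect under the
  generator's assumptions; they are not evidence about real recordings.
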