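# Methods

This note documents the models and procedures implemented in `myolearn`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic data do and do not establish.

## Task geometry and timing

The trial clock starts when the descending box begins to move; the path's
leading edge reaches the cursor zone at 1.0 s, the path crosses the zone
during [1.0, 1.5] s, and the cursor is hidden from 0.75 s. The canonical
path is a piecewise squared-sine bump in the crossing-time offset τ: it
rises over 0.21 s and falls over 0.29 s, so the displacement peak crosses
at trial time 1.21 s — the anchor used for peak alignment. The bump is
the simplest smooth, compactly supported shape consistent with the task's
amplitude (90 px per magnitude unit) and peak-time anchors, and
its parameters are configurable (`PathShapeParams`). The six variants are
pure scalings and mirrorings of this shape; 25 six-pixel targets are placed
at uniform crossing times.

Pseudo-randomised test blocks (five trials of each of the 12 conditions, no
condition within three trials of its last occurrence) are generated by
sequential construction — each next condition drawn among those absent from
the last three slots, weighted by remaining count — with restart on dead
ends and a 10 000-restart cap. Whole-permutation rejection is hopeless at
this block size (the acceptance probability of a random permutation is
below e⁻¹⁰); the sequential scheme succeeds in a handful of restarts and
its mild ordering bias is irrelevant to the analyses, which never condition
on within-block position.

## Interface chain

Smoothing is a causal weighted average of rectified raw EMG; kernel weights
sum to one, with triangular weights proportional to (256 − lag). Signals
are implicitly zero-padded before t = 0, so the first kernel-length of
output is a warm-up ramp; exactness tests evaluate beyond it. Calibration
takes tail means (final 4 s of the 10 s contraction; final 10 s of the 15 s
rest), and the main-task noise threshold is the 99.99th percentile of a
log-normal fitted to the smoothed rest tail by method of moments on logs
(the maximum-likelihood estimator for this family) plus 1 % of maximum
power; the power-cycle variant uses only the 1 % term. Scaling divides the
threshold-subtracted power by 0.35 × maximum power — the gain reading of
the "35 % of maximum gives 1" anchor; the alternative reading
(denominator 0.35·max − threshold) differs by under ~2 % of range and is
not implemented. Cursor positions are the left-Riemann running integral of
α·(w₁h + w₂s) at 1/2048 s steps, matching a per-sample real-time update
loop; only the session-1 calibration sets the gain — later calibrations
are recorded for noise tracking but never change the interface.

## Synthetic participants

Raw EMG is amplitude-modulated Gaussian white noise: raw(t) =
(envelope(t)·k + floor)·ξ(t). This is the minimal process with
signal-dependent noise — the raw SD, and hence the rectified-smoothed mean
(√(2/π) times the SD), scales with the envelope. A deterministic carrier
(alternating signs at the same expected magnitude) gives exactly noise-free
renderings for closed-loop checks.

Each participant owns, per channel, a burst shape (width ~ log-normal
around 0.25 s, rise fraction ~ 0.45, squared-sine family) and a fixed
amplitude repertoire with one entry per (channel, magnitude), set so the
burst area integrates to the path amplitude times a log-normal personal
gain. The repertoire never changes across sessions; only the jitter around
it decays. Trials draw the two channel peak times from a bivariate normal
(first-channel mean 1.105 s plus a late-onset bias, inter-peak interval
0.25 s, correlation ρ ~ 0.6 per participant) and amplitudes log-normally
around the repertoire entry. Learning is geometric decay per session of the
timing bias (0.7/session), timing SD (0.85) and amplitude jitter (0.85);
the incongruent group starts with 1.4× larger spreads. All hyperparameters
are stand-ins chosen for plausibility — e.g. they put hit percentages near
the mid-teens and session-1 RMS near 50 px on the 90–270 px paths — not
estimates of any real population, and they are recorded in outputs.

Rendering inverts the measured chain: the target control profile is mapped
to a smoothed-power target (threshold + 0.35·max·control inside the burst,
tapering over 60 ms to the rest level outside, so thresholding reproduces
the control target without edge artefacts), the smoothing kernel is
deconvolved out by regularised FFT division, and the result is clamped at
the noise floor. One physical constraint remains: after a burst the causal
kernel's memory flushes over ~125 ms, and non-negative raw power cannot
cancel that tail within one channel. Real profiles keep this tail (real
EMG behaves the same way). The *ideal* participant — noise- and jitter-free,
with quarter-sine bursts equal to the canonical path's velocity lobes —
enables `compensate_flush`: an iterative correction (damping 0.5, 40
iterations) that lifts the *opposing* channel by the flush excess, which
leaves the weighted velocity sum, and hence the trajectory, essentially
exact (RMS ≤ 0.3 px, 100 % hits, aligned peak at 1.21 s). This models a
skilled user's anticipatory co-activation and is off by default.

## Feature extraction

"Non-zero activity" means strictly positive post-threshold control signal;
a qualifying run must be strictly longer than 16 samples; the channel peak
is the maximum inside [0.7, 1.8] s lying in such a run, earliest sample on
ties, and initiation is that run's start. Alignment finds the trajectory's
maximal |displacement| between the two channel peaks (again earliest on
ties), shifts it to 1.21 s and resamples 2048 → 1000 Hz, linearly
interpolating with boundary-value extension. ε and hit percentage are
invariant to pure time shifts by construction; the pre-alignment peak time
is not, and serves as the timing measure. A target is hit when the aligned
position at the target's crossing time is within its 6 px radius — a
point-cursor rule; the contact geometry admits alternatives (e.g. a full
two-dimensional sweep intersection), and this instant-of-crossing test is
the recorded default. Participants are
excluded when their mean cursor amplitude exceeds twice the maximum
required (540 px) or their mean peak time falls after trial end (1.5 s).

## Bayesian models

All models operate on transformed features. Centring a positive feature
before taking logs would produce logs of negatives, so the only coherent
order — log, then centre, then scale to unit pooled sample SD (denominator
n − 1) — is implemented, with the transform recorded and invertible. Peak times are positive on the trial clock, so the same log
transform applies; `transform="standard"` (no log) and `transform="none"`
are config switches, the latter used when data are already on the model
scale (as in calibration studies of the sampler itself).

The hierarchical model and the channel-feature model are linear-Gaussian
hierarchies, which the implementation exploits: the per-cell means are
marginalised analytically (each cell's data are Gaussian with covariance
σ²I + τ²J, τ the cell-mean prior SD), the ensemble MCMC sampler (`emcee`,
differential-evolution and snooker moves, walkers initialised at empirical
cell statistics) samples only the group means and log-SDs, and the cell
means are then drawn exactly from their conjugate Gaussian conditionals.
This Rao-Blackwellisation halves the dimension and makes the cell-mean
draws exact given the sampled scales; in recovery simulations the 95 %
credible intervals for cell means attain ~95 % coverage, while the σ
intervals remain slightly narrow (~85 % at 32 cells) — a known
underdispersion of affine-invariant ensembles that longer chains reduce
only slowly, and which does not affect the mean-comparison Bayes factors.
Defaults: 2000 burn-in steps, ≥ 4000 kept draws pooled over walkers,
split-R-hat over four pooled walker groups with a 1.05 convergence flag
(non-convergence is flagged, never silently discarded). The correlation
model samples (μ₁, μ₂, log σ₁, log σ₂, atanh r) directly — five dimensions
need no marginalisation — with a hard |atanh r| ≤ 8 bound that keeps the
posterior proper when pairs are exactly collinear. The preview-time
variant of the hierarchical model is obtained by passing preview time in
the day slot.

Bayes factors use satisfaction proportions of posterior and prior draws;
the prior draws come from the full joint prior pushed through the same
marginalisation (e.g. across-participant averaging) as the posterior.
Zero counts are replaced by 1/(N + 1) and flagged as bounds, so BF10·BF01 =
1 holds exactly and no infinities are reported. Improver classification is
strict: BF10 > 3.

## Similarity analyses

Minimum-difference statistics use absolute differences for scalars and
Euclidean distances for fPCA score vectors; the 99th percentile uses linear
interpolation between order statistics (the common default; recorded in
output metadata), and the reported trial pair is the one whose minimum lies
closest to the percentile value. fPCA is a discretised covariance
eigen-decomposition (SVD of the mean-centred profile matrix) on the common
grid, without basis smoothing. KDE modes use a Gaussian kernel with
Silverman bandwidth on a 512-point grid spanning the data ± 3 bandwidths;
bandwidth and percentile conventions are free choices, so these defaults
are recorded in output metadata rather than asserted as canonical. The distinguishable label
requires all three pairwise modal gaps of some channel to exceed 0.2.

## What the synthetic tests show — and what they do not

The generator gives every downstream stage a known ground truth: channel
peaks recover generating latents (r > 0.95 at the default noise), the
repertoire-fixity control produces near-zero 99th-percentile minimum
differences, the session decays produce positive learning Bayes factors,
and the ideal participant closes the full loop to sub-pixel accuracy.
Passing these establishes the correctness of the pipeline's computations,
not any property of real muscle physiology: the carrier is white (band
limitation is a config option), there is no fatigue, crosstalk or electrode
artefact, incorrect activation orders are rare under the default timing
spread, and cohort-level conclusions about real behaviour depend on real
recordings, which this package deliberately does not require.

## Problem sizes and numerical tolerances

Tests and the reproduction script run at reduced sizes chosen as the
package's own verification budget: cohorts of 2 + 2 participants with
shortened blocks, 20 replicate hierarchical fits, 50 correlation fits, and
200 simulation-based-calibration replicates at reduced draw counts (the
χ²-uniformity check on rank statistics passes at p ≈ 0.3–0.5). Alignment
and resampling comparisons allow one sample period (interpolation
tolerance ~1e−6 of amplitude for repeated alignment); exact-arithmetic
checks (kernel weights, tail means, Riemann sums, percentiles) are asserted
to machine precision against brute-force oracles.
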