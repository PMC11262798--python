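# Methods

This note documents the models, estimators and design choices behind
`thetabmi`, in the order data flows through the system.

## Streaming coherence estimator

Two time-aligned LFP channels (nominally 2 kHz, 1–600 Hz bandlimited,
microvolt scale) are processed in overlapping windows of 1.25 s advanced in
0.25 s steps. Each window is detrended by subtracting its least-squares
cubic fit and z-scored against a pre-session baseline (mean and SD of a
calibration recording, per channel). Magnitude-squared coherence is
estimated by Welch averaging: 0.5 s Hann-tapered segments with 50% overlap
(K = 4 segments per window), FFTs zero-padded so every point of the fixed
1–20 Hz grid (0.5 Hz spacing) falls on a bin. The window length and grid
are the design constants; the segment scheme is this implementation's
choice and is exposed in `WindowSpec` (`seg_len`, `seg_overlap`) so it can
be varied. "Theta coherence" is the arithmetic mean of the coherence over
the grid points in [6, 11] Hz inclusive — 11 points at the default spacing
— and delta coherence likewise over [1, 4] Hz (7 points).

Two estimator facts matter for interpretation and are asserted by test:

- **Positive bias.** For independent inputs the Welch MSC estimate has
  expectation ≈ 1/K_eff, where K_eff < K accounts for segment overlap
  correlation; at the defaults K_eff ≈ 3.84, bias ≈ 0.26. The closed form
  (from the Hann overlap correlations) is the reference the implementation
  is checked against.
- **Low-frequency degeneracy.** A 1 Hz component completes barely one cycle
  per window, so the per-window delta-band coherence estimate has very few
  effective degrees of freedom and a heavy upper tail; strong narrowband
  theta additionally leaks into delta bins through the taper sidelobes
  unless independent delta-band energy masks it. Chance delta-dominance on
  artifact-free windows is therefore a property of the estimator itself,
  not a bug in the gate (see *Validation regimes* below).

## Artifact gating

A window is excluded (can never trigger) if, in either channel, the
fraction of samples with |z| > 4 strictly exceeds 1% — exactly 1% passes —
or, failing that, if delta coherence exceeds theta coherence. Saturation is
checked first: a saturated window's spectra are meaningless, so its
delta/theta comparison is never consulted. The delta comparison uses band
means (band peaks would be an alternative reading; means are implemented).
Zero-variance windows (hard-clipped flat) have undefined coherence and are
emitted as saturated with a NaN spectrum.

## Threshold calibration and detection

Per subject, the trigger thresholds are the mean ± one sample standard
deviation (n−1 denominator) of a distribution of clean theta-coherence
values; each subject therefore carries unique numerical thresholds. No
floor at zero is applied to the low threshold. The detector slides the
window by one step, evaluates only full windows, and triggers on the first
clean window at or beyond the threshold (≥ high in high mode, ≤ low in low
mode); if none crosses within the timeout (30 s delayed alternation, 20 s
conditional discrimination) the trial starts at the timeout. The z-score
baseline is per-channel; a pooled baseline would be the other reading.

## Trial scheduling

Sessions are planned in 10-trial blocks. Delayed alternation: 1 high,
1 low, 1 yoked-high, 1 yoked-low, 6 random-delay trials per block (the only
integer solution to 10%/10%/20%/60%); conditional discrimination: 4 high,
4 yoked-high, 2 random. Block orders are sampled uniformly over admissible
permutations (rejection sampling): the k-th yoked trial of a type must
follow the k-th experimental trial of that type, because a yoked trial
replays its partner's logged delay bit-exactly. On a detector timeout the
trial starts at the timeout and the earliest pending yoked partner in the
block is converted to a random-delay trial in place (block length stays
10), with a provenance flag for accounting. Random delays are uniform on
[5, 30] s. The conditional-discrimination minimum wait (uniform on
[3.5, 5] s — the protocol states a range, not a fixed value) applies as a
floor to every trial's delay. Session screens: conditional discrimination
requires performance strictly above 70%, alternation strictly below 70%,
and at least three coherence-triggered trials; delayed alternation requires
performance of at least 70%.

The rat is a caller-supplied outcome hook: a per-trial-type probability of
a correct choice. The defaults (high 0.90, low 0.70, yoked/random 0.75)
mirror the qualitative effect the interface targets — choices presented
during strong coherence succeed more often than delay-matched controls —
and are knobs, not estimates.

## Offline analyses

**Power.** Multitaper spectra use 3 Slepian tapers with time-bandwidth
product 2, averaged and log₁₀-transformed to counter the 1/f power law.
Theta peak frequency is the argmax of power in [4, 12] Hz, ties broken
toward the lower frequency. The offline theta band for power comparisons
is 6–9 Hz; the real-time detection band stays 6–11 Hz; both are module
constants.

**Coherograms.** Event-locked epochs (default 2 s before to 0.5 s after
choice-point entry) are scanned with the same moving window as the
real-time estimator and averaged across events; the internal window scheme
is declared, not inferred.

**Autocorrelation vs. shuffle.** The theta-coherence series (0.25 s step)
is autocorrelated with the biased, lag-0-normalized estimator (guarantees
|r| ≤ 1); the null is built from random temporal permutations of the same
values, preserving the multiset exactly. Because adjacent windows share
samples, comparisons are reported only from the fifth lag on (index ≥ 4
relative to lag 0). Two null bands are computed: a pointwise central-95%
band per lag, and a simultaneous band calibrated on the maximum studentized
deviation across reported lags. A whole-curve containment statement ("the
series stays inside the null at all lags") is only well-posed against the
simultaneous band — a pointwise band's joint coverage decays as 0.95^K and
would reject most i.i.d. series by chance; single-lag exceedance tests use
the pointwise 97.5% bound.

**Granger prediction.** All fits are ordinary least squares on lag-stacked
regressors with MLE residual normalization, so nested models always
satisfy Var[e] ≥ Var[ε] and both time-domain directions are nonnegative.
(The upstream toolbox's "LWR" estimation mode denotes the
Levinson–Wiggins–Robinson recursion; OLS is the reference estimator with
the identities used here and is what this package implements.) Model order
comes from per-signal univariate BIC (orders up to 20, all candidates fit
on the same rows), the median across signals rounded half away from zero.
Spectral estimates follow Geweke: with transfer H(ω) = (I − Σ A_l
e^{−iωl})⁻¹, spectrum S = HΣH*, and the source innovation partialled on
the target (Σ_ss|t), the directed spectrum is
ln[S_tt / (S_tt − H_ts Σ_ss|t H_ts*)]. Its mean over frequency matches the
time-domain log-variance ratio (integral identity) within a fraction of a
percent on stable simulations. Pairwise-conditional GC for three sites
uses the two-model approach: the full VAR's autocovariance sequence (solved
through the companion-form Lyapunov equation, then the Yule–Walker
recursion) yields a long-order reduced VAR over each source-omitted pair
via the block-Toeplitz Yule–Walker equations; the conditional spectrum is
formed from Q(ω) = Ḡ(ω)⁻¹H(ω) with the reduced inverse transfer embedded
over an identity in the source slot. Desk-scale defaults (autocovariance
lag 200, reduced order equal to it) replace the upstream 100-lag/1000-lag
search; both are parameters. Epoch lists are fit without ever regressing
across an epoch boundary. Stability (companion spectral radius < 1) and
autocovariance positive-definiteness are checked before any GC is formed.

**Spike-phase entrainment.** Epochs for spike analyses are screened by a
per-region z cutoff (computed on the concatenated session signal; default
4 SD, a required parameter since the upstream rule assigned cutoffs per
session without a stated formula) with the same >1% rule, plus an absolute
±3500 µV limit on mPFC/VMT channels; survivors are concatenated and spike
timestamps mapped into the concatenated timeline with duplicates removed.
Phases come from the 4–12 Hz third-order Butterworth filtered signal
(zero-phase forward–backward, so no lag shift) via the Hilbert transform;
a spike counts only when the instantaneous theta envelope is at least
twice the delta envelope (windowed-RMS gating is available behind a flag).
Rayleigh's test uses z = N·R̄² with the standard small-sample correction;
units need strictly more than 50 gated phases in both coherence states.
The bootstrapped MRL draws 50 phases without replacement (the most literal
reading of "using 50 spikes"; with-replacement is a flag), 1000 draws,
averaged — under uniformity it concentrates at √π/2·50^{−1/2} ≈ 0.125, and
for von Mises phases at I₁(κ)/I₀(κ). Spike-field coherence convolves the
LFP with L2-normalized six-cycle complex Morlet wavelets on the 1–20 Hz
grid and takes |Σ e^{−iθ_k}|/N over spike-time phases; it is phase-only,
hence amplitude-invariant, and spikes within half a wavelet support of a
record edge are ineligible at that frequency.

**Behavior.** Tracks are smoothed with a Gaussian-weighted moving average
(default width 0.2 s, σ = width/5, truncated-renormalized at the edges).
Velocities use discrete time-adaptive windowing: around each sample the
symmetric window grows (3–15 samples by default, tolerance 1 position
unit) while all interior points stay within tolerance of the chord joining
the endpoints; the derivative is the endpoint difference quotient. This
suppresses differentiated jitter during stationary dwell. Phi is the
four-quadrant angle of (dX, dY) (a principal-branch arctangent of a ratio
would be ill-defined), unwrapped; dPhi applies the same adaptive windowing
to the unwrapped heading; IdPhi is the time integral of |dPhi| — zero for
straight runs, 2π for one smooth loop, invariant to rigid motion. Distance
traveled sums successive Euclidean steps (by default over the last 1.25 s
before the trigger) and is min-max normalized per session; a degenerate
session (all distances equal) normalizes to zeros with a warning rather
than NaNs. Scores are in native tracker units unless the track carries a
cm scale. Time-to-choice pairs each door opening with the next
choice-point exit; unmatched or out-of-order events are flagged, never
silently dropped.

**Statistics.** Bonferroni multiplies the raw p by the declared number of
tests (capped at 1); Benjamini–Hochberg is the step-up procedure (used for
more than ~5 comparisons); normalized difference scores (X−Y)/(X+Y) are
tested against a zero null with a two-sided one-sample t-test.

## Synthetic data: what it emulates, and what it does not

Oscillators are narrowband-filtered Gaussian noise (theta: ±1.5 Hz around
8 Hz; delta: 1–4 Hz) plus white noise, on a nominal µV scale (theta
amplitudes ~200 µV, saturation injected at ±2000 µV) so absolute-voltage
rules are meaningful. A pure tone was deliberately avoided — tones at a
shared frequency carry a fixed relative phase and produce unit coherence
even with zero coupling — and no deterministic drive is added for the same
reason. Inter-site coupling is a shared narrowband theta component whose
mixing weight follows an alternating high/low state track; the frozen
default high-state weight (1.7) was calibrated once by brute-force sweep
against the package's own estimator to yield ≈0.70 MSC at 8 Hz on clean
windows at 2 kHz, then fixed. Artifacts are contiguous clipping runs and
Hann-windowed 1.5–3.5 Hz transients, injected identically into both
channels of a pair (movement artifacts are common-mode in vivo) and always
returned with ground-truth intervals. Spike trains draw phases directly
from the requested von Mises law and invert the monotonicized Hilbert
phase of the band-filtered LFP, snapping to sample centers and discarding
placements on phase slips, so the measured phase distribution matches the
law it was drawn from. Trajectories are constant-speed paths: straight
(constant heading) or tortuous (zig-zag with periodic heading reversals).

Real LFP is none of these things — it is nonstationary, broadband, with
state-dependent spectra, volume conduction and electrode drift. Passing
tests on this generator shows that the estimators and the decision logic
are correct on data satisfying their assumptions; it does not certify
performance on recordings.

Two validation regimes are frozen constants of the package:

- the **default regime** (theta coherence ≈ 0.7 in high states, ≈ 0.45 in
  low states after clean-window selection) exercises detection, scheduling
  and the burst-rejection rule under realistic ambiguity;
- the **clean theta-dominant regime** (`CLEAN_THETA_SPEC`: shared 1200,
  private 15, noise 15, delta 300, constant-envelope oscillators) is used
  to measure false rejections of the artifact gate. Constant-envelope
  (phase-noise) oscillators are essential there: Gaussian narrowband
  envelopes occasionally exceed 4σ for more than 1% of a window — a
  correct rejection by the stated rule, not a false one — and the chance
  delta-dominance tail only drops below measurability when theta coherence
  is pushed to ≈0.997 with independent delta noise masking spectral
  leakage. In this regime no uncorrupted window was rejected in >25,000
  windows.

## Numerical choices and degenerate inputs

Seconds as 64-bit floats throughout; epochs are half-open sample-index
intervals; event-time→sample-index conversion floors toward −∞. The cubic
detrend fits on a normalized abscissa for conditioning. Coherence values
are clipped to [0, 1] against rounding. Threshold-profile algebra
(high − low = 2·sd) holds to the last floating-point bit but not always
bitwise, since (mean+sd)−(mean−sd) rounds once. Calibration rejects
degenerate (zero-variance) distributions; the coherence estimator rejects
zero-variance windows; Rayleigh exclusion (N ≤ 50) returns a sentinel
rather than raising, since exclusion is an expected outcome. The
bootstrapped MRL is clamped at 1 against accumulated rounding.

## Problem sizes in the validation suite

The validation studies (`thetabmi.validation`, driven by
`scripts/acceptance.py` and the acceptance tests) use: 100 scheduler
blocks; 1000 scheduled trials; 1000 independent-noise windows and 500
windows per coherence state at 1 kHz; 10,000 calibration values; 300
saturation-corrupted and 1000 clean windows; 100 seeds of length-20,000
unidirectional VARs and 100 AR(2) ensembles of length 5000; 5000 phases
per von Mises concentration with the 50×1000 bootstrap; 500 null units for
Rayleigh-p uniformity; 1000 independent spikes for the SFC null; and 20
runs of the 300-point autocorrelation null with 200–300 shuffles. One full
pass takes tens of seconds on a laptop-class core.

## Known limitations

No vendor acquisition formats, no spike sorting, no hardware latency
modeling, no adaptive re-calibration of thresholds mid-session, no
state-space Granger variants, and no claim that the oscillator model is a
generative account of real LFP. The conditional-GC reduced model is a
long-order VAR approximation to the exact VARMA reduction; its order is a
parameter, and the defaults trade exactness for desk-scale runtime.
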