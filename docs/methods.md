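# Methods

This note documents the models, conventions and numerical choices behind
`autonomics`: what each stage computes, which knobs matter, what the
synthetic cohorts do and do not emulate, and where the design was
genuinely open.

## Signal model and preprocessing

**ECG → tachogram.** R peaks are detected with a Pan-Tompkins chain:
zero-phase 5–15 Hz band-pass, differentiation, squaring, 150 ms
moving-window integration, adaptive signal/noise thresholds with
search-back for missed beats, and a 200 ms refractory period.  Peak times
are refined to the extremum of the band-passed trace within ±100 ms.  The
tachogram (RR series, ms) is the sequence of inter-peak intervals.

**RR correction.** Manual beat editing is replaced by a deterministic
rule: an interval deviating more than 30 % (configurable) from the running
median of 9 neighbors is linearly interpolated from the surrounding good
intervals and flagged.  The rule is iterated to a fixpoint — repairing a
spike can expose a borderline neighbor — which makes the operation
idempotent.  If more than 20 % of a segment's intervals are flagged, the
segment is rejected as low quality.  Removal (instead of interpolation) is
available; interpolation is the default so that windowed series keep their
beat alignment.

**Respiration.** The belt signal is low-pass filtered at 10 Hz (symmetric
Kaiser FIR, ≥ 60 dB stop-band, applied by reflection-padded convolution so
that the phase is exactly zero and edges see no artificial step),
downsampled to 64 Hz, and band-passed 0.05–1 Hz (4th-order Butterworth,
forward–backward).  Filters are specified by their response (cutoffs,
stop-band attenuation) rather than tap counts, since tap counts are not
portable across ripple/transition choices.  Breaths are positive peaks of
the conditioned trace with prominence ≥ 0.2 on the max-abs-normalized
trace and spacing ≥ 1.5 s (equivalently a 40 breaths/min ceiling).  The
**respirogram** samples the conditioned respiration at each R peak
(nearest sample), giving a series beat-synchronous with the tachogram.

**EDA.** Conductance is low-pass filtered at 2.5 Hz (zero-phase Kaiser
FIR), downsampled to 16 Hz, and z-scored over the full recording; phasic
features are therefore in normalized units.

**Windows.** All indices are computed on the central four minutes of each
protocol phase (REST, MIST, MGT, VS), centered on the arithmetic midpoint
of the phase span.  RR intervals and breath-to-breath intervals must lie
entirely inside the window.

## HRV indices

**Time domain.** meanRR, stdRR (sample SD, n−1) and RMSSD
(√mean(ΔRR²)), all in ms.

**Univariate spectrum.** The detrended RR window is modeled as AR(p),
`y(n) = −Σ a_i y(n−i) + u(n)`, fitted by Yule–Walker (Levinson–Durbin on
the biased autocovariance, which guarantees a stable model).  The order is
selected in 7–15 by AIC = N ln σ̂² + 2p; residual whiteness is checked by
Ljung–Box (lag 20, α = 0.05) and reported as a flag.  The PSD is
`T σ² / |A(e^{2πjfT})|²` with T the window's mean RR in seconds, so the
PSD integrates to the process variance in ms².  Band powers (LF
0.04–0.15 Hz, HF 0.15–0.4 Hz, half-open bands) use the classical pole
decomposition: the lag-zero autocovariance is split into the residue
contributions of the individual poles (conjugate pairs pooled), and each
component is assigned to the band containing its central frequency
`|arg p_k| / (2πT)`.  The components sum to the process variance exactly
(machine precision; the suite checks 1 %).  Normalized powers are
100·band/(total − VLF) with VLF the components below 0.04 Hz.  Individual
residue components can be negative for heavily damped poles; this is a
known property of the decomposition and does not affect well-separated
resonances, for which pole components and numeric band integration agree
(the suite checks 10 % in the sharp-resonance regime, pole moduli ≥ 0.98).

**Bivariate decomposition (RSA).** The pair (RR, respirogram), both
detrended, is modeled as a two-channel AR process fitted by the
multichannel Yule–Walker equations solved with the
Levinson–Wiggins–Robinson recursion; order again 7–15 by the multivariate
AIC = N ln det Σ̂ + 2(4p), whiteness checked per channel.  With
H(f) = [I + Σ A(i) e^{−2πjfiT}]⁻¹ and the innovation covariance forced
diagonal (σ₁², σ₂²), the RR auto-spectrum splits into

    S11(f) = |H11|² σ₁² T  +  |H12|² σ₂² T ,

whose two-sided integrals over [0, Nyquist] are **PNCOH** (intrinsic, not
coherent with respiration) and **PCOH** (respiration-coherent; the RSA
index).  Integration uses the trapezoid rule on a 1024-point grid.  The
diagonal forcing is required for a unique split and presumes uncorrelated
channel innovations; the off-diagonal correlation of the raw estimate is
kept as a diagnostic.  PCOH + PNCOH matches the window variance within
~10 % when that presumption holds.  A vanishing PCOH reports the ratio
PNCOH/PCOH as missing rather than infinite.

**Nonlinear.** Sample entropy uses m = 2, Chebyshev distance, tolerance
r = 0.2 × SD of the analyzed window, self-matches excluded and N−m
templates for both lengths; zero counts yield a missing value, never ±∞.
DFA integrates the mean-centered series, removes a per-box least-squares
line (every integer box size, non-overlapping boxes) and regresses
log F(n) on log n over 4–12 (a1) and 12–64 (a2) beats.  The residual mean
square per box uses an (n−1) normalization: the degrees-of-freedom
correction removes most of the small-box bias of least-squares detrending
(theoretical white-noise a1 is 0.520 with this convention over boxes 4–12,
versus 0.608 with 1/n; a Brownian input gives 1.418).  A constant input
has zero profile and yields missing slopes; a pure linear trend gives the
textbook trend-dominated a1 ≈ 2.  Poincaré indices come from the lag-1
variance identities, SD1² = RMSSD²/2 and SD2² = 2·var(RR) − SD1² with the
population variance, so SD1 = RMSSD/√2 and SD1² + SD2² = 2·var(RR) hold
exactly; a geometric ellipse fit agrees asymptotically.  Nonlinear indices
take the RR series in seconds by default (SD1/SD2 magnitudes ~0.02/0.07),
configurable to ms.

**Respiration and EDA features.** meanBB and stdBB are the mean and
sample SD of the breath intervals fully inside the window (≥ 5 intervals
required, else missing).  EDA decomposition exploits that the discretized
Bateman kernel (τ₁ = 0.75 s, τ₂ = 2.0 s; standard skin-conductance values)
is the impulse response of a two-pole IIR system, so its exact inverse is
a three-tap FIR recursion.  The deconvolved driver is smoothed (Gaussian,
SD 0.25 s), a slow tonic driver (centered 20 s running median, unbiased
under linear drift) is subtracted, and the non-negative remainder is
segmented into SCR lobes at the minima between peaks.  An SCR's amplitude
is the integrated driver mass of its lobe — for an ideal impulse of
amplitude A this recovers exactly A, and superposed responses separate at
the driver level.  The detection floor is the larger of the
`min_amplitude` (default 0.01 normalized units) implied peak height and
5× a robust (MAD) estimate of the residual driver noise; peaks within the
tonic-window reach of the trace boundaries are discarded as edge
artifacts.  Window features are nSCR (count, reported per minute), SCR
(mean amplitude of the detected SCRs — the "mean amplitude of the phasic
driver" is interpreted as a mean over detections) and AmpSum (sum of
amplitudes).  Tonic-level features are deliberately not computed.

## Statistics

The battery is non-parametric throughout.  A Lilliefors-corrected
Kolmogorov–Smirnov screen plus a QQ-straightness summary is informational
only.  Friedman's test (χ², 3 df, midrank tie correction) compares the
four matched conditions; when it rejects at α = 0.05, all six pairwise
Wilcoxon signed-rank tests are run with Bonferroni ×6 correction, a
direction flag (sign of the median difference) and the non-parametric
effect size r = |Z|/√n (n = non-zero pairs; Z from the normal
approximation with tie and continuity corrections).  Exact p-values are
used for n ≤ 12 without ties; an exact Friedman p is available for small
cohorts by dynamic-programming enumeration of the per-subject rank
permutations (states are rank-sum vectors, making (k!)^n tractable).
Between-group contrasts use Mann–Whitney U on per-subject task − REST
deltas with r = |Z|/√N.  Spearman correlations link physiological deltas
to SUDS change and to cortisol percentage change 100·(t0 − t)/t0;
cortisol t1/t2 vs t0 uses paired Wilcoxon, with a mean + 3 SD outlier
exclusion available for the correlation stage.

## Multivariable stage

Candidate features default to the panel nSCR, AmpSum, meanRR, meanBB,
PCOH, PNCOH/PCOH, SamEn, SD1/SD2, with a configurable extra slot.
Greedy correlation pruning removes, while any |Pearson r| > 0.75 remains,
the member of the worst pair with the higher mean absolute correlation
(ties keep the earlier column).  Each binary contrast (REST vs MIST/MGT/
VS) is evaluated by a 100-tree random forest under leave-one-subject-out
CV; z-scoring is fit on the training subjects and applied to the held-out
subject (global pre-CV scaling is available as `scaling="global"`, but the
fold-wise default avoids leakage).  The procedure repeats over seeds
derived from a master seed (the first n states of
`numpy.random.SeedSequence(master)`, shifted below 2³¹); accuracy is
pooled over held-out rows and averaged across repeats.

Feature importance is the mean absolute Shapley attribution of the
held-out predictions (training-set attribution is a switch).  Because no
Shapley library is assumed, attributions are computed exactly in-package:
for each tree the coalition value v(S) is the cover-weighted conditional
expectation (follow the sample's branch for features in S, average
children by training cover otherwise — the value function of
path-dependent tree attribution), and the Shapley combination runs over
all 2^M coalitions.  This is exact (the efficiency identity
Σφ + E[f] = f(x) holds to machine precision, asserted at 1e-6 in the
suite) and fast for panels up to the enforced M ≤ 15.

## Synthetic cohorts

The generator realizes the two-component HRV model the analysis assumes:
per beat, `RR(n) = meanRR + g·resp(n − lag) + e(n)` with a unit-RMS
quasi-sinusoidal respirogram (cycle periods drawn truncated-normal,
≥ 1.5 s), gain g in ms, and AR(2) noise with a low-frequency resonance
(poles at modulus 0.85, ≈0.09 Hz) scaled to a target process variance.
The coupling lag defaults to one beat: with instantaneous coupling the
true innovations of the two channels are cross-correlated and the
diagonal-forcing decomposition overcounts PCOH + PNCOH by tens of
percent, whereas the strictly lagged model matches the uncorrelated-
residual regime the decomposition is defined for (lag = 0 remains
available).  The realized coherent fraction g²·var(resp)/var(RR − mean)
is recorded per phase as the recovery target.

Raw traces are layered on the beat-level truth: ECG as a Gaussian R
template (10 ms SD) at the cumulative beat times at 2048 Hz (no P/T waves
or artifacts — detector validation, not morphology, is the goal),
respiration as the sinusoid of the breathing phase at 2048 Hz, EDA as
baseline + linear drift + Bateman responses at Poisson event times
(≥ 2 s apart, kept 25 s from phase edges) at 256 Hz, with optional white
sensor noise.  Default phase durations are REST 300 s, MIST 360 s,
MGT 300 s, VS 300 s, analyzed over their central four minutes.

Cohort-level defaults encode only effect *signs* expected under task
load — meanRR, RR variability, respiration-to-RR gain and breath period
lower in tasks than REST, SCR rate/amplitude higher, an extra MIST meanRR
drop and larger SUDS increase in the STRESS group, null cortisol — with
magnitudes chosen once to sit in the physiologic range of short-term
recordings (e.g., REST noise variance 2100 ms², gain 23 ms → PCOH ≈ 530
ms²; breath period 3.9 s → 3.2 s).  They are configuration, not empirical
claims.  `EffectConfig.null()` removes every systematic effect for
type-I-error studies.  Identical seeds give bit-identical cohorts.

Two routes produce the feature table: the **raw route** (full detector
chain) and the **beat route** (features computed from the recorded
beat-level truth, EDA still synthesized and decomposed).  The beat route
exists for large simulation studies; the suite checks that the two routes
agree on shared indices.  What passing tests show about real data is
limited accordingly: the generator has no ectopy, no movement artifacts,
no non-stationary within-window drifts beyond a linear EDA trend, and a
strictly linear respiration→RR path, so the validations certify the
estimators under the model's assumptions, not robustness to every
clinical artifact.

## Problem sizes in the validation suite

Simulation-based checks run at sizes chosen to keep the full suite
comfortably reproducible on one CPU: 100 random AR models for power
conservation, 100 replicates (~240 beats each) for coherent-fraction
recovery, 200 runs for DFA calibration, 500 null cohorts of 60 subjects
(beat route, time-domain and respiration features) for the type-I-error
check, 100 label-permutation repeats at 30 subjects, and 50
planted-effect cohorts of 24 subjects with 2 CV repeats each for the
Shapley ranking check.

## Known limitations

* The EDA tonic estimate is held only to the reconstruction identity;
  tonic features are out of scope by design.
* Residue components of heavily damped poles can be negative; band powers
  are reported as-is rather than clipped.
* The exact Shapley enumeration is exponential in the panel size
  (practical to M = 15); larger panels would need the polynomial-time
  recursion.
* The Pan-Tompkins detector is tuned for upright R deflections; inverted
  leads would need a polarity switch upstream.
* With instantaneous respiration→RR coupling (lag = 0) the diagonal
  innovation assumption is violated by construction and PCOH + PNCOH
  exceeds the window variance; the conservation diagnostic flags this.
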