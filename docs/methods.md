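# Methods

## Scope and signal path

This package models the audio-side processing of an n-of-m cochlear-implant
(CI) coding strategy with a built-in single-channel noise reducer, and the
evaluation machinery needed to study it offline:

```
WAV → pre-amp → STFT framing → 24-band power summation          (front end)
    → noise-power tracking per channel                          (tracker)
    → SNR estimate → Wiener or binary-mask gain → S = G0 · P    (gain stage)
    → select n = 8 of m = 24 channels per frame                 (peak selection)
    → electrodogram / vocoder resynthesis                       (back end)
```

The electric domain (threshold/comfort-level mapping, pulse timing,
current units) is deliberately out of scope; the back end stops at a
normalized-amplitude electrodogram and an acoustic vocoder simulation.

## Front end

Audio is mono at 16 kHz. Frames are 16 ms long with an 8 ms shift (the
shift is the published value; the length and the Hann window are this
package's choices), zero-padded to a 256-point FFT. Band k's power
|Y(λ,k)|² is the sum of squared bin magnitudes over the bins assigned to
band k — all later recursions operate on power, so the "envelope" carried
forward is a power envelope.

Band edges are Greenwood-map spaced between 200 and 7800 Hz: edges are
equidistant on the cochlear position axis x where f = 165.4·(10^(2.1x) −
0.88), then snapped to FFT-bin boundaries with a monotone repair pass so
every band owns at least one bin even for a 128-point FFT. The commercial
allocation is unpublished; edges are config-overridable.

## Noise tracker

A minima-controlled recursive-averaging (MCRA-2 family) estimator, one
scalar state set per channel:

1. `P ← η·P_prev + (1−η)·|Y|²` — smoothed noisy power, η = 0.7.
2. Minimum tracking: `Pmin ← P` when `Pmin_prev ≥ P`, else
   `Pmin ← γ·Pmin_prev + (1−γ)/(1−β)·(P − β·P_prev)` with γ = 0.998,
   β = 0.96 — the creeping branch lets the minimum recover when the noise
   floor rises.
3. Speech presence: `I = 1` iff `Sr = P/Pmin ≥ T`. The threshold is
   dynamic, `T = clip(5 − 0.1·SNR_dB_prev, 2, 8)`: a confident prior SNR
   lowers the bar for declaring speech. With no SNR history the rule sits
   at its upper clip (8), which keeps the tracker conservative on
   noise-only input.
4. Noise update gated by the smoothed presence probability:
   `K ← α·K_prev + (1−α)·I`, `αs = α_d + (1−α_d)·K`,
   `D ← αs·D_prev + (1−αs)·|Y|²`, with α = 0.2 and α_d = 0.85. When
   speech is certain (K → 1) the estimate freezes; in pure noise it
   relaxes toward the observed power with a ~50 ms time constant.

The presence-probability recursion is stated with the previous frame's K
on the right-hand side; the same-frame form would collapse to K = I and
carry no memory, so the one-frame lag is the only self-consistent reading.

α = 0.2 deserves a note: K exists to freeze the noise update the moment
speech appears. A sluggish K (α near 1) arrives ~10 frames late, by which
time D has already chased the syllable onset upward, the estimated SNR
collapses, and the chain attenuates clean speech. The fast value is the
one the MCRA-2 literature uses for exactly this recursion, and it is what
makes the chain transparent in quiet.

Cold start: the first frame initializes P = Pmin = D = max(|Y|², ε) and
K = 0 — the leading frames are assumed noise, standard for
minimum-statistics trackers. ε = 1e−10 (on the power scale of full-scale
±1 samples) floors Pmin and D so the ratios Sr and P/D stay defined
through digital silence.

## Gain stage

The SNR recursion is `SNR ← δ·SNR_prev + (1−δ)·max(P/D − 1, 0)`. The
instantaneous term is clamped at zero (P < D happens constantly under
estimation noise) so the Wiener gain stays in [0, 1). δ = 0.6 by default:
this recursion smooths the SNR trajectory itself, so its time constant
must sit well below a syllable quarter-period or the gain cannot follow
speech on/off structure at an 8-ms frame rate — τ ≈ 16 ms at δ = 0.6,
versus ≈ 0.4 s at the 0.98 typical of classic decision-directed
estimators, which smooth a different quantity (the prior-frame *enhanced*
amplitude) and can therefore afford to be slow.

The Wiener-type gain `G = SNR/(SNR+1)` is floored: `G0 = g` where
`G < T_g(SNR)`, else `G0 = G`, with g = 0.1 (≈ −10 dB maximum per-channel
attenuation) and the monotone threshold `T_g = 0.2/(1 + SNR)` — aggressive
flooring at low SNR, vanishing interference at high SNR. With these
defaults the floor engages exactly when SNR < 0.2. The comparison
algorithm is a binary mask on the same SNR estimate: gain 1 when
SNR ≥ 1, else g. Mode `off` is the exact identity.

Gains are computed on, and applied to, the smoothed power P (the output
is S = G0·P, not G0·|Y|²), and peak selection operates on sqrt(S)
amplitudes, pre-compression, ties to the lower channel index, silent
frames selecting nothing.

## Synthetic signals

The generators define the test conditions; none of them is recorded
audio.

* **Speech-like target** — a glottal-style pulse train (f0 drawn in
  180–240 Hz per talker, mild vibrato) plus low-level aspiration noise,
  shaped by four parallel formant resonators (F1–F4 drawn per talker from
  female-typical ranges), gated by a quasi-periodic syllable envelope
  (3–5 Hz half-wave profile) with sentence-like pauses every 1.5–2.5 s.
  It reproduces the two properties the processing chain is sensitive to —
  formant-band energy concentration and syllable-rate envelope modulation
  with true silent gaps — and none of the linguistic structure of real
  sentences. Mixture durations of 3 s are used throughout the shipped
  experiments; they hold 10–12 syllable cycles, enough for every
  recursion to traverse many speech/gap alternations.
* **Speech-shaped noise (SSN)** — Gaussian noise filtered by a
  linear-phase FIR (512 taps, Kaiser β = 9) fitted to the reference's
  Welch spectrum, RMS-matched to the reference. It matches the reference's
  1/3-octave spectrum within 3 dB wherever speech carries energy; bands
  narrower than the voice's harmonic spacing (below ≈ 350 Hz here) fall
  between spectral lines and cannot be matched by any smooth-spectrum
  noise — a property shared by real SSN versus real speech.
* **Same-talker babble** — the sum of n independent speech-like streams
  drawn from the *target talker's* formant and pitch parameters,
  RMS-normalized. Sharing the talker makes it the pathological masker for
  a single-channel noise reducer: the masker occupies the same channels
  as the target and its envelope modulation defeats minimum tracking. The
  shipped experiments use n = 4, which keeps visible envelope modulation
  (real multi-talker babble saturates toward stationarity as n grows).
* **Mixing** — noise is looped/cropped to the target length and scaled so
  the full-duration RMS SNR is exact; the returned noise component is the
  literal difference mixture − target, so shadow filtering sees an exact
  decomposition. Full-duration (rather than active-speech) level is used
  because it is unambiguous and exactly invertible; measured benefits are
  therefore not numerically comparable to studies using active-speech
  levels.

## Evaluation

**Shadow filtering.** The gain matrix derived from a mixture run is
applied separately to the clean and noise components' band powers;
ΔSNR is the broadband output-minus-input SNR in dB. Any constant gain
cancels exactly (mode `off` scores 0 by construction), so a positive
value isolates the time-frequency selectivity of the gains. Under the
default configuration, ten 3-s mixtures at +5 dB input SNR yield a mean
ΔSNR of ≈ 2.5 dB in SSN and less in same-talker babble — the same
direction as the behavioral contrast the algorithm class shows in
listeners (benefit in stationary noise, little or none in same-talker
babble).

**Quiet transparency.** On clean speech the mean per-frame output/input
power ratio over speech-active frames (within 25 dB of the loudest
frame) stays ≥ 0.8 — the chain leaves speech in quiet essentially
untouched.

**Envelope distortion.** Mean squared distance between log-power
envelopes, ε-floored at 1e−10; used to confirm the processed mixture
lands closer to clean speech than the raw mixture does.

## SRT staircase simulation

The adaptive protocol is modeled exactly: 1-up/1-down on trial SNR, step
8 dB before the second reversal, 4 dB before the fourth, 2 dB after, the
first direction change counting as reversal 1, the step for a trial
reflecting any reversal its response causes; the SRT is the mean of the
last eight presented SNRs of a 20-trial track.

Listeners are replaced by a logistic sentence-level psychometric function
P(correct) = (1−lapse)·σ(slope·(SNR_eff − midpoint)), where the effective
SNR is the presented SNR plus the processing chain's shadow-filtered
broadband benefit for that masker. This is a minimal, explicitly labeled
simulation: it links DSP benefit to the behavioral protocol and supports
directional statements only, not predictions of human SRTs. Word-level
scoring, the 80 %-words criterion, and sentence re-presentation are not
modeled. A deterministic (infinite-slope) listener recovers its threshold
within one terminal step; 100 seeded tracks with slope 4/dB recover it
within 2 dB, with n = 20 trials per track.

## Numerical choices and degenerate inputs

* All recursions run in float64; the batch driver is literally a loop
  over the streaming path, so streaming and batch agree bit-for-bit, and
  a naive scalar per-frame/per-channel reimplementation of the full
  recursion stack is bit-identical to the vectorized code (this is
  asserted in the tests).
* Zero-SNR history maps to a very negative finite dB value (−1e12) in the
  dynamic-threshold rule rather than −∞, keeping the rule defined for a
  zero slope setting.
* All-zero frames: floored state keeps every ratio finite; peak selection
  emits an empty set (no stimulation in silence); the vocoder emits
  silence for an empty electrodogram.
* WAV I/O is 16-bit PCM (or float32), mono; out-of-range samples are
  clipped with a warning; multichannel files require an explicit channel
  selection.

## Known limitations

* Tracker constants, the dynamic-threshold rules, band edges, window and
  frame length are this package's own documented defaults — the shipped
  commercial tuning is proprietary and no claim of equivalence is made.
* Shadow ΔSNR is an energetic proxy; it does not model electric-hearing
  intelligibility, channel interaction, or compression.
* The speech-like generator has no consonant bursts, coarticulation or
  linguistic content; results transfer to real speech only directionally.
* The vocoder is an evaluation aid (noise or sine carriers, linear
  envelope interpolation), not a model of electric stimulation percepts.
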