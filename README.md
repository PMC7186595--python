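# evoice-ci

Single-channel noise reduction inside an n-of-m cochlear-implant (CI)
coding chain, with everything needed to study it offline: an STFT band
front end, an MCRA-style per-channel noise tracker, Wiener-type and
binary-mask gain stages, 8-of-24 peak selection with electrodogram and
vocoder output, synthetic speech-like/SSN/babble generators, shadow-filter
SNR evaluation, and an adaptive-staircase speech-reception-threshold (SRT)
simulator.

It is aimed at hearing-science and audio-DSP researchers who want a
transparent, fully seeded reference implementation of this algorithm
family — every recursion is a few lines of NumPy, every constant is in a
config dataclass, and every experiment runs from synthetic signals with
no corpus downloads.

## The algorithm

Per frame λ and channel k, with band power |Y(λ,k)|²:

```
P(λ,k)    = η P(λ−1,k) + (1−η) |Y(λ,k)|²                smoothed power
Pmin(λ,k) : running local minimum of P (minima-controlled tracking)
I(λ,k)    = 1  iff  P/Pmin ≥ T(SNR(λ−1,k))              speech presence
K(λ,k)    = α K(λ−1,k) + (1−α) I(λ,k)                   smoothed presence
αs(λ,k)   = α_d + (1−α_d) K(λ,k)
D(λ,k)    = αs D(λ−1,k) + (1−αs) |Y(λ,k)|²              noise estimate
SNR(λ,k)  = δ SNR(λ−1,k) + (1−δ) max(P/D − 1, 0)
G(λ,k)    = SNR/(SNR+1)                                  Wiener-type gain
G0(λ,k)   = G  if G ≥ T_g(SNR), else g                   floored gain
S(λ,k)    = G0(λ,k) P(λ,k)                               output power
```

The n = 8 channels (of m = 24) with the largest √S are then selected for
stimulation. The binary-mask comparison algorithm shares the same noise
estimate and sets G0 ∈ {g, 1} by thresholding SNR. See `docs/methods.md`
for parameter values, rationale, and limitations.

## Worked example

```python
import evoice as ev

speech = ev.generate_speechlike(3.0, seed=1)          # synthetic target
ssn = ev.generate_ssn(speech, 3.0, seed=2)            # speech-shaped noise
mix, clean, noise = ev.mix_at_snr(ev.MixtureSpec(speech, ssn, snr_db=5.0))

delta, result = ev.evaluate_mixture(mix, clean, noise)
print(f"shadow-filtered SNR benefit: {delta:+.2f} dB")
print(f"quiet transparency: {ev.quiet_transparency(speech):.3f}")
```

prints (seed 1):

```
shadow-filtered SNR benefit: +2.53 dB
quiet transparency: 0.956
```

The first number says the gains the chain derived from the +5 dB mixture,
applied separately to its clean and noise components, raised the
broadband SNR by 2.5 dB; the second says clean speech passes with ~96 %
of its frame power intact (1.0 would be perfectly transparent).

The same pipeline is available from the shell:

```
evoice synth speech sp.wav --seed 3            # render a synthetic signal
evoice process sp.wav out.wav --mode evoice    # full chain to vocoded WAV
evoice demo-fig2 --channel 8 --plot trace.png  # channel-8 power trace in SSN
evoice srt-sim --n-tracks 20                   # seeded staircase simulations
```

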