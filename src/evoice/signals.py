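"""Synthetic test signals: speech-like targets, SSN, babble, SNR mixing.

Nothing here is recorded speech.  The speech-like generator produces an
amplitude-modulated multi-formant signal — a glottal-style pulse train
plus aspiration noise, shaped by parallel formant resonators, gated by a
syllable-rate (2-6 Hz) envelope with silent gaps.  It stands in for
sentence corpora so that every experiment in the package runs without
downloads.  Speech-shaped noise (SSN) is Gaussian noise spectrally
matched to a reference's long-term average spectrum and carries no
syllabic modulation; babble sums several independent streams from the
same simulated talker (same formant parameters), emulating the
same-talker babble masker, which is the hardest case for any
single-channel noise reducer.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, firwin2, lfilter, sosfilt, welch

from .audio import AudioBuffer


@dataclass(frozen=True)
class TalkerParams:
    """Formant and pitch parameters of one simulated talker."""

    f0: float                 # glottal pulse rate, Hz
    formants: tuple[float, ...]
    bandwidths: tuple[float, ...]

    @classmethod
    def from_seed(cls, seed: int) -> "TalkerParams":
        rng = np.random.default_rng(seed)
        f0 = float(rng.uniform(180.0, 240.0))  # female-range pitch
        formants = (
            float(rng.uniform(400.0, 700.0)),
            float(rng.uniform(1200.0, 1900.0)),
            float(rng.uniform(2300.0, 2900.0)),
            float(rng.uniform(3300.0, 3900.0)),
        )
        bandwidths = (90.0, 120.0, 160.0, 220.0)
        return cls(f0=f0, formants=formants, bandwidths=bandwidths)


@dataclass(frozen=True)
class MixtureSpec:
    """A target/noise pair to be mixed at a prescribed SNR."""

    target: AudioBuffer
    noise: AudioBuffer
    snr_db: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target.rate != self.noise.rate:
            raise ValueError("target and noise must share a sample rate")


def _formant_filterbank(x: np.ndarray, rate: int,
                        talker: TalkerParams) -> np.ndarray:
    """Parallel formant shaping with 1/f spectral tilt across formants."""
    out = np.zeros_like(x)
    nyq = rate / 2
    for i, (fc, bw) in enumerate(zip(talker.formants, talker.bandwidths)):
        lo = max((fc - bw) / nyq, 1e-3)
        hi = min((fc + bw) / nyq, 0.999)
        sos = butter(2, [lo, hi], btype="bandpass", output="sos")
        out += sosfilt(sos, x) / (i + 1.0)
    return out


def _syllabic_envelope(n: int, rate: int, rng: np.random.Generator) -> np.ndarray:
    """Quasi-periodic syllable gating with sentence-level pauses."""
    t = np.arange(n) / rate
    f_syl = rng.uniform(3.0, 5.0)  # syllable rate, Hz
    phase = rng.uniform(0, 2 * np.pi)
    syllables = np.maximum(0.0, np.sin(2 * np.pi * f_syl * t + phase)) ** 0.7
    # ~0.3 s pause about every 1.5-2.5 s, like sentence boundaries
    env = syllables
    pos = rng.uniform(1.0, 2.0)
    while pos < t[-1]:
        env = env * (1.0 - np.exp(-0.5 * ((t - pos) / 0.12) ** 2))
        pos += rng.uniform(1.5, 2.5)
    return env


def generate_speechlike(duration: float, rate: int = 16000, seed: int = 0,
                        talker: TalkerParams | None = None) -> AudioBuffer:
    """Deterministic speech-like signal: voiced pulse train + aspiration,
    formant-shaped, syllabically gated.  Peak-normalized to 0.5."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    talker = talker or TalkerParams.from_seed(seed)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    # glottal-style excitation: narrow pulses with mild pitch drift
    f0 = talker.f0 * (1.0 + 0.03 * np.sin(2 * np.pi * 0.4 * t + rng.uniform(0, 6)))
    phase = 2 * np.pi * np.cumsum(f0) / rate
    pulses = np.maximum(0.0, np.cos(phase)) ** 8
    aspiration = 0.05 * rng.standard_normal(n)
    voiced = _formant_filterbank(pulses + aspiration, rate, talker)
    env = _syllabic_envelope(n, rate, rng)
    x = voiced * env
    peak = np.max(np.abs(x))
    if peak > 0:
        x = 0.5 * x / peak
    return AudioBuffer(x, rate)


def generate_ssn(reference: AudioBuffer, duration: float,
                 seed: int = 0, fir_length: int = 512) -> AudioBuffer:
    """Stationary Gaussian noise with the reference's long-term spectrum.

    A linear-phase FIR (frequency-sampling design on the reference's
    Welch spectrum) shapes white noise; output RMS matches the reference.
    """
    ref = reference.samples
    if np.max(np.abs(ref)) == 0:
        raise ValueError("reference signal is silent")
    rate = reference.rate
    freqs, psd = welch(ref, fs=rate, nperseg=min(fir_length, ref.size))
    amp = np.sqrt(np.maximum(psd, 0.0))
    amp /= np.max(amp)
    # firwin2 wants gains on [0, 1] normalized frequency incl. endpoints
    norm_f = freqs / (rate / 2)
    norm_f[0], norm_f[-1] = 0.0, 1.0
    # Kaiser window: the default Hamming stopband (~-53 dB) cannot follow
    # speech spectra whose floor sits 80 dB below the formant peaks
    fir = firwin2(fir_length + 1, norm_f, amp, window=("kaiser", 9.0))
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    white = rng.standard_normal(n + fir_length)
    shaped = lfilter(fir, 1.0, white)[fir_length:]  # drop filter transient
    ref_rms = np.sqrt(np.mean(ref**2))
    out_rms = np.sqrt(np.mean(shaped**2))
    return AudioBuffer(shaped * (ref_rms / out_rms), rate)


def generate_babble(n_talkers: int, duration: float, rate: int = 16000,
                    seed: int = 0,
                    talker: TalkerParams | None = None) -> AudioBuffer:
    """Sum of independent speech-like streams from one talker's formant
    set (same-talker babble); RMS-normalized to 0.1."""
    if n_talkers < 1:
        raise ValueError("n_talkers must be >= 1")
    talker = talker or TalkerParams.from_seed(seed)
    streams = np.zeros(int(round(duration * rate)))
    for i in range(n_talkers):
        s = generate_speechlike(duration, rate, seed=seed * 1009 + 7 * i + 1,
                                talker=talker)
        streams = streams + s.samples
    rms = np.sqrt(np.mean(streams**2))
    return AudioBuffer(0.1 * streams / rms, rate)


def _fit_noise_length(noise: np.ndarray, n: int) -> np.ndarray:
    """Deterministically loop/crop the noise to n samples."""
    if noise.size >= n:
        return noise[:n]
    reps = int(np.ceil(n / noise.size))
    return np.tile(noise, reps)[:n]


def mix_at_snr(spec: MixtureSpec) -> tuple[AudioBuffer, AudioBuffer, AudioBuffer]:
    """Scale the noise so the full-duration RMS SNR is exactly ``snr_db``.

    Returns (mixture, scaled_target, scaled_noise); mixture is their exact
    sum, so shadow-filter evaluation can use the components directly.  An
    infinite snr_db is the quiet condition (zero noise).  SNR is defined
    on full-duration RMS of the target, not active-speech level.
    """
    target = spec.target.samples
    noise = _fit_noise_length(spec.noise.samples, target.size)
    t_rms = np.sqrt(np.mean(target**2))
    n_rms = np.sqrt(np.mean(noise**2))
    if t_rms == 0 or n_rms == 0:
        raise ValueError("silent target or noise")
    if np.isinf(spec.snr_db):
        scale = 0.0
    else:
        scale = (t_rms / n_rms) * 10.0 ** (-spec.snr_db / 20.0)
    rate = spec.target.rate
    mixture = target + noise * scale
    # the returned noise is the literal difference, so the three buffers
    # satisfy mixture - target == noise to the last bit
    return (AudioBuffer(mixture, rate),
            AudioBuffer(target, rate),
            AudioBuffer(mixture - target, rate))
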