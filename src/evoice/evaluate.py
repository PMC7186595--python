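"""Objective evaluation: shadow-filtered SNR benefit and envelope distortion.

Shadow filtering applies the gain matrix derived from a *mixture* run
separately to the clean-speech and noise components of that mixture (both
analyzed with the same front end), and compares broadband output SNR with
input SNR.  Because a common gain factor cancels in the ratio, an
unprocessed chain scores exactly 0 dB; a positive score means the gains
favored speech-dominated time-frequency cells.
"""

from __future__ import annotations

import numpy as np

from .audio import AudioBuffer
from .chain import ChainResult, process_powers
from .frontend import AnalysisConfig, BandMap, analyze
from .gain import GainParams
from .noise import NoiseTrackerParams


def shadow_snr_improvement(gains: np.ndarray,
                           clean_powers: np.ndarray,
                           noise_powers: np.ndarray) -> float:
    """Broadband output-minus-input SNR (dB) under a shared gain matrix.

    Input and output SNRs are ratios of total (frames x channels summed)
    clean to noise power, the output with the gain applied to both.
    """
    gains = np.asarray(gains, dtype=np.float64)
    clean = np.asarray(clean_powers, dtype=np.float64)
    noise = np.asarray(noise_powers, dtype=np.float64)
    if not gains.shape == clean.shape == noise.shape:
        raise ValueError("gains/clean/noise shape mismatch")
    in_snr = clean.sum() / noise.sum()
    out_snr = (gains * clean).sum() / (gains * noise).sum()
    return float(10.0 * np.log10(out_snr) - 10.0 * np.log10(in_snr))


def envelope_distortion(processed: np.ndarray, clean: np.ndarray,
                        eps: float = 1e-10) -> float:
    """Mean squared log-power distance between two channel-power matrices."""
    processed = np.asarray(processed, dtype=np.float64)
    clean = np.asarray(clean, dtype=np.float64)
    if processed.shape != clean.shape:
        raise ValueError("shape mismatch")
    d = 10.0 * np.log10(processed + eps) - 10.0 * np.log10(clean + eps)
    return float(np.mean(d**2))


def speech_active_frames(powers: np.ndarray, threshold_db: float = 25.0) -> np.ndarray:
    """Boolean mask of frames whose broadband power is within
    ``threshold_db`` of the loudest frame."""
    frame_power = np.asarray(powers).sum(axis=1)
    peak = frame_power.max()
    if peak <= 0:
        return np.zeros(frame_power.size, dtype=bool)
    return frame_power >= peak * 10.0 ** (-threshold_db / 10.0)


def evaluate_mixture(mixture: AudioBuffer, clean: AudioBuffer,
                     noise: AudioBuffer,
                     config: AnalysisConfig | None = None,
                     band_map: BandMap | None = None,
                     noise_params: NoiseTrackerParams | None = None,
                     gain_params: GainParams | None = None,
                     ) -> tuple[float, ChainResult]:
    """End-to-end shadow evaluation of one mixture.

    Analyzes mixture/clean/noise with one front end, runs the enhancement
    chain on the mixture powers, and shadow-filters the components with
    the resulting gain matrix.  Returns (delta SNR in dB, chain result).
    """
    config = config or AnalysisConfig()
    mix_p = analyze(mixture, config, band_map)
    clean_p = analyze(clean, config, band_map)
    noise_p = analyze(noise, config, band_map)
    result = process_powers(mix_p, noise_params, gain_params)
    delta = shadow_snr_improvement(result.gain, clean_p.values, noise_p.values)
    return delta, result


def quiet_transparency(clean: AudioBuffer,
                       config: AnalysisConfig | None = None,
                       band_map: BandMap | None = None,
                       noise_params: NoiseTrackerParams | None = None,
                       gain_params: GainParams | None = None,
                       threshold_db: float = 25.0) -> float:
    """Mean per-frame output/input power ratio over speech-active frames.

    A value near 1 means the chain leaves clean speech untouched — the
    "no effect in quiet" property.
    """
    config = config or AnalysisConfig()
    powers = analyze(clean, config, band_map)
    result = process_powers(powers, noise_params, gain_params)
    active = speech_active_frames(powers.values, threshold_db)
    in_p = result.P[active].sum(axis=1)
    out_p = result.S[active].sum(axis=1)
    return float(np.mean(out_p / in_p))
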