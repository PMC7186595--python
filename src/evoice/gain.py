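"""SNR estimation and gain application.

Two gain laws share one SNR estimate:

* ``evoice`` — a Wiener-type smooth gain G = SNR/(SNR+1), floored at a
  small constant wherever it falls below a dynamic threshold T_g(SNR);
* ``binary`` — an SNR-thresholded binary mask taking only the values
  {g_floor, 1} (the comparison algorithm);
* ``off`` — the exact identity, for unprocessed baselines.

The SNR recursion is decision-directed style: a smoothed combination of
the previous frame's SNR and the instantaneous excess-power ratio
P/D - 1, with the instantaneous term clamped at zero so the Wiener gain
stays inside [0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

Mode = str  # {"evoice", "binary", "off"}
_MODES = ("evoice", "binary", "off")


@dataclass(frozen=True)
class GainParams:
    """Gain-stage constants.

    ``delta`` smooths the SNR recursion; ``g_floor`` is the maximum
    per-channel attenuation (0.1 is about -10 dB); ``tg_scale`` sets the
    dynamic flooring threshold T_g = tg_scale / (1 + SNR) — aggressive at
    low SNR, vanishing at high SNR; ``binary_snr_threshold`` is the
    linear-SNR decision point of the binary mask.
    """

    delta: float = 0.6
    g_floor: float = 0.1
    tg_scale: float = 0.2
    binary_snr_threshold: float = 1.0
    mode: Mode = "evoice"

    def __post_init__(self) -> None:
        if not 0.0 < self.delta < 1.0:
            raise ValueError("delta must be in (0, 1)")
        if not 0.0 < self.g_floor < 1.0:
            raise ValueError("g_floor must be in (0, 1)")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")

    def tg(self, snr: np.ndarray) -> np.ndarray:
        """Dynamic flooring threshold, monotone decreasing in SNR."""
        return self.tg_scale / (1.0 + snr)


@dataclass(frozen=True)
class GainResult:
    """Per-frame gain-stage outputs (arrays share one shape)."""

    snr: np.ndarray        # smoothed SNR estimate, >= 0
    gain_raw: np.ndarray   # Wiener gain before flooring, in [0, 1)
    gain: np.ndarray       # applied gain, in [g_floor, 1]
    out_power: np.ndarray  # gain * smoothed power


def estimate_snr(prev_snr: np.ndarray, P: np.ndarray, D: np.ndarray,
                 delta: float) -> np.ndarray:
    """Smoothed SNR: delta * prev + (1 - delta) * max(P/D - 1, 0)."""
    instantaneous = np.maximum(P / D - 1.0, 0.0)
    return delta * prev_snr + (1.0 - delta) * instantaneous


def wiener_gain(snr: np.ndarray) -> np.ndarray:
    """G = SNR / (SNR + 1); strictly increasing, range [0, 1)."""
    snr = np.asarray(snr, dtype=np.float64)
    return snr / (snr + 1.0)


def floor_gain(gain: np.ndarray, snr: np.ndarray,
               params: GainParams) -> np.ndarray:
    """Replace gains below the dynamic threshold T_g(SNR) by the floor."""
    return np.where(gain >= params.tg(snr), gain, params.g_floor)


def binary_mask_gain(snr: np.ndarray, params: GainParams) -> np.ndarray:
    """Binary mask: 1 where speech dominates (SNR >= threshold), floor
    elsewhere."""
    return np.where(snr >= params.binary_snr_threshold, 1.0, params.g_floor)


def apply_gain(gain: np.ndarray, power: np.ndarray) -> np.ndarray:
    """Elementwise S = G0 * P."""
    gain = np.asarray(gain, dtype=np.float64)
    power = np.asarray(power, dtype=np.float64)
    if gain.shape != power.shape:
        raise ValueError("gain/power shape mismatch")
    return gain * power


def gain_frame(prev_snr: np.ndarray, P: np.ndarray, D: np.ndarray,
               params: GainParams) -> GainResult:
    """One full gain-stage step on smoothed power P and noise estimate D."""
    snr = estimate_snr(prev_snr, P, D, params.delta)
    raw = wiener_gain(snr)
    if params.mode == "evoice":
        gain = floor_gain(raw, snr, params)
    elif params.mode == "binary":
        gain = binary_mask_gain(snr, params)
    else:  # off: exact identity
        gain = np.ones_like(P)
    return GainResult(snr=snr, gain_raw=raw, gain=gain,
                      out_power=apply_gain(gain, P))
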