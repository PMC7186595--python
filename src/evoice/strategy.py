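"""n-of-m back end: peak selection, electrodogram, vocoder resynthesis.

Each frame, the n channels (of m) with the largest amplitudes are kept
for stimulation; ties break toward the lower channel index and all-zero
channels are never selected, so a silent frame produces no stimulation.
The electric-domain mapping (T/C levels, pulse trains) is replaced by a
normalized-amplitude electrodogram.  A noise- or sine-carrier vocoder
reconstructs audio from the selected channel envelopes for objective
evaluation, standard practice in CI simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfilt

from .audio import AudioBuffer
from .frontend import BandMap, ChannelPowerMatrix


@dataclass(frozen=True)
class StrategyConfig:
    """n-of-m selection and back-end options."""

    m: int = 24
    n: int = 8
    compression: str = "none"       # {"none", "log"} placeholder
    vocoder_carrier: str = "noise"  # {"noise", "sine"}

    def __post_init__(self) -> None:
        if not 1 <= self.n <= self.m:
            raise ValueError("need 1 <= n <= m")
        if self.compression not in ("none", "log"):
            raise ValueError("compression must be 'none' or 'log'")
        if self.vocoder_carrier not in ("noise", "sine"):
            raise ValueError("vocoder_carrier must be 'noise' or 'sine'")


@dataclass
class Electrodogram:
    """Per-frame selected channels and their post-gain amplitudes."""

    selections: list[tuple[np.ndarray, np.ndarray]]  # (channel idx, amplitude)
    n_channels: int
    frame_shift: float = 0.008

    @property
    def n_frames(self) -> int:
        return len(self.selections)

    def to_dense(self) -> np.ndarray:
        """frames x channels amplitude matrix, zero where unselected."""
        out = np.zeros((self.n_frames, self.n_channels))
        for lam, (idx, amp) in enumerate(self.selections):
            out[lam, idx] = amp
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = [(lam, int(ch), float(a))
                for lam, (idx, amp) in enumerate(self.selections)
                for ch, a in zip(idx, amp)]
        return pd.DataFrame(rows, columns=["frame_index", "channel", "amplitude"])

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def select_peaks(amplitudes: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Indices and values of the n largest strictly positive channels.

    Ties break toward the lower channel index; fewer than n channels are
    returned when fewer are strictly positive (none for a silent frame).
    """
    amps = np.asarray(amplitudes, dtype=np.float64)
    if n > amps.size:
        raise ValueError(f"cannot select {n} of {amps.size} channels")
    order = np.argsort(-amps, kind="stable")  # stable => lowest index wins ties
    chosen = order[:n]
    chosen = chosen[amps[chosen] > 0.0]
    chosen = np.sort(chosen)
    return chosen, amps[chosen]


def _compress(amp: np.ndarray, kind: str) -> np.ndarray:
    if kind == "none":
        return amp
    # placeholder log map; monotone, zero-preserving
    return np.log1p(100.0 * amp) / np.log1p(100.0)


def build_electrodogram(powers: ChannelPowerMatrix,
                        config: StrategyConfig | None = None) -> Electrodogram:
    """Frame-wise peak selection on sqrt(power) amplitudes.

    Selection happens pre-compression; the optional log compression is
    applied to the selected amplitudes only.
    """
    config = config or StrategyConfig()
    if powers.n_channels != config.m:
        raise ValueError(
            f"matrix has {powers.n_channels} channels, config expects {config.m}")
    amplitudes = np.sqrt(powers.values)
    selections = []
    for lam in range(powers.n_frames):
        idx, amp = select_peaks(amplitudes[lam], config.n)
        selections.append((idx, _compress(amp, config.compression)))
    return Electrodogram(selections=selections, n_channels=config.m,
                         frame_shift=powers.frame_shift)


def _band_noise_carrier(rng: np.random.Generator, n_samples: int, rate: int,
                        f_lo: float, f_hi: float) -> np.ndarray:
    noise = rng.standard_normal(n_samples)
    nyq = rate / 2
    lo = max(f_lo / nyq, 1e-4)
    hi = min(f_hi / nyq, 0.9999)
    sos = butter(4, [lo, hi], btype="bandpass", output="sos")
    return sosfilt(sos, noise)


def synthesize_vocoder(source: Electrodogram | ChannelPowerMatrix,
                       band_map: BandMap,
                       carrier: str = "noise",
                       seed: int = 0) -> AudioBuffer:
    """Reconstruct audio from channel envelopes.

    Each channel's envelope (sqrt of power, linearly interpolated between
    frame centers) modulates a band-limited noise or band-center sine
    carrier; channels are summed and the result peak-normalized.
    """
    if isinstance(source, Electrodogram):
        env = source.to_dense()
        frame_shift = source.frame_shift
    else:
        env = np.sqrt(source.values)
        frame_shift = source.frame_shift
    n_frames, n_channels = env.shape
    if n_channels != band_map.m:
        raise ValueError("band map inconsistent with channel count")
    rate = band_map.rate
    hop = int(round(frame_shift * rate))
    n_samples = n_frames * hop
    t_frames = (np.arange(n_frames) + 0.5) * hop
    t_samples = np.arange(n_samples)
    rng = np.random.default_rng(seed)
    out = np.zeros(n_samples)
    centers = band_map.center_frequencies
    for k in range(n_channels):
        if not np.any(env[:, k] > 0):
            continue
        envelope = np.interp(t_samples, t_frames, env[:, k])
        if carrier == "sine":
            c = np.sin(2 * np.pi * centers[k] * t_samples / rate)
        elif carrier == "noise":
            c = _band_noise_carrier(rng, n_samples, rate,
                                    band_map.edges[k], band_map.edges[k + 1])
            rms = np.sqrt(np.mean(c**2))
            if rms > 0:
                c = c / rms
        else:
            raise ValueError("carrier must be 'noise' or 'sine'")
        out += envelope * c
    peak = np.max(np.abs(out))
    if peak > 0:
        out = out / peak
    return AudioBuffer(out, rate)
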