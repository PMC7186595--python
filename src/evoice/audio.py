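"""Mono audio containers and WAV I/O.

Audio is held as float64 samples nominally in [-1, 1] with an integer
sample rate. Files are plain PCM WAV (16-bit int or 32-bit float), mono;
multichannel files are rejected unless a channel is selected explicitly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

log = logging.getLogger(__name__)

_PCM16_SCALE = 32768.0


@dataclass(frozen=True)
class AudioBuffer:
    """A mono sampled waveform: ``samples`` (float64) at ``rate`` Hz."""

    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1:
            raise ValueError("AudioBuffer requires a 1-D sample array")
        if samples.size == 0:
            raise ValueError("AudioBuffer may not be empty")
        if not np.all(np.isfinite(samples)):
            raise ValueError("AudioBuffer samples must be finite")
        if int(self.rate) <= 0:
            raise ValueError("sample rate must be positive")
        object.__setattr__(self, "rate", int(self.rate))

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))


def resample(buf: AudioBuffer, rate: int) -> AudioBuffer:
    """Polyphase resampling to ``rate`` Hz (duration preserved ±1 sample)."""
    if rate == buf.rate:
        return buf
    frac = Fraction(rate, buf.rate).limit_denominator(1000)
    out = resample_poly(buf.samples, frac.numerator, frac.denominator)
    return AudioBuffer(out, rate)


def read_wav(
    path: str | Path,
    *,
    expected_rate: int | None = None,
    resample_to_expected: bool = False,
    channel: int | None = None,
) -> AudioBuffer:
    """Read a PCM/float WAV file into an :class:`AudioBuffer`.

    Parameters
    ----------
    expected_rate:
        If given and the file rate differs, either resample (when
        ``resample_to_expected``) or raise.
    channel:
        Required to accept a multichannel file; selects that channel.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rate, data = wavfile.read(path)
    if data.ndim == 2:
        if channel is None:
            raise ValueError(
                f"{path} has {data.shape[1]} channels; pass channel= to select one"
            )
        data = data[:, channel]
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / _PCM16_SCALE
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"unsupported WAV encoding {data.dtype} in {path}")
    buf = AudioBuffer(samples, rate)
    if expected_rate is not None and rate != expected_rate:
        if not resample_to_expected:
            raise ValueError(
                f"{path}: rate {rate} != expected {expected_rate} "
                "(pass resample_to_expected=True to convert)"
            )
        buf = resample(buf, expected_rate)
    return buf


def write_wav(path: str | Path, buf: AudioBuffer, *, subtype: str = "pcm16") -> None:
    """Write an :class:`AudioBuffer` to WAV; samples outside [-1, 1] are
    clipped with a warning."""
    samples = buf.samples
    if np.any(np.abs(samples) > 1.0):
        warnings.warn("samples outside [-1, 1] clipped on WAV write", stacklevel=2)
        log.warning("clipping %d samples on write to %s",
                    int(np.sum(np.abs(samples) > 1.0)), path)
        samples = np.clip(samples, -1.0, 1.0)
    if subtype == "pcm16":
        # symmetric quantization; +1.0 maps to the largest positive code
        data = np.clip(np.round(samples * _PCM16_SCALE), -32768, 32767).astype(np.int16)
    elif subtype == "float32":
        data = samples.astype(np.float32)
    else:
        raise ValueError(f"unsupported subtype {subtype!r}")
    wavfile.write(Path(path), buf.rate, data)
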