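"""STFT analysis front end: framing, windowing and 24-band power summation.

This is the "bandpass filtering + envelope calculation" stage of an
n-of-m cochlear-implant chain.  The incoming waveform is pre-amplified,
cut into overlapping frames (16 ms Hann window, 8 ms shift at 16 kHz by
default), transformed with an FFT, and the squared bin magnitudes are
summed within each of ``m`` contiguous analysis bands.  The result is a
frames x channels matrix of non-negative band powers |Y(lambda, k)|^2 —
the quantity every downstream recursion operates on.

Band edges follow Greenwood's cochlear frequency-position map, giving
quasi-logarithmic spacing between a low and a high corner frequency;
edges are snapped to FFT-bin boundaries so that every band owns at least
one bin.  The true electrode allocation of any commercial device is not
public; edges here are an explicit, overridable choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal.windows import hann

from .audio import AudioBuffer

# Greenwood map f(x) = A (10^(a x) - k), x in [0, 1] along the cochlea
_GW_A = 165.4
_GW_a = 2.1
_GW_k = 0.88


@dataclass(frozen=True)
class AnalysisConfig:
    """Framing parameters of the analysis front end.

    ``frame_shift`` and ``frame_length`` are in seconds; ``fft_size`` in
    samples and at least one frame long; ``preamp_gain`` is a plain linear
    factor (no AGC).
    """

    rate: int = 16000
    frame_shift: float = 0.008
    frame_length: float = 0.016
    fft_size: int = 256
    preamp_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.frame_length < self.frame_shift:
            raise ValueError("frame_length must be >= frame_shift")
        if self.fft_size < self.frame_length_samples:
            raise ValueError("fft_size must cover one frame")

    @property
    def frame_length_samples(self) -> int:
        return int(round(self.frame_length * self.rate))

    @property
    def frame_shift_samples(self) -> int:
        return int(round(self.frame_shift * self.rate))


@dataclass(frozen=True)
class BandMap:
    """Assignment of FFT bins to ``m`` contiguous analysis bands.

    ``edges`` are the m+1 strictly increasing band-edge frequencies (Hz,
    snapped to bin boundaries); ``bin_edges`` the corresponding rfft bin
    indices: band k owns bins ``bin_edges[k] .. bin_edges[k+1]-1``.
    """

    edges: np.ndarray
    bin_edges: np.ndarray
    fft_size: int
    rate: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", np.asarray(self.edges, dtype=np.float64))
        object.__setattr__(self, "bin_edges", np.asarray(self.bin_edges, dtype=np.int64))
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("band edges must be strictly increasing")
        if np.any(np.diff(self.bin_edges) < 1):
            raise ValueError("every band must own at least one FFT bin")

    @property
    def m(self) -> int:
        return len(self.bin_edges) - 1

    @property
    def center_frequencies(self) -> np.ndarray:
        """Geometric-mean center frequency of each band (Hz)."""
        return np.sqrt(self.edges[:-1] * self.edges[1:])

    def bin_assignment(self) -> np.ndarray:
        """Band index per rfft bin; -1 for unassigned bins."""
        n_bins = self.fft_size // 2 + 1
        out = np.full(n_bins, -1, dtype=np.int64)
        for k in range(self.m):
            out[self.bin_edges[k]:self.bin_edges[k + 1]] = k
        return out


@dataclass(frozen=True)
class ChannelPowerMatrix:
    """Frames x channels matrix of non-negative band powers."""

    values: np.ndarray
    frame_shift: float
    band_map: BandMap | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValueError("ChannelPowerMatrix requires a 2-D array")
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise ValueError("band powers must be finite and non-negative")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_shift


def _greenwood_position(f: np.ndarray | float) -> np.ndarray | float:
    return np.log10(np.asarray(f) / _GW_A + _GW_k) / _GW_a


def _greenwood_frequency(x: np.ndarray | float) -> np.ndarray | float:
    return _GW_A * (10.0 ** (_GW_a * np.asarray(x)) - _GW_k)


def make_band_map(
    rate: int = 16000,
    m: int = 24,
    f_low: float = 200.0,
    f_high: float = 7800.0,
    fft_size: int = 256,
) -> BandMap:
    """Build ``m`` contiguous quasi-logarithmic (Greenwood-spaced) bands.

    Ideal edges are placed equidistantly on the Greenwood cochlear
    position axis between ``f_low`` and ``f_high`` and then snapped to
    rfft-bin boundaries, enforcing at least one bin per band.  Raises if
    fewer usable bins exist than bands.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not (0 < f_low < f_high <= rate / 2):
        raise ValueError("need 0 < f_low < f_high <= rate/2")
    bin_width = rate / fft_size
    lo_bin = int(round(f_low / bin_width))
    hi_bin = int(round(f_high / bin_width))
    hi_bin = min(hi_bin, fft_size // 2)
    if hi_bin - lo_bin < m:
        raise ValueError(
            f"only {hi_bin - lo_bin} FFT bins between {f_low} and {f_high} Hz "
            f"for {m} bands; increase fft_size"
        )
    x = np.linspace(_greenwood_position(f_low), _greenwood_position(f_high), m + 1)
    ideal = np.asarray(_greenwood_frequency(x))
    bin_edges = np.round(ideal / bin_width).astype(np.int64)
    bin_edges[0], bin_edges[-1] = lo_bin, hi_bin
    # monotone repair: each interior edge at least one bin above its left
    # neighbour, then the same sweep from the right
    for i in range(1, m + 1):
        bin_edges[i] = max(bin_edges[i], bin_edges[i - 1] + 1)
    for i in range(m - 1, -1, -1):
        bin_edges[i] = min(bin_edges[i], bin_edges[i + 1] - 1)
    if bin_edges[0] < 0 or np.any(np.diff(bin_edges) < 1):
        raise ValueError("infeasible band spacing for this FFT size")
    return BandMap(edges=bin_edges * bin_width, bin_edges=bin_edges,
                   fft_size=fft_size, rate=rate)


def frame_count(n_samples: int, config: AnalysisConfig) -> int:
    win, hop = config.frame_length_samples, config.frame_shift_samples
    if n_samples < win:
        raise ValueError("input shorter than one analysis frame")
    return (n_samples - win) // hop + 1


def analyze(
    buf: AudioBuffer,
    config: AnalysisConfig | None = None,
    band_map: BandMap | None = None,
) -> ChannelPowerMatrix:
    """Short-time band-power analysis of a waveform.

    Entry (lambda, k) is the sum of squared windowed-FFT magnitudes over
    the bins of band k in frame lambda.  Frames start at multiples of the
    frame shift; no padding is applied, so the last partial frame is
    dropped.
    """
    config = config or AnalysisConfig()
    band_map = band_map or make_band_map(rate=config.rate, fft_size=config.fft_size)
    if buf.rate != config.rate:
        raise ValueError(f"buffer rate {buf.rate} != config rate {config.rate}")
    win = config.frame_length_samples
    hop = config.frame_shift_samples
    n = frame_count(buf.samples.size, config)
    x = buf.samples * config.preamp_gain
    frames = sliding_window_view(x, win)[::hop][:n]
    window = hann(win, sym=False)
    spec = np.fft.rfft(frames * window, n=config.fft_size, axis=1)
    power = spec.real**2 + spec.imag**2
    values = np.empty((n, band_map.m), dtype=np.float64)
    for k in range(band_map.m):
        lo, hi = band_map.bin_edges[k], band_map.bin_edges[k + 1]
        values[:, k] = power[:, lo:hi].sum(axis=1)
    return ChannelPowerMatrix(values=values, frame_shift=config.frame_shift,
                              band_map=band_map)
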