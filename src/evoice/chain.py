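"""The full enhancement chain: noise tracker + gain stage, streaming.

``EnhancerChain`` consumes one frame of band powers at a time and carries
all recursion state; :func:`process_powers` is the batch driver and is
nothing but a loop over the streaming path, so the two are bit-identical
by construction.  After each frame the gain stage's smoothed SNR is
written back into the tracker state, where it drives the next frame's
dynamic speech-presence threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import gain as _gain
from . import noise as _noise
from .frontend import ChannelPowerMatrix
from .gain import GainParams, GainResult
from .noise import NoiseTrackerParams, NoiseTrackerState


@dataclass
class ChainResult:
    """Whole-signal trajectories of the chain (frames x channels each)."""

    P: np.ndarray        # smoothed noisy power
    Pmin: np.ndarray     # tracked local minimum
    I: np.ndarray        # binary speech-presence decisions
    K: np.ndarray        # smoothed speech-presence probability
    D: np.ndarray        # noise-power estimate
    snr: np.ndarray      # smoothed SNR
    gain: np.ndarray     # applied gain G0
    S: np.ndarray        # output power G0 * P
    frame_shift: float = 0.008

    def output_matrix(self) -> ChannelPowerMatrix:
        return ChannelPowerMatrix(values=self.S, frame_shift=self.frame_shift)


class EnhancerChain:
    """Stateful frame-by-frame processor.

    The first frame initializes the tracker (noise estimate = observed
    power, zero SNR history) and passes power through at the gain
    dictated by zero SNR.
    """

    def __init__(self, noise_params: NoiseTrackerParams | None = None,
                 gain_params: GainParams | None = None) -> None:
        self.noise_params = noise_params or NoiseTrackerParams()
        self.gain_params = gain_params or GainParams()
        self.state: NoiseTrackerState | None = None

    def process_frame(self, raw_power: np.ndarray) -> tuple[_noise.FrameTrace, GainResult]:
        raw = np.asarray(raw_power, dtype=np.float64)
        if self.state is None:
            self.state = NoiseTrackerState.from_first_frame(raw)
            trace = _noise.FrameTrace(
                P=self.state.P.copy(), Pmin=self.state.Pmin.copy(),
                Sr=np.ones_like(raw), I=np.zeros_like(raw),
                K=self.state.K.copy(), D=self.state.D.copy())
        else:
            if raw.size != self.state.n_channels:
                raise ValueError("channel count mismatch with chain state")
            trace = _noise.process_frame(self.state, raw, self.noise_params)
        result = _gain.gain_frame(self.state.prev_snr, trace.P, trace.D,
                                  self.gain_params)
        # feedback: this frame's SNR drives the next frame's thresholds
        self.state.prev_snr = result.snr
        return trace, result

    def reset(self) -> None:
        self.state = None


def process_powers(powers: ChannelPowerMatrix | np.ndarray,
                   noise_params: NoiseTrackerParams | None = None,
                   gain_params: GainParams | None = None,
                   frame_shift: float = 0.008) -> ChainResult:
    """Run the chain over a whole frames x channels power matrix."""
    if isinstance(powers, ChannelPowerMatrix):
        values = powers.values
        frame_shift = powers.frame_shift
    else:
        values = np.asarray(powers, dtype=np.float64)
    n_frames, n_channels = values.shape
    chain = EnhancerChain(noise_params, gain_params)
    out = {name: np.empty((n_frames, n_channels))
           for name in ("P", "Pmin", "I", "K", "D", "snr", "gain", "S")}
    for lam in range(n_frames):
        trace, result = chain.process_frame(values[lam])
        out["P"][lam] = trace.P
        out["Pmin"][lam] = trace.Pmin
        out["I"][lam] = trace.I
        out["K"][lam] = trace.K
        out["D"][lam] = trace.D
        out["snr"][lam] = result.snr
        out["gain"][lam] = result.gain
        out["S"][lam] = result.out_power
    return ChainResult(frame_shift=frame_shift, **out)
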