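"""Frame-by-frame noise-power estimation per channel.

A minima-controlled recursive-averaging (MCRA-2 family) tracker.  For each
channel the noisy band power is smoothed recursively, a local minimum of
that smoothed power is tracked, and the ratio of power to minimum is
compared against a dynamic threshold to obtain a binary speech-presence
decision.  The decision is smoothed into a soft speech-presence
probability that gates the noise-power update: when speech is certainly
present the noise estimate freezes; in pure noise it relaxes toward the
observed power with time constant set by ``alpha_d``.

Update order per frame (one recursion step):

    P      <- eta * P_prev + (1 - eta) * |Y|^2
    Pmin   <- P                                        if Pmin_prev >= P
              gamma * Pmin_prev
                + (1-gamma)/(1-beta) * (P - beta * P_prev)   otherwise
    Sr     <- P / Pmin ;  I <- [Sr >= T(prev SNR)]
    K      <- alpha * K_prev + (1 - alpha) * I
    alpha_s <- alpha_d + (1 - alpha_d) * K
    D      <- alpha_s * D_prev + (1 - alpha_s) * |Y|^2

The smoothed-probability recursion is written here with the previous
frame's K on the right-hand side; a same-frame K would make the recursion
degenerate (it would collapse to K = I), so the one-frame lag is the only
self-consistent reading and is used throughout.

The speech-presence threshold T is not a constant: it is derived from the
previous frame's estimated SNR through a monotone rule (higher prior SNR
means a lower threshold, i.e. easier speech detection).  The tracker does
not update ``prev_snr`` itself — the processing chain writes the gain
stage's smoothed SNR back into the state after each frame, so a tracker
driven standalone runs at the base threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

PMIN_FLOOR = 1e-10  # on the normalized power scale; keeps Sr defined


@dataclass(frozen=True)
class NoiseTrackerParams:
    """Constants of the tracker recursions.

    All smoothing factors must lie strictly inside (0, 1).  The dynamic
    speech-presence threshold is T = clip(t_base - t_slope * SNR_dB, t_min,
    t_max) where SNR_dB is the previous frame's smoothed SNR in dB.
    """

    eta: float = 0.7
    gamma: float = 0.998
    beta: float = 0.96
    alpha: float = 0.2
    alpha_d: float = 0.85
    t_base: float = 5.0
    t_slope: float = 0.1
    t_min: float = 2.0
    t_max: float = 8.0

    def __post_init__(self) -> None:
        for name in ("eta", "gamma", "beta", "alpha", "alpha_d"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.t_min < 1.0 or self.t_max < self.t_min:
            raise ValueError("need 1 <= t_min <= t_max")

    def threshold(self, prev_snr: np.ndarray) -> np.ndarray:
        """Dynamic speech-presence threshold from previous-frame linear SNR."""
        # zero SNR maps to a very negative finite dB value so that the rule
        # stays defined (and clips to t_max) even when t_slope is 0
        snr_db = np.where(prev_snr > 0.0,
                          10.0 * np.log10(np.maximum(prev_snr, 1e-300)),
                          -1e12)
        return np.clip(self.t_base - self.t_slope * snr_db, self.t_min, self.t_max)


@dataclass
class NoiseTrackerState:
    """All recursion memory, one value per channel."""

    P: np.ndarray          # smoothed noisy power
    P_prev: np.ndarray     # previous frame's smoothed power
    Pmin: np.ndarray       # tracked local minimum
    K: np.ndarray          # smoothed speech-presence probability
    D: np.ndarray          # noise-power estimate
    prev_snr: np.ndarray   # previous-frame SNR (set by the chain)

    @classmethod
    def from_first_frame(cls, raw_power: np.ndarray) -> "NoiseTrackerState":
        """Cold start assuming the first frame is noise."""
        raw = np.maximum(np.asarray(raw_power, dtype=np.float64), PMIN_FLOOR)
        return cls(
            P=raw.copy(),
            P_prev=raw.copy(),
            Pmin=raw.copy(),
            K=np.zeros_like(raw),
            D=raw.copy(),
            prev_snr=np.zeros_like(raw),
        )

    def copy(self) -> "NoiseTrackerState":
        return NoiseTrackerState(**{k: v.copy() for k, v in self.__dict__.items()})

    @property
    def n_channels(self) -> int:
        return self.P.size


def update_smoothed_power(state: NoiseTrackerState, raw_power: np.ndarray,
                          params: NoiseTrackerParams) -> np.ndarray:
    """First-order recursive smoothing of the noisy band power."""
    raw = np.asarray(raw_power, dtype=np.float64)
    if np.any(raw < 0):
        raise ValueError("band power must be non-negative")
    if raw.size != state.n_channels:
        raise ValueError("channel count mismatch")
    state.P_prev = state.P
    state.P = params.eta * state.P_prev + (1.0 - params.eta) * raw
    return state.P


def update_local_minimum(state: NoiseTrackerState,
                         params: NoiseTrackerParams) -> np.ndarray:
    """Track the local minimum of the smoothed power.

    When the running minimum already exceeds the current power it snaps to
    it; otherwise it creeps upward through a first-difference correction,
    which lets the minimum recover after the noise floor rises.
    """
    take = state.Pmin >= state.P
    crept = (params.gamma * state.Pmin
             + (1.0 - params.gamma) / (1.0 - params.beta)
             * (state.P - params.beta * state.P_prev))
    state.Pmin = np.maximum(np.where(take, state.P, crept), PMIN_FLOOR)
    return state.Pmin


def speech_presence(state: NoiseTrackerState,
                    params: NoiseTrackerParams) -> tuple[np.ndarray, np.ndarray]:
    """Binary speech-presence decision I and the power ratio Sr = P/Pmin."""
    sr = state.P / state.Pmin
    threshold = params.threshold(state.prev_snr)
    indicator = (sr >= threshold).astype(np.float64)
    return indicator, sr


def update_noise_power(state: NoiseTrackerState, raw_power: np.ndarray,
                       indicator: np.ndarray,
                       params: NoiseTrackerParams) -> np.ndarray:
    """Probability-gated recursive noise-power update."""
    raw = np.asarray(raw_power, dtype=np.float64)
    state.K = params.alpha * state.K + (1.0 - params.alpha) * indicator
    alpha_s = params.alpha_d + (1.0 - params.alpha_d) * state.K
    # epsilon floor keeps the SNR ratio P/D defined through long silences
    state.D = np.maximum(alpha_s * state.D + (1.0 - alpha_s) * raw, PMIN_FLOOR)
    return state.D


@dataclass(frozen=True)
class FrameTrace:
    """Per-frame diagnostic values of one tracker step."""

    P: np.ndarray
    Pmin: np.ndarray
    Sr: np.ndarray
    I: np.ndarray
    K: np.ndarray
    D: np.ndarray


def process_frame(state: NoiseTrackerState, raw_power: np.ndarray,
                  params: NoiseTrackerParams) -> FrameTrace:
    """One full tracker step; ``state`` is mutated in place and is the sole
    carrier of recursion memory."""
    update_smoothed_power(state, raw_power, params)
    update_local_minimum(state, params)
    indicator, sr = speech_presence(state, params)
    update_noise_power(state, raw_power, indicator, params)
    return FrameTrace(P=state.P.copy(), Pmin=state.Pmin.copy(), Sr=sr,
                      I=indicator, K=state.K.copy(), D=state.D.copy())


def track_noise(powers: np.ndarray,
                params: NoiseTrackerParams | None = None) -> np.ndarray:
    """Run the tracker over a frames x channels power matrix standalone.

    Returns the frames x channels noise-estimate trajectory D.  Frame 0
    initializes the state (D = raw power).
    """
    params = params or NoiseTrackerParams()
    powers = np.asarray(powers, dtype=np.float64)
    out = np.empty_like(powers)
    state = NoiseTrackerState.from_first_frame(powers[0])
    out[0] = state.D
    for lam in range(1, powers.shape[0]):
        out[lam] = process_frame(state, powers[lam], params).D
    return out
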