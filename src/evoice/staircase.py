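"""Adaptive 1-up/1-down staircase for speech reception thresholds (SRT).

Protocol: the trial SNR decreases after a correct response ("no less than
eight of the words repeated") and increases after an incorrect one.  The
step is 8 dB before the second reversal, 4 dB before the fourth and 2 dB
for the remaining reversals; the SRT is the arithmetic mean of the SNRs
of the last eight sentences.  A reversal is counted whenever the movement
direction changes, the first direction change counting as reversal 1.

Human listeners are replaced by a logistic psychometric model whose
correctness probability depends on the trial's *effective* SNR — the
presented SNR plus whatever broadband SNR benefit the processing chain
achieves on that noise type (its shadow-filtered gain).  This is a
minimal simulation linking the DSP to the behavioral protocol, not a
claim about human performance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

STEP_SCHEDULE_DB = (8.0, 4.0, 2.0)  # before 2nd reversal / before 4th / after


@dataclass
class StaircaseState:
    """Mutable state of one adaptive track."""

    snr_db: float
    step_db: float = STEP_SCHEDULE_DB[0]
    reversals: int = 0
    direction: str = "undefined"  # {"up", "down", "undefined"}
    history: list[tuple[float, bool]] = field(default_factory=list)
    finished: bool = False


def _current_step(reversals: int) -> float:
    if reversals < 2:
        return STEP_SCHEDULE_DB[0]
    if reversals < 4:
        return STEP_SCHEDULE_DB[1]
    return STEP_SCHEDULE_DB[2]


def staircase_update(state: StaircaseState, correct: bool) -> StaircaseState:
    """Log one response and move the track.

    The presented SNR is recorded in the history; the step used for the
    move reflects any reversal this response causes.
    """
    if state.finished:
        raise RuntimeError("staircase already finished")
    state.history.append((state.snr_db, bool(correct)))
    new_direction = "down" if correct else "up"
    if state.direction != "undefined" and new_direction != state.direction:
        state.reversals += 1
    state.direction = new_direction
    state.step_db = _current_step(state.reversals)
    state.snr_db += -state.step_db if correct else state.step_db
    return state


def srt_from_history(state: StaircaseState, n_last: int = 8) -> float:
    """Arithmetic mean of the SNRs of the last ``n_last`` sentences."""
    if len(state.history) < n_last:
        raise ValueError(f"track has fewer than {n_last} trials")
    return float(np.mean([snr for snr, _ in state.history[-n_last:]]))


@dataclass(frozen=True)
class ListenerModel:
    """Logistic sentence-level psychometric function.

    P(correct at SNR s) = (1 - lapse) / (1 + exp(-slope * (s - midpoint))).
    An infinite slope gives a deterministic hard-threshold listener.
    """

    midpoint_db: float
    slope: float = 1.0       # per dB
    lapse: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if not 0.0 <= self.lapse <= 0.1:
            raise ValueError("lapse must be in [0, 0.1]")

    def p_correct(self, snr_db: float) -> float:
        if math.isinf(self.slope):
            p = 1.0 if snr_db >= self.midpoint_db else 0.0
        else:
            p = 1.0 / (1.0 + math.exp(-self.slope * (snr_db - self.midpoint_db)))
        return (1.0 - self.lapse) * p


def run_srt_track(listener: ListenerModel, n_sentences: int = 20,
                  start_snr_db: float = 20.0,
                  processing_benefit_db: float = 0.0,
                  rng: np.random.Generator | None = None) -> float:
    """Simulate one adaptive track and return its SRT.

    ``processing_benefit_db`` shifts the listener's effective SNR — pass
    the shadow-filtered broadband benefit of the processing chain under
    test to couple DSP performance to the behavioral outcome.
    """
    if n_sentences < 8:
        raise ValueError("need at least eight sentences for an SRT")
    rng = rng if rng is not None else np.random.default_rng(listener.seed)
    state = StaircaseState(snr_db=start_snr_db)
    for _ in range(n_sentences):
        p = listener.p_correct(state.snr_db + processing_benefit_db)
        correct = bool(rng.random() < p)
        staircase_update(state, correct)
    state.finished = True
    return srt_from_history(state)
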