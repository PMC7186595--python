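import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import evoice as ev
from evoice.noise import (NoiseTrackerParams, NoiseTrackerState, process_frame,
                          speech_presence, track_noise, update_local_minimum,
                          update_noise_power, update_smoothed_power)


def state_with(P=1.0, P_prev=1.0, Pmin=1.0, K=0.0, D=1.0, prev_snr=0.0, n=1):
    mk = lambda v: np.full(n, v, dtype=np.float64)
    return NoiseTrackerState(P=mk(P), P_prev=mk(P_prev), Pmin=mk(Pmin),
                             K=mk(K), D=mk(D), prev_snr=mk(prev_snr))


class TestSmoothedPower:
    def test_fixed_point(self):
        state = state_with(P=3.0)
        out = update_smoothed_power(state, np.array([3.0]), NoiseTrackerParams())
        assert out[0] == pytest.approx(3.0)

    def test_one_step_hand_value(self):
        # eta=0.7, P_prev=1, input=2 -> 0.7*1 + 0.3*2 = 1.3
        state = state_with(P=1.0)
        out = update_smoothed_power(state, np.array([2.0]),
                                    NoiseTrackerParams(eta=0.7))
        assert out[0] == pytest.approx(1.3)

    def test_zero_input_decays_geometrically(self):
        params = NoiseTrackerParams(eta=0.7)
        state = state_with(P=1.0)
        values = [update_smoothed_power(state, np.array([0.0]), params)[0]
                  for _ in range(5)]
        np.testing.assert_allclose(values, [0.7**i for i in range(1, 6)])

    def test_negative_power_rejected(self):
        with pytest.raises(ValueError):
            update_smoothed_power(state_with(), np.array([-1.0]),
                                  NoiseTrackerParams())


class TestLocalMinimum:
    def test_first_branch_takes_current_power(self):
        state = state_with(P=1.0, Pmin=2.0)
        out = update_local_minimum(state, NoiseTrackerParams())
        assert out[0] == pytest.approx(1.0)

    def test_second_branch_hand_value(self):
        # gamma=0.998, beta=0.96, Pmin_prev=1, P=1.5, P_prev=1.4:
        # 0.998*1 + (0.002/0.04)*(1.5 - 0.96*1.4) = 1.0058
        state = state_with(P=1.5, P_prev=1.4, Pmin=1.0)
        out = update_local_minimum(state,
                                   NoiseTrackerParams(gamma=0.998, beta=0.96))
        assert out[0] == pytest.approx(1.0058, rel=1e-12)

    def test_constant_input_stationary(self):
        params = NoiseTrackerParams()
        state = NoiseTrackerState.from_first_frame(np.array([2.5]))
        for _ in range(20):
            process_frame(state, np.array([2.5]), params)
            assert state.Pmin[0] == pytest.approx(2.5)


class TestSpeechPresence:
    def test_ratio_far_above_threshold(self):
        # fixed threshold T=2: Sr = 4/1 = 4 >= 2 -> speech
        params = NoiseTrackerParams(t_base=2.0, t_slope=0.0, t_min=2.0, t_max=2.0)
        state = state_with(P=4.0, Pmin=1.0)
        indicator, sr = speech_presence(state, params)
        assert sr[0] == pytest.approx(4.0)
        assert indicator[0] == 1.0

    def test_cold_prior_uses_maximum_threshold(self):
        # zero prior SNR (-inf dB) clips the dynamic threshold at t_max
        state = state_with(P=4.0, Pmin=1.0, prev_snr=0.0)
        indicator, _ = speech_presence(state, NoiseTrackerParams())
        assert indicator[0] == 0.0  # Sr=4 < t_max=8

    def test_boundary_equality_counts_as_speech(self):
        params = NoiseTrackerParams(t_min=2.0, t_max=2.0, t_base=2.0, t_slope=0.0)
        state = state_with(P=2.0, Pmin=1.0)
        indicator, sr = speech_presence(state, params)
        assert sr[0] == pytest.approx(2.0)
        assert indicator[0] == 1.0  # the inequality is >=

    def test_minimum_tracking_frame_is_noise(self):
        state = state_with(P=1.0, Pmin=1.0)
        indicator, sr = speech_presence(state, NoiseTrackerParams())
        assert sr[0] == 1.0
        assert indicator[0] == 0.0

    def test_threshold_monotone_in_prior_snr(self):
        params = NoiseTrackerParams()
        snrs = np.array([0.0, 0.5, 1.0, 10.0, 100.0])
        t = params.threshold(snrs)
        assert np.all(np.diff(t) <= 0)
        assert t.max() <= params.t_max and t.min() >= params.t_min


class TestNoisePowerUpdate:
    def test_certain_speech_freezes_noise(self):
        params = NoiseTrackerParams(alpha=0.9, alpha_d=0.85)
        state = state_with(K=1.0, D=0.7)
        out = update_noise_power(state, np.array([100.0]), np.array([1.0]), params)
        assert state.K[0] == pytest.approx(1.0)
        assert out[0] == pytest.approx(0.7)

    def test_pure_noise_limit(self):
        params = NoiseTrackerParams(alpha=0.9, alpha_d=0.85)
        state = state_with(K=0.0, D=1.0)
        out = update_noise_power(state, np.array([2.0]), np.array([0.0]), params)
        # K stays 0 -> alpha_s = alpha_d -> D = 0.85*1 + 0.15*2
        assert out[0] == pytest.approx(0.85 + 0.15 * 2.0)

    def test_one_step_hand_values(self):
        # alpha=0.9, K_prev=0, I=1 -> K=0.1; alpha_d=0.85 -> alpha_s=0.865
        params = NoiseTrackerParams(alpha=0.9, alpha_d=0.85)
        state = state_with(K=0.0, D=1.0)
        update_noise_power(state, np.array([1.0]), np.array([1.0]), params)
        assert state.K[0] == pytest.approx(0.1)
        # implied alpha_s appears in D: D = 0.865*1 + 0.135*1 = 1
        assert state.D[0] == pytest.approx(1.0)

    @given(st.lists(st.floats(0.01, 100.0), min_size=2, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_noise_estimate_bounded_by_history(self, powers):
        """D is a convex combination of observed powers per channel."""
        params = NoiseTrackerParams()
        mat = np.array(powers)[:, None]
        d = track_noise(mat, params)
        assert np.all(d <= mat.max() + 1e-12)
        assert np.all(d >= min(mat.min(), 1e-10) - 1e-15)

    def test_larger_k_never_moves_d_further(self):
        """alpha_s grows with K, so higher speech probability keeps D
        closer to its previous value."""
        params = NoiseTrackerParams(alpha=0.5)
        raw = np.array([10.0])
        moves = []
        for k0 in (0.0, 0.3, 0.6, 0.9):
            state = state_with(K=k0, D=1.0)
            update_noise_power(state, raw, np.array([0.0]), params)
            moves.append(abs(state.D[0] - 1.0))
        assert np.all(np.diff(moves) <= 0)


class TestFrameDriver:
    def test_channel_count_mismatch(self):
        state = NoiseTrackerState.from_first_frame(np.ones(4))
        with pytest.raises(ValueError):
            process_frame(state, np.ones(5), NoiseTrackerParams())

    def test_stationary_input_is_deterministic(self):
        params = NoiseTrackerParams()
        s1 = NoiseTrackerState.from_first_frame(np.ones(3))
        s2 = NoiseTrackerState.from_first_frame(np.ones(3))
        for _ in range(5):
            t1 = process_frame(s1, np.ones(3), params)
            t2 = process_frame(s2, np.ones(3), params)
            assert np.array_equal(t1.D, t2.D)

    def test_streaming_equals_batch_driver(self, ssn):
        powers = ev.analyze(ssn).values
        batch = track_noise(powers)
        state = NoiseTrackerState.from_first_frame(powers[0])
        stream = [state.D.copy()]
        for lam in range(1, powers.shape[0]):
            stream.append(process_frame(state, powers[lam],
                                        NoiseTrackerParams()).D)
        assert np.array_equal(batch, np.array(stream))

    def test_mostly_noise_declared_on_stationary_input(self, speech):
        """On noise-only stationary input the tracker flags speech rarely."""
        noise = ev.generate_ssn(speech, 6.0, seed=5)
        powers = ev.analyze(noise).values
        params = NoiseTrackerParams()
        state = NoiseTrackerState.from_first_frame(powers[0])
        indicators = []
        for lam in range(1, powers.shape[0]):
            indicators.append(process_frame(state, powers[lam], params).I)
        burn = int(2.0 / 0.008)
        assert np.mean(np.array(indicators)[burn:]) <= 0.2

    def test_converges_to_stationary_noise_power(self, speech):
        noise = ev.generate_ssn(speech, 6.0, seed=6)
        p = ev.analyze(noise)
        d = track_noise(p.values)
        burn = int(2.0 / 0.008)
        true = p.values[burn:].mean(axis=0)
        est = d[burn:].mean(axis=0)
        assert np.all(np.abs(est / true - 1.0) < 0.3)
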