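import numpy as np
import pytest

import evoice as ev


@pytest.fixture(scope="session")
def analysis_config():
    return ev.AnalysisConfig()


@pytest.fixture(scope="session")
def band_map(analysis_config):
    return ev.make_band_map(rate=analysis_config.rate,
                            fft_size=analysis_config.fft_size)


@pytest.fixture(scope="session")
def speech():
    return ev.generate_speechlike(3.0, seed=11)


@pytest.fixture(scope="session")
def ssn(speech):
    return ev.generate_ssn(speech, 3.0, seed=12)


@pytest.fixture(scope="session")
def mixture_5db(speech, ssn):
    """(mixture, clean, noise) at +5 dB SNR."""
    return ev.mix_at_snr(ev.MixtureSpec(speech, ssn, 5.0))


def modulation_index(buf, band=(2.0, 8.0)):
    """Depth of syllable-rate envelope modulation: RMS of the 2-8 Hz
    band of the Hilbert envelope over its mean (test-side oracle)."""
    from scipy.signal import butter, hilbert, sosfiltfilt

    env = np.abs(hilbert(buf.samples))
    sos = butter(2, [band[0] / (buf.rate / 2), band[1] / (buf.rate / 2)],
                 btype="bandpass", output="sos")
    mod = sosfiltfilt(sos, env)
    return float(np.sqrt(np.mean(mod**2)) / np.mean(env))


def envelope_modulation_peak_hz(buf):
    """Frequency of the strongest component of the broadband envelope's
    modulation spectrum, DC excluded (test-side oracle)."""
    from scipy.signal import hilbert

    env = np.abs(hilbert(buf.samples))
    env = env - env.mean()
    spec = np.abs(np.fft.rfft(env))
    freqs = np.fft.rfftfreq(env.size, 1.0 / buf.rate)
    keep = (freqs > 0.5) & (freqs < 32.0)
    return float(freqs[keep][np.argmax(spec[keep])])
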