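import numpy as np
import pytest

from topospeech.core import GridSpec
from topospeech.design import WordPool, generate_plan
from topospeech.encoder import Waveform, WordToken


@pytest.fixture(scope="session")
def test_pool() -> WordPool:
    return WordPool("test", tuple(WordToken(token_id=f"w{i:02d}") for i in range(30)))


@pytest.fixture(scope="session")
def training_pool() -> WordPool:
    tokens = tuple(
        WordToken(token_id=f"t{i:02d}", bias_flag="high" if i < 8 else ("low" if i < 16 else "none"))
        for i in range(20)
    )
    return WordPool("training", tokens)


@pytest.fixture(scope="session")
def test_plan(test_pool):
    return generate_plan("test", test_pool, GridSpec(), seed=1)


def fft_f0_oracle(w: Waveform, fmin: float = 80.0, fmax: float = 600.0) -> float:
    """Independent f0 oracle: interpolated magnitude-spectrum peak.

    Deliberately a different method from the package's autocorrelation
    estimator.  Valid for signals whose fundamental is the strongest
    spectral line in [fmin, fmax] (true for the synthetic stimuli).
    """
    x = w.samples - np.mean(w.samples)
    nfft = int(2 ** np.ceil(np.log2(x.size * 8)))
    mag = np.abs(np.fft.rfft(x * np.hanning(x.size), nfft))
    freqs = np.fft.rfftfreq(nfft, 1.0 / w.sample_rate)
    band = (freqs >= fmin) & (freqs <= fmax)
    idx = np.flatnonzero(band)
    k = idx[np.argmax(mag[idx])]
    y0, y1, y2 = mag[k - 1], mag[k], mag[k + 1]
    denom = y0 - 2 * y1 + y2
    delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
    return float((k + delta) * w.sample_rate / nfft)
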