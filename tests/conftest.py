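import numpy as np
import pytest

from spstates import StateDef, sliding_spectra
from spstates.spectral import N_BINS


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


@pytest.fixture
def three_state_defs():
    """Well-separated single-tone states over a weak 1/f + white floor."""
    return {
        "A": StateDef("A", (3.0,), (20.0,), 1.0, 1.0),
        "B": StateDef("B", (10.0,), (20.0,), 1.0, 1.0),
        "C": StateDef("C", (21.0,), (20.0,), 1.0, 1.0),
    }


def single_peak_spectrum(bin_idx: int, peak: float = 10.0, floor: float = 0.1):
    """A 59-bin spectrum with one triangular peak on a flat floor."""
    p = np.full(N_BINS, floor)
    p[bin_idx] = peak
    if bin_idx > 0:
        p[bin_idx - 1] = peak / 2
    if bin_idx < N_BINS - 1:
        p[bin_idx + 1] = peak / 2
    return p


def tone_spectra(freq: float, duration: float = 2.0, amp: float = 10.0,
                 fs: float = 128.0, seed: int = 0, noise: float = 0.0):
    """Sliding spectra of a pure tone (optionally noisy)."""
    sig = StateDef("t", (freq,), (amp,), noise, 0.0)
    from spstates import gen_oscillation

    return sliding_spectra(gen_oscillation(sig, duration, fs, seed), fs)
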