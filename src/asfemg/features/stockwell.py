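"""Stockwell (S-) transform feature.

Frequency-domain implementation of the discrete S-transform: for each
positive frequency index k the voice is the inverse FFT of the shifted
spectrum multiplied by a Gaussian window exp(-2 pi^2 m^2 / k^2). The
zero-frequency row is the window mean, following the standard convention.
"""

from __future__ import annotations

import numpy as np


def stockwell_transform(x: np.ndarray) -> np.ndarray:
    """Full S-transform matrix, shape (N//2 + 1, N), rows = 0..fs/2."""
    x = np.asarray(x, float)
    n = x.size
    if n < 8:
        raise ValueError("need at least 8 samples")
    X = np.fft.fft(x)
    n_half = n // 2
    S = np.zeros((n_half + 1, n), dtype=complex)
    S[0, :] = np.mean(x)
    m = np.fft.fftfreq(n) * n  # -N/2..N/2 ordering matching fft bins
    for k in range(1, n_half + 1):
        gauss = np.exp(-2 * np.pi**2 * m**2 / k**2)
        S[k, :] = np.fft.ifft(np.roll(X, -k) * gauss)
    return S


def stockwell_feature(x: np.ndarray, fs: float) -> float:
    """Mean time-frequency magnitude of the S-transform over [0, fs/2].

    Linear in the signal amplitude; 0 for an all-zero window.
    """
    return float(np.mean(np.abs(stockwell_transform(x))))
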