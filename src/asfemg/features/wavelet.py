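"""Wavelet-packet / DWT energy features (MEWP and MEWT).

The window is decomposed to level J = floor(log2 N) - 2 (at least 1) with
zero-extension boundaries; each terminal packet node (packet mode) or
each coefficient level (dwt mode) contributes its mean squared
coefficient energy (1/K) sum W^2, and the feature is a reducer across
nodes: the median (MEWP — robust choice used for the affected-side
style) or the mean (MEWT).
"""

from __future__ import annotations

import numpy as np
import pywt

#: Boundary mode; zero-extension keeps the decomposition identical to a
#: plain convolution-decimation cascade.
MODE = "zero"


def decomposition_level(n_samples: int) -> int:
    return max(int(np.floor(np.log2(n_samples))) - 2, 1)


def node_energies(
    x: np.ndarray, wavelet_name: str = "db4", mode: str = "packet"
) -> np.ndarray:
    """Per-node (or per-level) mean squared coefficient energies."""
    x = np.asarray(x, float)
    w = pywt.Wavelet(wavelet_name)
    if x.size < w.dec_len:
        raise ValueError(
            f"window of {x.size} samples shorter than {wavelet_name} filter ({w.dec_len})"
        )
    level = decomposition_level(x.size)
    if mode == "packet":
        wp = pywt.WaveletPacket(data=x, wavelet=w, mode=MODE, maxlevel=level)
        nodes = wp.get_level(level, order="natural")
        return np.array([np.mean(np.asarray(nd.data) ** 2) for nd in nodes])
    if mode == "dwt":
        coeffs = pywt.wavedec(x, w, mode=MODE, level=level)
        return np.array([np.mean(np.asarray(c) ** 2) for c in coeffs])
    raise ValueError(f"unknown mode {mode!r}")


def wavelet_energy_feature(
    x: np.ndarray,
    wavelet_name: str = "db4",
    reducer: str = "median",
    mode: str = "packet",
) -> float:
    """Reduce per-node packet energies to one scalar (median or mean).

    Quadratic in the signal amplitude: scaling x by c scales the feature
    by c^2.
    """
    energies = node_energies(x, wavelet_name, mode)
    if reducer == "median":
        return float(np.median(energies))
    if reducer == "mean":
        return float(np.mean(energies))
    raise ValueError(f"unknown reducer {reducer!r}")
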