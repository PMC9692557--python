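"""Hilbert-Huang feature: empirical mode decomposition + Hilbert spectrum.

The EMD here is the classic sifting algorithm (cubic-spline envelopes of
the local extrema, endpoints anchored, Cauchy-type stopping criterion).
It is a self-contained implementation tailored to the short 90-sample
gesture windows this package analyses; only the first intrinsic mode
function (IMF) is consumed by the feature.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import hilbert

log = logging.getLogger(__name__)


def _extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.diff(x)
    maxima = np.nonzero((d[:-1] > 0) & (d[1:] <= 0))[0] + 1
    minima = np.nonzero((d[:-1] < 0) & (d[1:] >= 0))[0] + 1
    return maxima, minima


def _envelope(idx: np.ndarray, x: np.ndarray) -> np.ndarray:
    # anchor the spline at the window endpoints to limit end swings
    n = x.size
    pts = np.concatenate(([0], idx, [n - 1]))
    pts, order = np.unique(pts, return_index=True)
    vals = np.concatenate(([x[0]], x[idx], [x[n - 1]]))[order]
    return CubicSpline(pts, vals)(np.arange(n))


def emd(
    x: np.ndarray,
    max_imfs: int = 8,
    max_siftings: int = 64,
    stop_sd: float = 0.2,
) -> list[np.ndarray]:
    """Decompose ``x`` into intrinsic mode functions by sifting.

    Stops when the residual has fewer than two maxima or two minima, or
    ``max_imfs`` modes were extracted. Deterministic.
    """
    x = np.asarray(x, float)
    residual = x.copy()
    imfs: list[np.ndarray] = []
    for _ in range(max_imfs):
        maxima, minima = _extrema(residual)
        if maxima.size < 2 or minima.size < 2:
            break
        h = residual.copy()
        for _ in range(max_siftings):
            mx, mn = _extrema(h)
            if mx.size < 2 or mn.size < 2:
                break
            mean_env = 0.5 * (_envelope(mx, h) + _envelope(mn, h))
            h_new = h - mean_env
            denom = np.sum(h**2)
            sd = np.sum((h - h_new) ** 2) / denom if denom > 0 else 0.0
            h = h_new
            if sd < stop_sd:
                break
        imfs.append(h)
        residual = residual - h
    return imfs


def hht_feature(x: np.ndarray, fs: float) -> float:
    """Energy-weighted mean instantaneous frequency of the first IMF (Hz).

    The analytic signal of IMF-1 yields an instantaneous amplitude a(t)
    and frequency f(t); the scalar is sum(a^2 f) / sum(a^2). For a pure
    sinusoid this recovers its frequency. Returns 0 (with a log notice)
    when the decomposition yields no IMF, e.g. for monotone or all-zero
    windows.
    """
    x = np.asarray(x, float)
    if x.size < 16:
        raise ValueError("need at least 16 samples")
    imfs = emd(x)
    if not imfs:
        log.info("EMD produced no IMF; HHT feature set to 0")
        return 0.0
    analytic = hilbert(imfs[0])
    a = np.abs(analytic)
    phase = np.unwrap(np.angle(analytic))
    inst_f = np.diff(phase) * fs / (2 * np.pi)
    w = (0.5 * (a[:-1] + a[1:])) ** 2
    wsum = w.sum()
    if wsum == 0:
        return 0.0
    return float(np.sum(w * inst_f) / wsum)
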