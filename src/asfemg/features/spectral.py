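"""Frequency-domain features: spectra, centroids, AR/LPC models, STFT.

Spectra are one-sided FFTs of the demeaned, rectangular-windowed segment
(no zero padding). The amplitude spectrum A_j and the periodogram PSD_j
exclude the DC bin; PSD scaling satisfies Parseval, i.e. the PSD sums to
the mean-square power of the demeaned window.
"""

from __future__ import annotations

import numpy as np

__all__ = ["spectrum", "spectral_suite", "ar_lpc", "stft_feature"]


def spectrum(x: np.ndarray, fs: float):
    """One-sided (f_j, A_j, PSD_j) of the demeaned window, DC bin dropped."""
    x = np.asarray(x, float)
    n = x.size
    if n < 8:
        raise ValueError("need at least 8 samples for a spectrum")
    xd = x - x.mean()
    X = np.fft.rfft(xd)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    # one-sided scaling: double interior bins, not DC/Nyquist
    scale = np.full(X.size, 2.0)
    scale[0] = 1.0
    if n % 2 == 0:
        scale[-1] = 1.0
    amp = scale * np.abs(X) / n
    psd = scale * np.abs(X) ** 2 / n**2
    return f[1:], amp[1:], psd[1:]


def spectral_suite(x: np.ndarray, fs: float) -> dict[str, float | np.ndarray]:
    """MMDF, SMD, SMN, MMNF and the 5-band MASP of one window.

    MMDF/SMD are the half-sums of the amplitude spectrum and the PSD (as
    defined for these feature names in the myoelectric literature this set
    follows); SMN/MMNF are the PSD- and amplitude-weighted spectral
    centroids; MASP splits the one-sided |FFT| into five equal contiguous
    frequency bands and reports each band's sum divided by N.
    """
    x = np.asarray(x, float)
    n = x.size
    f, amp, psd = spectrum(x, fs)
    a_sum = amp.sum()
    p_sum = psd.sum()
    out: dict[str, float | np.ndarray] = {
        "MMDF": 0.5 * a_sum,
        "SMD": 0.5 * p_sum,
        "SMN": float((f * psd).sum() / p_sum) if p_sum > 0 else 0.0,
        "MMNF": float((f * amp).sum() / a_sum) if a_sum > 0 else 0.0,
    }
    mag = np.abs(np.fft.rfft(x - x.mean()))
    out["MASP"] = np.array([band.sum() / n for band in np.array_split(mag, 5)])
    return out


def _autocorr(x: np.ndarray, maxlag: int) -> np.ndarray:
    n = x.size
    return np.array([np.dot(x[: n - k], x[k:]) / n for k in range(maxlag + 1)])


def _levinson(r: np.ndarray, order: int):
    """Levinson-Durbin: predictor coefficients a (x_n ~ sum a_i x_{n-i})
    and final prediction-error variance."""
    if r[0] <= 0:
        raise ValueError("singular autocorrelation (zero energy)")
    a = np.zeros(order)
    err = r[0]
    for i in range(order):
        acc = r[i + 1] - np.dot(a[:i], r[i:0:-1])
        k = acc / err
        a_new = a.copy()
        a_new[i] = k
        a_new[:i] = a[:i] - k * a[:i][::-1]
        a = a_new
        err *= 1 - k**2
        if err <= 0:
            raise ValueError("singular autocorrelation matrix")
    return a, err


def ar_lpc(x: np.ndarray, order: int = 3) -> dict[str, np.ndarray]:
    """Third-order autoregressive and linear-prediction coefficients.

    AR3 = (a0, ar1, ar2, ar3): Yule-Walker coefficients of the demeaned
    window with a0 the window mean (intercept). LPC3 = (b0, b1, b2, b3):
    autocorrelation-method predictor of the raw window with b0 the gain
    (root prediction-error variance).
    """
    x = np.asarray(x, float)
    if x.size < 10:
        raise ValueError("need at least 10 samples")
    xd = x - x.mean()
    r = _autocorr(xd, order)
    a, _ = _levinson(r, order)
    ar = np.concatenate(([x.mean()], a))
    r_raw = _autocorr(x, order)
    b, err = _levinson(r_raw, order)
    lpc = np.concatenate(([np.sqrt(max(err, 0.0))], b))
    return {"AR3": ar, "LPC3": lpc}


def stft_feature(x: np.ndarray, fs: float, win_frac: int = 4) -> float:
    """Mean short-time Fourier magnitude.

    Hamming window of length N // ``win_frac`` with 50% overlap; the
    scalar is the mean magnitude of the one-sided spectrogram. Linear in
    the signal amplitude.
    """
    x = np.asarray(x, float)
    n = x.size
    if n < 32:
        raise ValueError("need at least 32 samples")
    wlen = max(n // win_frac, 8)
    hop = max(wlen // 2, 1)
    w = np.hamming(wlen)
    mags = []
    for start in range(0, n - wlen + 1, hop):
        frame = x[start : start + wlen] * w
        mags.append(np.abs(np.fft.rfft(frame)))
    return float(np.mean(mags))


def stft_mean_rows(x: np.ndarray, fs: float, win_frac: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged STFT magnitude per frequency row (for diagnostics)."""
    x = np.asarray(x, float)
    n = x.size
    wlen = max(n // win_frac, 8)
    hop = max(wlen // 2, 1)
    w = np.hamming(wlen)
    rows = np.mean(
        [np.abs(np.fft.rfft(x[s : s + wlen] * w)) for s in range(0, n - wlen + 1, hop)],
        axis=0,
    )
    return np.fft.rfftfreq(wlen, 1.0 / fs), rows
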