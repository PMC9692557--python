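"""Time-domain features over fixed 90 ms gesture segments.

All formulas use the 1-based sample index n = 1..N of the segment window;
storage is 0-based numpy and the mapping is fixed here, in one place, by
``_n = arange(1, N + 1)``.
"""

from __future__ import annotations

import logging

import numpy as np

log = logging.getLogger(__name__)

#: Sentinel replacing log(0) for degenerate (all-zero) windows so feature
#: vectors of silent rest segments stay finite.
LOG_ZERO_SENTINEL = -1.0e6


def temporal_moment(x: np.ndarray, m: int) -> float:
    """Absolute m-th temporal moment |1/N sum x^m| (m = 4 or 5)."""
    x = np.asarray(x, float)
    if x.size == 0:
        raise ValueError("empty window")
    return float(abs(np.mean(x**m)))


def lcard(x: np.ndarray, threshold: float = 0.001) -> float:
    """Logarithmic cardinality: log(1 + #equivalence classes).

    Samples closer than ``threshold`` are merged into one class; classes
    are found by sorting and splitting where consecutive gaps exceed the
    threshold, making the count scale with waveform richness rather than
    raw amplitude.
    """
    x = np.asarray(x, float)
    if x.size == 0:
        raise ValueError("empty window")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    s = np.sort(x)
    n_classes = 1 + int(np.count_nonzero(np.diff(s) > threshold))
    return float(np.log1p(n_classes))


def _check_window(x: np.ndarray, min_n: int = 1) -> np.ndarray:
    x = np.asarray(x, float)
    if x.size < min_n:
        raise ValueError(f"window of {x.size} samples; need >= {min_n}")
    return x


def lrmsv(x: np.ndarray, gamma: int) -> float:
    """Logarithmic root mean square value of order gamma."""
    x = _check_window(x)
    p = np.mean(np.abs(x) ** gamma) ** (1.0 / gamma)
    if p == 0:
        log.info("LRMSV%d of all-zero window; returning sentinel", gamma)
        return LOG_ZERO_SENTINEL
    return float(np.log(p))


def asm(x: np.ndarray) -> float:
    """Mean absolute value with a piecewise exponent.

    Exponent 0.5 on the central half of the window (0.25N <= n <= 0.75N,
    1-based, boundaries inclusive), 0.75 on the flanks.
    """
    x = _check_window(x)
    n1 = np.arange(1, x.size + 1)
    e = np.where((n1 >= 0.25 * x.size) & (n1 <= 0.75 * x.size), 0.5, 0.75)
    return float(np.mean(np.abs(x) ** e))


def asr(x: np.ndarray) -> float:
    """Absolute summation of square roots: sum |x_n|^(1/2)."""
    x = _check_window(x)
    return float(np.sum(np.abs(x) ** 0.5))


def aac(x: np.ndarray) -> float:
    """Average amplitude change: (1/N) sum |x_{n+1} - x_n|."""
    x = _check_window(x, 2)
    return float(np.sum(np.abs(np.diff(x))) / x.size)


def ssi(x: np.ndarray) -> float:
    """Simple square integral: sum x^2."""
    x = _check_window(x)
    return float(np.sum(x**2))


def kurtosis_feature(x: np.ndarray) -> float:
    """Bias-corrected sample (excess) kurtosis G2."""
    x = _check_window(x, 4)
    n = x.size
    s = x.std(ddof=1)
    if s == 0:
        raise ValueError("kurtosis undefined for constant window")
    g = np.sum(((x - x.mean()) / s) ** 4)
    return float(
        n * (n + 1) / ((n - 1) * (n - 2) * (n - 3)) * g
        - 3 * (n - 1) ** 2 / ((n - 2) * (n - 3))
    )


def sd_population(x: np.ndarray) -> float:
    """Population standard deviation sqrt((1/N) sum (x - mean)^2)."""
    x = _check_window(x)
    return float(x.std(ddof=0))


def mfl(x: np.ndarray) -> float:
    """Maximum fractal length: log10 of the waveform's Euclidean length."""
    x = _check_window(x, 2)
    s = np.sqrt(np.sum(np.diff(x) ** 2))
    if s == 0:
        log.info("MFL of constant window; returning sentinel")
        return LOG_ZERO_SENTINEL
    return float(np.log10(s))


def wl(x: np.ndarray, threshold: float = 0.05) -> float:
    """Thresholded waveform length.

    Sums |x_{n+1} - x_n| over steps exceeding ``threshold`` times the
    largest step, suppressing sub-threshold jitter from the length sum.
    """
    x = _check_window(x, 2)
    d = np.abs(np.diff(x))
    if d.size == 0 or d.max() == 0:
        return 0.0
    return float(d[d > threshold * d.max()].sum())


def _mmav_weights2(n_samples: int) -> np.ndarray:
    n1 = np.arange(1, n_samples + 1)
    w = np.where(
        (n1 >= 0.25 * n_samples) & (n1 <= 0.75 * n_samples),
        1.0,
        np.where(n1 < 0.25 * n_samples, 4 * n1 / n_samples, 4 * (n_samples - n1) / n_samples),
    )
    return w


def _mmav_weights5(n_samples: int) -> np.ndarray:
    # four branches in printed order; first match wins on boundaries
    n1 = np.arange(1, n_samples + 1)
    r = 4 * n1 / n_samples
    w = np.empty(n_samples)
    for i, nv in enumerate(n1):
        if nv < 0.25 * n_samples:
            w[i] = r[i]
        elif nv <= 0.5 * n_samples:
            w[i] = r[i] - 1
        elif nv <= 0.75 * n_samples:
            w[i] = r[i] - 2
        else:
            w[i] = r[i] - 3
    return w


def mmav2(x: np.ndarray) -> float:
    """Modified mean absolute value, trapezoid-weighted window."""
    x = _check_window(x)
    return float(np.mean(_mmav_weights2(x.size) * np.abs(x)))


def mmav5(x: np.ndarray) -> float:
    """Modified mean absolute value, sawtooth five-segment weighting."""
    x = _check_window(x)
    return float(np.mean(_mmav_weights5(x.size) * np.abs(x)))


def mhw(x: np.ndarray) -> float:
    """Multiple Hamming windows: sum (W_n x_n)^2 with Hamming W of length N."""
    x = _check_window(x)
    w = np.hamming(x.size)
    return float(np.sum((w * x) ** 2))


def hjorth_complexity(x: np.ndarray) -> float:
    """Hjorth complexity: Mobility(dx)/Mobility(x).

    Equals 1 for any pure sinusoid (differencing shifts phase but not the
    mobility ratio) and exceeds 1 for broadband signals.
    """
    x = _check_window(x, 3)

    def activity(y: np.ndarray) -> float:
        return float(np.mean((y - y.mean()) ** 2))

    def mobility(y: np.ndarray) -> float:
        a = activity(y)
        if a == 0:
            raise ValueError("zero activity; Hjorth mobility undefined")
        return float(np.sqrt(activity(np.diff(y)) / a))

    return mobility(np.diff(x)) / mobility(x)


def time_domain_suite(x: np.ndarray) -> dict[str, float]:
    """All named time-domain scalars used by the larger feature sets."""
    x = _check_window(x, 4)
    return {
        "LRMSV2": lrmsv(x, 2),
        "LRMSV3": lrmsv(x, 3),
        "ASM": asm(x),
        "ASR": asr(x),
        "AAC": aac(x),
        "SSI": ssi(x),
        "KT": kurtosis_feature(x),
        "SD": sd_population(x),
        "MFL": mfl(x),
        "WL": wl(x),
        "MMAV2": mmav2(x),
        "MMAV5": mmav5(x),
        "MHW": mhw(x),
    }
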