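"""Higuchi fractal dimension."""

from __future__ import annotations

import logging

import numpy as np

log = logging.getLogger(__name__)


def higuchi_fd(x: np.ndarray, kmax: int = 8) -> float:
    """Higuchi fractal dimension of a sampled curve.

    Builds the normalised curve length L(k) over decimation steps
    k = 1..kmax and returns the least-squares slope of log L(k) against
    log(1/k). Smooth curves give ~1, white noise ~2; the estimate is
    clamped to [1, 2] (with a log notice) if the fit strays outside.
    Constant windows return 1 by convention.
    """
    x = np.asarray(x, float)
    if x.size < 2 * kmax:
        raise ValueError(f"need at least {2 * kmax} samples for kmax={kmax}")
    n = x.size
    if np.ptp(x) == 0:
        return 1.0
    lks = []
    ks = []
    for k in range(1, kmax + 1):
        lm = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if idx.size < 2:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / ((idx.size - 1) * k)
            lm.append(dist * norm / k)
        if lm:
            lk = np.mean(lm)
            if lk > 0:
                lks.append(np.log(lk))
                ks.append(np.log(1.0 / k))
    if len(lks) < 2:
        return 1.0
    slope = np.polyfit(ks, lks, 1)[0]
    if not 1.0 <= slope <= 2.0:
        log.info("Higuchi FD %.3f outside [1, 2]; clamped", slope)
        slope = min(max(slope, 1.0), 2.0)
    return float(slope)
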