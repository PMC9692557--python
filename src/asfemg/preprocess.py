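"""Filtering chain for calibrated sEMG: band-pass, Hampel, envelope, normalize.

The offline chain applied before segmentation and feature extraction is

    band-pass (Butterworth 20-300 Hz, zero phase)
      -> Hampel outlier suppression (100-sample neighbourhood, 2 SD rule)
      -> moving RMS envelope (segmentation only)
      -> demean + normalize

Features are computed on the filtered, Hampel-cleaned signal; the RMS
envelope feeds peak detection and the flexor/extensor ratio. Both paths
are exposed so the alternative (features on the envelope) can be selected
explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .calibration import Recording


class PreprocessConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    The band edges and filter order follow standard surface-EMG practice
    (ISEK-motivated 20-300 Hz passband); ``bpf_order`` is the order of the
    analog low/high prototype, i.e. the band-pass has twice that many poles.
    """

    bpf_low_hz: float = 20.0
    bpf_high_hz: float = 300.0
    bpf_order: int = 4
    hampel_window: int = 100
    hampel_nsd: float = 2.0
    envelope_window_s: float = 0.05
    normalization: str = "zscore"

    def __post_init__(self) -> None:
        if not 0 < self.bpf_low_hz < self.bpf_high_hz:
            raise PreprocessConfigError("band edges must satisfy 0 < low < high")
        if self.hampel_window < 10 or self.hampel_window % 2:
            raise PreprocessConfigError("hampel_window must be even and >= 10")
        if self.hampel_nsd <= 0:
            raise PreprocessConfigError("hampel_nsd must be positive")
        if self.normalization not in ("zscore", "unit-max"):
            raise PreprocessConfigError(f"unknown normalization {self.normalization!r}")


def bandpass(rec: Recording, cfg: PreprocessConfig | None = None) -> Recording:
    """Zero-phase Butterworth band-pass.

    Applied forward-backward (``sosfiltfilt``) so burst timing used by the
    segmenter is not skewed by filter group delay.
    """
    cfg = cfg or PreprocessConfig()
    if cfg.bpf_high_hz >= rec.fs_hz / 2:
        raise PreprocessConfigError(
            f"bpf_high_hz={cfg.bpf_high_hz} requires fs > {2 * cfg.bpf_high_hz}"
        )
    sos = sps.butter(
        cfg.bpf_order,
        [cfg.bpf_low_hz, cfg.bpf_high_hz],
        btype="bandpass",
        fs=rec.fs_hz,
        output="sos",
    )
    return rec.with_data(sps.sosfiltfilt(sos, rec.mv, axis=-1))


def _hampel_1d(x: np.ndarray, window: int, nsd: float) -> np.ndarray:
    """Centre-excluded Hampel pass over one stream.

    Sample i is replaced by the median of the ``window`` neighbours centred
    on it (i itself excluded) iff it deviates from the neighbour mean by
    more than ``nsd`` neighbour standard deviations. Near the edges the
    neighbourhood is truncated.
    """
    n = x.size
    half = window // 2
    out = x.copy()
    # interior: vectorized via sliding windows of length window+1, centre dropped
    if n >= window + 1:
        w = np.lib.stride_tricks.sliding_window_view(x, window + 1)
        neigh = np.delete(w, half, axis=1)  # (n-window, window)
        mean = neigh.mean(axis=1)
        sd = neigh.std(axis=1)
        centre = x[half : n - half]
        fire = np.abs(centre - mean) > nsd * sd
        if fire.any():
            med = np.median(neigh[fire], axis=1)
            out[half : n - half][fire] = med
    # edges: truncated neighbourhoods
    for i in list(range(min(half, n))) + list(range(max(n - half, 0), n)):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        neigh = np.delete(x[lo:hi], i - lo)
        if neigh.size < 2:
            continue
        if abs(x[i] - neigh.mean()) > nsd * neigh.std():
            out[i] = np.median(neigh)
    return out


def hampel(rec: Recording, cfg: PreprocessConfig | None = None) -> Recording:
    """Hampel outlier suppression per channel."""
    cfg = cfg or PreprocessConfig()
    if rec.n_samples <= cfg.hampel_window:
        raise PreprocessConfigError(
            f"stream length {rec.n_samples} <= hampel_window {cfg.hampel_window}"
        )
    out = np.vstack(
        [_hampel_1d(ch, cfg.hampel_window, cfg.hampel_nsd) for ch in rec.mv]
    )
    return rec.with_data(out)


def rms_envelope(rec: Recording, cfg: PreprocessConfig | None = None) -> Recording:
    """Centred moving-RMS envelope, same length as the input.

    Edges are reflect-padded; for a steady sinusoid of amplitude A the
    envelope approaches A/sqrt(2).
    """
    cfg = cfg or PreprocessConfig()
    win = int(round(cfg.envelope_window_s * rec.fs_hz))
    if win < 3:
        raise PreprocessConfigError("envelope window must span >= 3 samples")
    kernel = np.full(win, 1.0 / win)
    half_l = (win - 1) // 2
    half_r = win - 1 - half_l
    out = np.empty_like(rec.mv)
    for c, ch in enumerate(rec.mv):
        padded = np.pad(ch**2, (half_l, half_r), mode="reflect")
        out[c] = np.sqrt(np.convolve(padded, kernel, mode="valid"))
    return rec.with_data(out)


def normalize(rec: Recording, mode: str | None = None) -> Recording:
    """Demean and normalize each channel (``zscore`` or ``unit-max``)."""
    mode = mode or "zscore"
    out = np.empty_like(rec.mv)
    for c, ch in enumerate(rec.mv):
        if mode == "zscore":
            sd = ch.std()
            if sd == 0:
                raise PreprocessConfigError(
                    f"channel {rec.channel_names[c]!r} is constant; z-score undefined"
                )
            out[c] = (ch - ch.mean()) / sd
        elif mode == "unit-max":
            m = np.abs(ch).max()
            if m == 0:
                raise PreprocessConfigError(
                    f"channel {rec.channel_names[c]!r} is all-zero; unit-max undefined"
                )
            out[c] = ch / m
        else:
            raise PreprocessConfigError(f"unknown normalization {mode!r}")
    return rec.with_data(out)


def clean(rec: Recording, cfg: PreprocessConfig | None = None) -> Recording:
    """Band-pass then Hampel: the signal features are extracted from."""
    cfg = cfg or PreprocessConfig()
    return hampel(bandpass(rec, cfg), cfg)
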