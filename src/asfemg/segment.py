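"""Semi-automatic burst segmentation.

Peaks are detected on the moving-average-smoothed sum of the four channel
envelopes (one detection function for all channels). Candidate maxima
closer than the minimum peak distance are merged keeping the larger;
low-prominence candidates are discarded against a scale-free threshold
(a quantile of the neighbouring peak-height differences). Within each
repetition block the first and last retained candidates are dropped until
at most ``max_peaks`` remain, mirroring the practice of discarding the
first and last repetitions of a guided 10-repetition set.

Each retained peak yields a fixed-geometry segment spanning 30 ms before
to 60 ms after the peak (90 samples at 1000 Hz) on all four channels.
Rest segments are cut with the same geometry at the centres of idle
intervals supplied explicitly (the manual step of the protocol).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .calibration import Recording

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentationConfig:
    max_peaks: int = 8
    min_peak_distance_s: float = 0.1
    prominence_quantile: float = 0.25
    pre_window_s: float = 0.030
    post_window_s: float = 0.060
    ma_window_s: float = 0.1
    block_gap_s: float = 2.0  # idle gap that delimits repetition blocks
    #: candidates below baseline + height_frac * dynamic-range of the fused
    #: envelope are discarded first — the automated surrogate of the manual
    #: visual-inspection step that rejects idle-noise candidates
    height_frac: float = 0.25

    def __post_init__(self) -> None:
        if self.max_peaks < 1:
            raise ValueError("max_peaks must be >= 1")
        if self.min_peak_distance_s <= 0:
            raise ValueError("min_peak_distance_s must be positive")
        if not 0 < self.prominence_quantile < 1:
            raise ValueError("prominence_quantile must be in (0, 1)")
        if self.pre_window_s <= 0 or self.post_window_s <= 0:
            raise ValueError("segment windows must be positive")

    def window_samples(self, fs: float) -> int:
        return int(round((self.pre_window_s + self.post_window_s) * fs))


@dataclass
class Segment:
    """Fixed-window single-gesture slice across all four channels."""

    x: np.ndarray  # (4, N) mV
    label: str
    peak_time_s: float
    subject_id: str = ""
    side: str = ""
    channel_names: tuple[str, ...] = ()
    fs_hz: float = 1000.0

    @property
    def n_samples(self) -> int:
        return self.x.shape[1]


def detect_peaks(env: Recording, cfg: SegmentationConfig | None = None) -> list[float]:
    """Detect burst peak times on a multichannel envelope.

    Returns retained peak times in seconds, at most ``max_peaks`` per
    repetition block. Deterministic: identical inputs give identical lists.
    """
    cfg = cfg or SegmentationConfig()
    fs = env.fs_hz
    fused = env.mv.sum(axis=0)
    ma = max(int(round(cfg.ma_window_s * fs)), 1)
    kernel = np.full(ma, 1.0 / ma)
    half_l = (ma - 1) // 2
    smooth = np.convolve(np.pad(fused, (half_l, ma - 1 - half_l), mode="edge"), kernel, mode="valid")

    if not np.any(smooth > 0) or np.ptp(smooth) == 0:
        log.warning("flat or empty envelope: no peaks detected")
        return []

    distance = max(int(round(cfg.min_peak_distance_s * fs)), 1)
    idx, props = sps.find_peaks(smooth, distance=distance, prominence=0)
    if idx.size == 0:
        return []
    prominences = props["prominences"]
    heights = smooth[idx]

    # height floor against the fused envelope's dynamic range; candidates
    # sharing one contiguous above-floor region belong to the same burst
    # and are merged keeping the tallest
    floor = smooth.min() + cfg.height_frac * np.ptp(smooth)
    keep = heights >= floor
    idx, heights, prominences = idx[keep], heights[keep], prominences[keep]
    if idx.size == 0:
        return []
    above = smooth >= floor
    starts = np.concatenate(([0], (np.diff(above.view(np.int8)) == 1).astype(int)))
    region_of = np.cumsum(starts)[idx]
    best: dict[int, int] = {}
    for j, (r, h) in enumerate(zip(region_of, heights)):
        if r not in best or h > heights[best[r]]:
            best[r] = j
    sel = np.sort(np.fromiter(best.values(), dtype=int))
    idx, heights, prominences = idx[sel], heights[sel], prominences[sel]

    # scale-free prominence gate: quantile of neighbouring peak-height
    # differences
    if idx.size > 1:
        neigh_diff = np.abs(np.diff(heights))
        thr = np.quantile(neigh_diff, cfg.prominence_quantile)
        keep = prominences >= thr
        idx = idx[keep]
    times = idx / fs
    if times.size == 0:
        return []

    # split into repetition blocks at idle gaps, trim each block
    gaps = np.diff(times)
    block_bounds = np.nonzero(gaps > cfg.block_gap_s)[0]
    blocks = np.split(times, block_bounds + 1)
    out: list[float] = []
    for block in blocks:
        block = list(block)
        while len(block) > cfg.max_peaks:
            block = block[1:-1] if len(block) >= 2 else block[:1]
        out.extend(block)
    return out


def extract_segments(
    rec: Recording,
    peaks: list[float],
    label: str,
    cfg: SegmentationConfig | None = None,
) -> list[Segment]:
    """Cut the fixed [peak - 30 ms, peak + 60 ms] window at each peak.

    Peaks too close to a recording edge are skipped and logged.
    """
    cfg = cfg or SegmentationConfig()
    fs = rec.fs_hz
    n_win = cfg.window_samples(fs)
    pre = int(round(cfg.pre_window_s * fs))
    out = []
    for t in peaks:
        i0 = int(round(t * fs)) - pre
        if i0 < 0 or i0 + n_win > rec.n_samples:
            log.warning("peak at %.3f s too close to recording edge; skipped", t)
            continue
        out.append(
            Segment(
                x=rec.mv[:, i0 : i0 + n_win].copy(),
                label=label,
                peak_time_s=t,
                subject_id=rec.subject_id,
                side=rec.side,
                channel_names=rec.channel_names,
                fs_hz=fs,
            )
        )
    return out


def label_rest(
    rec: Recording,
    intervals: list[tuple[float, float]],
    cfg: SegmentationConfig | None = None,
    burst_times: list[float] | None = None,
) -> list[Segment]:
    """Cut rest segments at the centres of idle intervals.

    Intervals must lie inside the recording and not overlap any detected
    burst window; offending intervals are rejected with a message.
    """
    cfg = cfg or SegmentationConfig()
    burst_times = burst_times or []
    out = []
    for t0, t1 in intervals:
        if t0 < 0 or t1 > rec.duration_s or t1 <= t0:
            raise ValueError(f"interval ({t0}, {t1}) outside recording")
        clash = [t for t in burst_times if t0 <= t <= t1]
        if clash:
            raise ValueError(
                f"interval ({t0}, {t1}) overlaps detected burst at {clash[0]:.3f} s"
            )
        centre = 0.5 * (t0 + t1)
        out.extend(extract_segments(rec, [centre], "rest", cfg))
    return out


def misdetection_report(detected: list[float], truth: list[float], tol_s: float = 0.1) -> float:
    """Fraction of ground-truth bursts with no detection within ``tol_s``."""
    if not truth:
        raise ValueError("misdetection rate undefined for empty ground truth")
    det = np.asarray(sorted(detected), float)
    missed = 0
    for t in truth:
        if det.size == 0 or np.abs(det - t).min() > tol_s:
            missed += 1
    return missed / len(truth)
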