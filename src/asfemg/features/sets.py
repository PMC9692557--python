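"""Feature-set registries and vector assembly.

Three multidomain feature sets are defined over 90 ms gesture segments:

* ``ASF4`` — the compact core: fourth/fifth temporal moments (twofold
  component TM4-5), logarithmic cardinality, the Hilbert-Huang scalar and
  the median wavelet-packet energy (Db4).
* ``ASF14NP`` — the non-paretic set: ASF-4 plus log-RMS values, piecewise
  mean-absolute statistics, average amplitude change, Hjorth complexity
  and two spectral half-sums, closed by the cross-channel
  flexor-to-extensor ratio (FER-4). Wavelet energy uses Db8 with the
  median reducer.
* ``ASF24P`` — the paretic set: ASF-4 with the wavelet energy switched to
  the mean reducer (MEWT, Db4), plus noise-resistant time-domain,
  autoregressive/linear-prediction, banded-spectrum, STFT, Stockwell and
  fractal components.

Per-channel components are evaluated on each of the four channels in the
canonical order FCR, FCU, APB, EDC and concatenated component-major;
FER-4 (ASF-14NP only) is appended as a single cross-channel block.
Component counts (4 named for ASF4, 14 for ASF14NP, 24 for ASF24P) are
asserted at import.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from ..segment import Segment
from . import fractal, hht, spectral, stockwell, timedomain, wavelet


def fer4(seg: Segment) -> np.ndarray:
    """Normalised flexor-to-extensor activity ratios, one per channel.

    ratio_c = mean|x_c| / mean|x_EDC|, normalised by the largest ratio so
    values lie in (0, 1].
    """
    names = seg.channel_names or ("FCR", "FCU", "APB", "EDC")
    mav = np.abs(seg.x).mean(axis=1)
    edc = mav[names.index("EDC")]
    if edc == 0:
        raise ValueError("silent EDC channel; FER-4 undefined")
    ratios = mav / edc
    return ratios / ratios.max()


@dataclass(frozen=True)
class Component:
    """One named component: a callable producing 1+ scalars per channel."""

    name: str
    func: Callable[[np.ndarray, float, dict], np.ndarray] | None
    width: int = 1  # scalars produced per channel
    cross_channel: bool = False


def _scalar(fn):
    return lambda x, fs, ctx: np.array([fn(x)])


def _scalar_fs(fn):
    return lambda x, fs, ctx: np.array([fn(x, fs)])


def _td(key):
    # per-channel suites are memoized in ctx so each is computed once
    def f(x, fs, ctx):
        if "td" not in ctx:
            ctx["td"] = timedomain.time_domain_suite(x)
        return np.array([ctx["td"][key]])

    return f


def _spec(key):
    def f(x, fs, ctx):
        if "spec" not in ctx:
            ctx["spec"] = spectral.spectral_suite(x, fs)
        return np.atleast_1d(np.asarray(ctx["spec"][key]))

    return f


def _wav(name, reducer):
    return lambda x, fs, ctx: np.array(
        [wavelet.wavelet_energy_feature(x, wavelet_name=name, reducer=reducer)]
    )


def _arlpc(key):
    def f(x, fs, ctx):
        if "arlpc" not in ctx:
            ctx["arlpc"] = spectral.ar_lpc(x)
        return ctx["arlpc"][key]

    return f


_TM45 = Component(
    "TM4-5",
    lambda x, fs, ctx: np.array(
        [timedomain.temporal_moment(x, 4), timedomain.temporal_moment(x, 5)]
    ),
    width=2,
)
_TM4 = Component("TM4", lambda x, fs, ctx: np.array([timedomain.temporal_moment(x, 4)]))
_TM5 = Component("TM5", lambda x, fs, ctx: np.array([timedomain.temporal_moment(x, 5)]))
_LCARD = Component("LCARD", _scalar(timedomain.lcard))
_HHT = Component("HHT", _scalar_fs(hht.hht_feature))

ASF4_COMPONENTS: tuple[Component, ...] = (
    _TM45,
    _LCARD,
    _HHT,
    Component("MEWP", _wav("db4", "median")),
)

ASF14NP_COMPONENTS: tuple[Component, ...] = (
    _TM4,
    _TM5,
    _LCARD,
    _HHT,
    Component("MEWP", _wav("db8", "median")),
    Component("LRMSV2", _td("LRMSV2")),
    Component("LRMSV3", _td("LRMSV3")),
    Component("ASM", _td("ASM")),
    Component("ASR", _td("ASR")),
    Component("AAC", _td("AAC")),
    Component("HPC", _scalar(timedomain.hjorth_complexity)),
    Component("MMDF", _spec("MMDF")),
    Component("SMD", _spec("SMD")),
    Component("FER-4", None, width=4, cross_channel=True),
)

ASF24P_COMPONENTS: tuple[Component, ...] = (
    _TM4,
    _TM5,
    _LCARD,
    _HHT,
    Component("MEWT", _wav("db4", "mean")),
    Component("MMAV2", _td("MMAV2")),
    Component("MMAV5", _td("MMAV5")),
    Component("SSI", _td("SSI")),
    Component("KT", _td("KT")),
    Component("LRMSV2", _td("LRMSV2")),
    Component("ASM", _td("ASM")),
    Component("ASR", _td("ASR")),
    Component("SD", _td("SD")),
    Component("MFL", _td("MFL")),
    Component("WL", _td("WL")),
    Component("MHW", _td("MHW")),
    Component("AR3", _arlpc("AR3"), width=4),
    Component("LPC3", _arlpc("LPC3"), width=4),
    Component("MASP", _spec("MASP"), width=5),
    Component("MMNF", _spec("MMNF")),
    Component("SMN", _spec("SMN")),
    Component("STFT", _scalar_fs(spectral.stft_feature)),
    Component("STW", _scalar_fs(stockwell.stockwell_feature)),
    Component("HFD", _scalar(fractal.higuchi_fd)),
)


@dataclass(frozen=True)
class FeatureSetSpec:
    name: str
    components: tuple[Component, ...]

    @property
    def vector_length(self) -> int:
        per_chan = sum(c.width for c in self.components if not c.cross_channel)
        cross = sum(c.width for c in self.components if c.cross_channel)
        return per_chan * 4 + cross

    def value_names(self, channel_names=("FCR", "FCU", "APB", "EDC")) -> list[str]:
        names = []
        for ch in channel_names:
            for c in self.components:
                if c.cross_channel:
                    continue
                if c.width == 1:
                    names.append(f"{ch}:{c.name}")
                else:
                    names.extend(f"{ch}:{c.name}[{i}]" for i in range(c.width))
        for c in self.components:
            if c.cross_channel:
                names.extend(f"{c.name}[{ch}]" for ch in channel_names)
        return names


FEATURE_SETS: dict[str, FeatureSetSpec] = {
    "ASF4": FeatureSetSpec("ASF4", ASF4_COMPONENTS),
    "ASF14NP": FeatureSetSpec("ASF14NP", ASF14NP_COMPONENTS),
    "ASF24P": FeatureSetSpec("ASF24P", ASF24P_COMPONENTS),
}

# registry sanity, checked at import
assert len(ASF4_COMPONENTS) == 4
assert sum(c.width for c in ASF4_COMPONENTS) == 5
assert len(ASF14NP_COMPONENTS) == 14
assert len(ASF24P_COMPONENTS) == 24
assert FEATURE_SETS["ASF4"].vector_length == 20
assert FEATURE_SETS["ASF14NP"].vector_length == 56


def extract_vector(seg: Segment, spec: FeatureSetSpec | str) -> tuple[np.ndarray, list[str]]:
    """Assemble one ordered feature vector for a segment.

    Channel-major: all of channel 1's components, then channel 2, ...;
    cross-channel FER-4 appended last. Deterministic — two extractions of
    the same segment are bit-identical.
    """
    if isinstance(spec, str):
        spec = FEATURE_SETS[spec]
    values: list[float] = []
    for ci, ch in enumerate(seg.channel_names or ("FCR", "FCU", "APB", "EDC")):
        x = seg.x[ci]
        ctx: dict = {}
        for comp in spec.components:
            if comp.cross_channel:
                continue
            try:
                v = np.asarray(comp.func(x, seg.fs_hz, ctx), float)
            except Exception as exc:
                raise RuntimeError(
                    f"feature {comp.name!r} failed on channel {ch!r}: {exc}"
                ) from exc
            if v.size != comp.width:
                raise RuntimeError(
                    f"feature {comp.name!r} produced {v.size} values, expected {comp.width}"
                )
            values.extend(v.tolist())
    for comp in spec.components:
        if comp.cross_channel:
            values.extend(fer4(seg).tolist())
    vec = np.asarray(values, float)
    if not np.all(np.isfinite(vec)):
        bad = [n for n, v in zip(spec.value_names(), vec) if not np.isfinite(v)]
        raise RuntimeError(f"non-finite feature values: {bad[:5]}")
    return vec, spec.value_names(seg.channel_names or ("FCR", "FCU", "APB", "EDC"))


def extract_matrix(segments: list[Segment], spec: FeatureSetSpec | str):
    """Feature matrix (n_segments, n_features), labels and value names."""
    if isinstance(spec, str):
        spec = FEATURE_SETS[spec]
    rows, labels = [], []
    names: list[str] = []
    for seg in segments:
        vec, names = extract_vector(seg, spec)
        rows.append(vec)
        labels.append(seg.label)
    return np.asarray(rows), np.asarray(labels), names
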