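"""Device calibration and raw-recording I/O.

Wireless four-channel sEMG acquisition units of the class modelled here
digitise the electrode signal with an n-bit ADC after a fixed-gain
instrumentation amplifier. The integer ADC codes are mapped back to
millivolts at the electrode with the affine transfer function

    EMG_mV = ((ADC / 2^n) - 1/2) * VCC / G * 1000

where VCC is the operating voltage (3 V), G the sensor gain (1000) and n
the channel bit depth (16). At these constants the dynamic range is
exactly [-1.5, +1.5] mV, with the mid-scale code 2^(n-1) mapping to 0 mV.

Recordings travel on disk as an OpenSignals-style TSV dialect: '#'-prefixed
header lines, one of which carries a JSON object with sampling metadata,
followed by tab-separated integer columns (one per channel).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

#: Canonical channel order: two wrist/finger flexors, the thenar abductor,
#: and the finger extensor. Crosstalk and flexor/extensor-ratio logic rely
#: on this layout.
CHANNEL_NAMES = ("FCR", "FCU", "APB", "EDC")

DEFAULT_FS_HZ = 1000.0


class CalibrationError(ValueError):
    """Raised for ADC codes or calibration constants outside their ranges."""


class RecordingParseError(ValueError):
    """Raised when a TSV recording file does not match the dialect."""


@dataclass(frozen=True)
class CalibrationSpec:
    """ADC-to-millivolt transfer-function constants."""

    vcc_volts: float = 3.0
    gain: float = 1000.0
    adc_bits: int = 16

    def __post_init__(self) -> None:
        if self.vcc_volts <= 0:
            raise CalibrationError("vcc_volts must be positive")
        if self.gain <= 0:
            raise CalibrationError("gain must be positive")
        if self.adc_bits not in (8, 12, 16):
            raise CalibrationError("adc_bits must be one of 8, 12, 16")

    @property
    def full_scale_mv(self) -> float:
        """Half dynamic range in mV (1.5 mV at defaults)."""
        return 0.5 * self.vcc_volts / self.gain * 1000.0


@dataclass
class RawRecording:
    """Uncalibrated integer sample streams, one row per channel."""

    adc: np.ndarray  # (n_channels, n_samples) integer
    fs_hz: float = DEFAULT_FS_HZ
    channel_names: tuple[str, ...] = CHANNEL_NAMES
    side: str = "non-paretic"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.adc = np.atleast_2d(np.asarray(self.adc))
        if self.adc.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.adc.shape[0]} streams for "
                f"{len(self.channel_names)} declared channels"
            )


@dataclass
class Recording:
    """Calibrated multichannel sEMG in millivolts."""

    mv: np.ndarray  # (n_channels, n_samples) float, mV
    fs_hz: float = DEFAULT_FS_HZ
    channel_names: tuple[str, ...] = CHANNEL_NAMES
    side: str = "non-paretic"
    subject_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mv = np.atleast_2d(np.asarray(self.mv, dtype=float))

    @property
    def n_channels(self) -> int:
        return self.mv.shape[0]

    @property
    def n_samples(self) -> int:
        return self.mv.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def channel(self, name: str) -> np.ndarray:
        return self.mv[self.channel_names.index(name)]

    def with_data(self, mv: np.ndarray) -> "Recording":
        return replace(self, mv=np.asarray(mv, dtype=float))


def adc_to_millivolts(raw: RawRecording, cal: CalibrationSpec | None = None) -> Recording:
    """Apply the device transfer function to integer ADC codes.

    The mapping is affine and monotone; the mid-scale code maps to exactly
    0 mV and codes 0 / 2^n map to the full-scale endpoints (±1.5 mV at the
    default constants). The full-scale code 2^n is accepted inclusively so
    the printed endpoints are attainable.
    """
    cal = cal or CalibrationSpec()
    full = 2 ** cal.adc_bits
    adc = np.asarray(raw.adc)
    bad = (adc < 0) | (adc > full)
    if bad.any():
        ch, idx = np.argwhere(bad)[0]
        raise CalibrationError(
            f"ADC value {adc[ch, idx]} outside [0, {full}] on channel "
            f"{raw.channel_names[ch]!r} at sample {idx}"
        )
    mv = (adc / full - 0.5) * cal.vcc_volts / cal.gain * 1000.0
    return Recording(
        mv=mv,
        fs_hz=raw.fs_hz,
        channel_names=raw.channel_names,
        side=raw.side,
        subject_id=raw.subject_id,
    )


def millivolts_to_adc(rec: Recording, cal: CalibrationSpec | None = None) -> RawRecording:
    """Inverse transfer function with rounding to integer codes.

    Composing with :func:`adc_to_millivolts` is the identity up to one LSB
    of quantisation.
    """
    cal = cal or CalibrationSpec()
    full = 2 ** cal.adc_bits
    codes = np.rint(
        (rec.mv / 1000.0 * cal.gain / cal.vcc_volts + 0.5) * full
    ).astype(np.int64)
    codes = np.clip(codes, 0, full)
    return RawRecording(
        adc=codes,
        fs_hz=rec.fs_hz,
        channel_names=rec.channel_names,
        side=rec.side,
        subject_id=rec.subject_id,
    )


# ---------------------------------------------------------------------------
# OpenSignals-style TSV dialect
# ---------------------------------------------------------------------------

_HEADER_MAGIC = "# OpenSignals-style sEMG recording"


def write_recording(raw: RawRecording, path) -> None:
    """Write a RawRecording in the documented TSV dialect."""
    header = {
        "fs": raw.fs_hz,
        "channels": list(raw.channel_names),
        "side": raw.side,
        "subject_id": raw.subject_id,
    }
    with open(path, "w") as fh:
        fh.write(_HEADER_MAGIC + "\n")
        fh.write("# " + json.dumps(header) + "\n")
        fh.write("# EndOfHeader\n")
        np.savetxt(fh, np.asarray(raw.adc).T, fmt="%d", delimiter="\t")


def read_recording(path) -> RawRecording:
    """Read the TSV dialect back into a RawRecording.

    ``read_recording(write_recording(r))`` is the identity.
    """
    header = None
    data_lines: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ").strip()
                if body.startswith("{"):
                    try:
                        header = json.loads(body)
                    except json.JSONDecodeError as exc:
                        raise RecordingParseError(
                            f"line {lineno}: malformed JSON header: {exc}"
                        ) from exc
                continue
            data_lines.append((lineno, line))
    if header is None:
        raise RecordingParseError("missing JSON header line")
    channels = tuple(header.get("channels", CHANNEL_NAMES))
    ncol = len(channels)
    rows = []
    for lineno, line in data_lines:
        parts = line.split("\t")
        if len(parts) != ncol:
            raise RecordingParseError(
                f"line {lineno}: {len(parts)} columns but {ncol} declared channels"
            )
        try:
            rows.append([int(p) for p in parts])
        except ValueError as exc:
            raise RecordingParseError(f"line {lineno}: non-integer sample") from exc
    adc = np.asarray(rows, dtype=np.int64).T if rows else np.zeros((ncol, 0), np.int64)
    return RawRecording(
        adc=adc,
        fs_hz=float(header.get("fs", DEFAULT_FS_HZ)),
        channel_names=channels,
        side=header.get("side", "non-paretic"),
        subject_id=header.get("subject_id", ""),
    )
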