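"""Bespoke binary container for synchronized four-channel recordings.

Layout (all little-endian):

====================  =======  ==========================================
field                 size     meaning
====================  =======  ==========================================
magic                 4 B      ``b"SPTR"``
version               u16      format version (currently 1)
sample_rate           f64      Hz, shared by all channels
start_time            i64      milliseconds since the Unix epoch, UTC
device_id             16 B     UTF-8, NUL padded
led_slot_meta         u32      reserved (written as 0, preserved on read)
frame_count           u64
event_count           u32
frames                12 B ea  4 x 24-bit signed two's complement:
                               ecg, ppg_green, ppg_red, ppg_ir
events                10 B ea  u64 sample_index + u16 event code
====================  =======  ==========================================

One frame is one synchronous 1 ms sample of all four channels; event
markers (e.g. the operator-signalled oxygen onset) are tied to sample
indices rather than wall-clock times so they stay unambiguous relative to
the waveform.  Round trips are bit-exact.
"""

from __future__ import annotations

import enum
import io as _stdio
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import BadMagicError, ParameterError, TruncatedError, VersionError

__all__ = [
    "EventCode",
    "Recording",
    "write_recording",
    "read_recording",
    "recording_capacity",
    "export_csv",
    "import_csv",
    "MAGIC",
    "FORMAT_VERSION",
    "FRAME_BYTES",
]

MAGIC = b"SPTR"
FORMAT_VERSION = 1
_HEADER = struct.Struct("<4sHdq16sIQI")
_EVENT = struct.Struct("<QH")
FRAME_BYTES = 12  # 4 channels x 3 bytes
FRAME_BITS = FRAME_BYTES * 8

_INT24_MIN = -(2**23)
_INT24_MAX = 2**23 - 1

CHANNELS = ("ecg", "ppg_green", "ppg_red", "ppg_ir")


class EventCode(enum.IntEnum):
    """Marker codes stored in the event table."""

    OXYGEN_ONSET = 1
    OXYGEN_OFF = 2
    USER_MARK = 3


def _as_channel(name: str, values) -> np.ndarray:
    arr = np.asarray(values)
    if arr.dtype.kind == "f":
        if not np.all(arr == np.round(arr)):
            raise ParameterError(f"channel '{name}' contains non-integer values")
    arr = arr.astype(np.int64)
    if arr.size and (arr.min() < _INT24_MIN or arr.max() > _INT24_MAX):
        raise ParameterError(
            f"channel '{name}' has values outside the 24-bit range "
            f"[{_INT24_MIN}, {_INT24_MAX}]"
        )
    return arr.astype(np.int32)


@dataclass(frozen=True)
class Recording:
    """In-memory recording: four synchronous integer channels plus markers."""

    ecg: np.ndarray
    ppg_green: np.ndarray
    ppg_red: np.ndarray
    ppg_ir: np.ndarray
    sample_rate: float = 1000.0
    start_time_ms: int = 0
    device_id: str = ""
    events: tuple = ()  # ordered (sample_index, event_code) pairs
    led_slot_meta: int = 0

    def __post_init__(self):
        if self.sample_rate <= 0:
            raise ParameterError("sample_rate must be positive")
        n = None
        for name in CHANNELS:
            arr = _as_channel(name, getattr(self, name))
            object.__setattr__(self, name, arr)
            if n is None:
                n = arr.size
            elif arr.size != n:
                raise ParameterError("all channels must have equal length")
        ev = tuple((int(i), int(c)) for i, c in self.events)
        for idx, code in ev:
            if not 0 <= idx < max(n, 1) or (n == 0):
                raise ParameterError(
                    f"event sample_index {idx} outside recording of {n} frames"
                )
            if not 0 <= code <= 0xFFFF:
                raise ParameterError(f"event code {code} does not fit in 16 bits")
        object.__setattr__(self, "events", ev)
        if len(self.device_id.encode("utf-8")) > 16:
            raise ParameterError("device_id longer than 16 bytes")

    @property
    def n_frames(self) -> int:
        return int(self.ecg.size)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.sample_rate

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNELS:
            raise ParameterError(f"unknown channel '{name}'; expected one of {CHANNELS}")
        return getattr(self, name)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Recording):
            return NotImplemented
        return (
            self.sample_rate == other.sample_rate
            and self.start_time_ms == other.start_time_ms
            and self.device_id == other.device_id
            and self.events == other.events
            and self.led_slot_meta == other.led_slot_meta
            and all(np.array_equal(getattr(self, c), getattr(other, c)) for c in CHANNELS)
        )


def _pack24(frames: np.ndarray) -> bytes:
    """Pack an (n, 4) int32 array into 24-bit little-endian frames."""
    u = (frames.astype(np.int64) & 0xFFFFFF).astype(np.uint32)
    out = np.empty(frames.shape[0] * FRAME_BYTES, dtype=np.uint8)
    view = out.reshape(frames.shape[0], 4, 3)
    view[:, :, 0] = u & 0xFF
    view[:, :, 1] = (u >> 8) & 0xFF
    view[:, :, 2] = (u >> 16) & 0xFF
    return out.tobytes()


def _unpack24(payload: bytes, n_frames: int) -> np.ndarray:
    raw = np.frombuffer(payload, dtype=np.uint8).reshape(n_frames, 4, 3)
    u = (
        raw[:, :, 0].astype(np.uint32)
        | (raw[:, :, 1].astype(np.uint32) << 8)
        | (raw[:, :, 2].astype(np.uint32) << 16)
    )
    signed = u.astype(np.int32)
    signed[signed >= 2**23] -= 2**24
    return signed


def write_recording(recording: Recording, destination) -> int:
    """Serialize ``recording``; returns the number of bytes written.

    ``destination`` may be a path or a binary file object.
    """
    if isinstance(destination, (str, Path)):
        with open(destination, "wb") as fh:
            return write_recording(recording, fh)

    header = _HEADER.pack(
        MAGIC,
        FORMAT_VERSION,
        float(recording.sample_rate),
        int(recording.start_time_ms),
        recording.device_id.encode("utf-8").ljust(16, b"\0"),
        int(recording.led_slot_meta),
        recording.n_frames,
        len(recording.events),
    )
    frames = np.stack(
        [recording.channel(c) for c in CHANNELS], axis=1
    ) if recording.n_frames else np.empty((0, 4), dtype=np.int32)
    body = _pack24(frames)
    events = b"".join(_EVENT.pack(i, c) for i, c in recording.events)
    destination.write(header)
    destination.write(body)
    destination.write(events)
    return len(header) + len(body) + len(events)


def _read_exact(source, n: int, what: str) -> bytes:
    data = source.read(n)
    if len(data) != n:
        raise TruncatedError(
            f"recording truncated while reading {what}: wanted {n} bytes, got {len(data)}"
        )
    return data


def read_recording(source) -> Recording:
    """Parse a recording written by :func:`write_recording` (bit-exact)."""
    if isinstance(source, (str, Path)):
        with open(source, "rb") as fh:
            return read_recording(fh)
    if isinstance(source, (bytes, bytearray)):
        return read_recording(_stdio.BytesIO(source))

    head = _read_exact(source, _HEADER.size, "header")
    magic, version, sample_rate, start_ms, dev, led_meta, n_frames, n_events = (
        _HEADER.unpack(head)
    )
    if magic != MAGIC:
        raise BadMagicError(f"bad magic {magic!r}, expected {MAGIC!r}")
    if version != FORMAT_VERSION:
        raise VersionError(found=version, supported=FORMAT_VERSION)

    payload = _read_exact(source, n_frames * FRAME_BYTES, f"{n_frames} frames")
    frames = _unpack24(payload, n_frames) if n_frames else np.empty((0, 4), dtype=np.int32)
    ev_raw = _read_exact(source, n_events * _EVENT.size, f"{n_events} events")
    events = tuple(
        _EVENT.unpack_from(ev_raw, k * _EVENT.size) for k in range(n_events)
    )
    return Recording(
        ecg=frames[:, 0],
        ppg_green=frames[:, 1],
        ppg_red=frames[:, 2],
        ppg_ir=frames[:, 3],
        sample_rate=sample_rate,
        start_time_ms=start_ms,
        device_id=dev.rstrip(b"\0").decode("utf-8"),
        events=events,
        led_slot_meta=led_meta,
    )


def recording_capacity(flash_bits: float, sample_rate: float, frame_bits: float = FRAME_BITS) -> float:
    """Recording time (s) a flash memory of ``flash_bits`` can hold.

    Pure arithmetic: ``flash_bits / (sample_rate * frame_bits)``.  The
    device configuration (1 Gbit, 1 kHz, 96-bit frames) yields ~2.9 h,
    which covers a full ~2 h therapy session.
    """
    if flash_bits <= 0 or sample_rate <= 0 or frame_bits <= 0:
        raise ParameterError("flash_bits, sample_rate and frame_bits must all be positive")
    return flash_bits / (sample_rate * frame_bits)


def export_csv(recording: Recording, destination, events_destination=None) -> int:
    """Write the recording as CSV; returns the number of data rows.

    Columns: ``time_s, ecg, ppg_green, ppg_red, ppg_ir`` with time in
    seconds (``sample_index / sample_rate``).  Event markers go to a
    companion CSV; when ``destination`` is a path and
    ``events_destination`` is omitted it defaults to
    ``<destination>.events.csv`` (only written if events exist).
    """
    import pandas as pd

    n = recording.n_frames
    df = pd.DataFrame({"time_s": np.arange(n) / recording.sample_rate})
    for c in CHANNELS:
        df[c] = recording.channel(c)
    df.to_csv(destination, index=False, float_format="%.6f")

    if recording.events:
        if events_destination is None:
            if not isinstance(destination, (str, Path)):
                raise ParameterError(
                    "events_destination required when destination is not a path"
                )
            events_destination = str(destination) + ".events.csv"
        ev = pd.DataFrame(recording.events, columns=["sample_index", "code"])
        ev["time_s"] = ev["sample_index"] / recording.sample_rate
        ev["label"] = [
            EventCode(c).name if c in EventCode._value2member_map_ else "UNKNOWN"
            for c in ev["code"]
        ]
        ev.to_csv(events_destination, index=False, float_format="%.6f")
    return n


def import_csv(source, sample_rate: float | None = None, device_id: str = "csv") -> Recording:
    """Rebuild a Recording from :func:`export_csv` output (channel-exact).

    Two-column files (``time, signal``) are accepted for interoperability:
    the single signal column is stored as the ECG channel with zeroed PPG
    channels.  ``sample_rate`` is inferred from the time column when not
    given.
    """
    import pandas as pd

    df = pd.read_csv(source)
    if df.shape[1] < 2:
        raise ParameterError("CSV needs a time column plus at least one signal column")
    time = df.iloc[:, 0].to_numpy(dtype=float)
    if sample_rate is None:
        if time.size < 2:
            raise ParameterError("cannot infer sample rate from fewer than 2 rows")
        sample_rate = 1.0 / float(np.median(np.diff(time)))

    if set(CHANNELS).issubset(df.columns):
        chans = {c: df[c].to_numpy() for c in CHANNELS}
    else:
        sig = df.iloc[:, 1].to_numpy(dtype=float)
        if not np.all(sig == np.round(sig)):
            # float physical units: quantize like the simulator's ADC scaling
            from .simulate import COUNTS_PER_UNIT

            sig = np.round(sig * COUNTS_PER_UNIT)
        zero = np.zeros(sig.size, dtype=np.int32)
        chans = {"ecg": sig, "ppg_green": zero, "ppg_red": zero, "ppg_ir": zero}
    return Recording(sample_rate=sample_rate, device_id=device_id, **chans)
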