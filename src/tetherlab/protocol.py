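"""Device/frame data model and the byte-level codec multiplexing all streams.

Every device shares one serialized channel.  A frame is the atomic unit:
``(device_id, timestamp_ticks, payload)``.  On the wire a frame is a fixed
14-byte little-endian header followed by the payload:

======  =====  ====================================
offset  bytes  field
======  =====  ====================================
0       4      device_id, unsigned
4       8      timestamp_ticks, unsigned
12      2      payload length, unsigned
14      n      payload
======  =====  ====================================

The 2-byte length field caps payloads at 65,535 bytes; larger payloads must
be chunked by the producer.
"""

from __future__ import annotations

import enum
import json
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from tetherlab.errors import (
    IncompleteFrameError,
    PayloadOverflowError,
    PayloadSizeError,
    UnknownDeviceError,
)

HEADER_STRUCT = struct.Struct("<IQH")
HEADER_BYTES = HEADER_STRUCT.size  # 14
MAX_PAYLOAD_BYTES = 0xFFFF

#: Default shared-clock frequency: one tick per spike-band sample period.
DEFAULT_CLOCK_HZ = 30_000.0


class DeviceKind(str, enum.Enum):
    EPHYS_SOURCE = "ephys_source"
    ORIENTATION_SOURCE = "orientation_source"
    LIGHTHOUSE_SOURCE = "lighthouse_source"
    HEARTBEAT_SOURCE = "heartbeat_source"
    STIMULATOR_SINK = "stimulator_sink"
    LED_SINK = "led_sink"
    GENERIC = "generic"


class Direction(str, enum.Enum):
    READ = "read"
    WRITE = "write"
    READ_WRITE = "read_write"


@dataclass(frozen=True)
class DeviceDescriptor:
    """One source or sink sharing the serialized link.

    ``sample_payload_bytes`` is the fixed per-frame payload size for
    fixed-rate devices; 0 marks a variable-length device.
    ``nominal_rate_hz`` is 0 for purely event-driven devices.
    """

    device_id: int
    kind: DeviceKind = DeviceKind.GENERIC
    direction: Direction = Direction.READ
    sample_payload_bytes: int = 0
    nominal_rate_hz: float = 0.0
    description: str = ""

    def __post_init__(self) -> None:
        if self.device_id < 0:
            raise ValueError("device_id must be unsigned")
        if self.sample_payload_bytes < 0:
            raise ValueError("sample_payload_bytes must be >= 0")
        if self.nominal_rate_hz < 0:
            raise ValueError("nominal_rate_hz must be >= 0")
        # Accept plain strings for convenience.
        object.__setattr__(self, "kind", DeviceKind(self.kind))
        object.__setattr__(self, "direction", Direction(self.direction))

    @property
    def fixed_size(self) -> bool:
        return self.sample_payload_bytes > 0

    def to_dict(self) -> dict:
        return {
            "device_id": self.device_id,
            "kind": self.kind.value,
            "direction": self.direction.value,
            "sample_payload_bytes": self.sample_payload_bytes,
            "nominal_rate_hz": self.nominal_rate_hz,
            "description": self.description,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DeviceDescriptor":
        return cls(
            device_id=int(d["device_id"]),
            kind=DeviceKind(d.get("kind", "generic")),
            direction=Direction(d.get("direction", "read")),
            sample_payload_bytes=int(d.get("sample_payload_bytes", 0)),
            nominal_rate_hz=float(d.get("nominal_rate_hz", 0.0)),
            description=str(d.get("description", "")),
        )


@dataclass
class DeviceMap:
    """Registry of devices sharing one link plus the shared clock frequency."""

    devices: Sequence[DeviceDescriptor] = field(default_factory=list)
    clock_hz: float = DEFAULT_CLOCK_HZ

    def __post_init__(self) -> None:
        if self.clock_hz <= 0:
            raise ValueError("clock_hz must be positive")
        ids = [d.device_id for d in self.devices]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate device_id in DeviceMap")
        self._by_id = {d.device_id: d for d in self.devices}

    def __contains__(self, device_id: int) -> bool:
        return device_id in self._by_id

    def __getitem__(self, device_id: int) -> DeviceDescriptor:
        try:
            return self._by_id[device_id]
        except KeyError:
            raise UnknownDeviceError(f"device_id {device_id} not in map") from None

    def __iter__(self):
        return iter(self.devices)

    def __len__(self) -> int:
        return len(self.devices)

    def to_dict(self) -> dict:
        return {
            "clock_hz": self.clock_hz,
            "devices": [d.to_dict() for d in self.devices],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DeviceMap":
        return cls(
            devices=[DeviceDescriptor.from_dict(x) for x in d.get("devices", [])],
            clock_hz=float(d.get("clock_hz", DEFAULT_CLOCK_HZ)),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "DeviceMap":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class Frame:
    """Atomic acquisition unit on the shared clock."""

    device_id: int
    timestamp_ticks: int
    payload: bytes = b""

    def __post_init__(self) -> None:
        if self.device_id < 0:
            raise ValueError("device_id must be unsigned")
        if not 0 <= self.timestamp_ticks < 2**64:
            raise ValueError("timestamp_ticks must fit an unsigned 64-bit counter")
        object.__setattr__(self, "payload", bytes(self.payload))

    @property
    def encoded_size(self) -> int:
        return HEADER_BYTES + len(self.payload)

    def time_s(self, clock_hz: float) -> float:
        return self.timestamp_ticks / clock_hz


def _validate_payload(frame: Frame, device_map: DeviceMap) -> DeviceDescriptor:
    desc = device_map[frame.device_id]  # raises UnknownDeviceError
    if len(frame.payload) > MAX_PAYLOAD_BYTES:
        raise PayloadOverflowError(
            f"payload of {len(frame.payload)} bytes exceeds {MAX_PAYLOAD_BYTES}"
        )
    if desc.fixed_size and len(frame.payload) != desc.sample_payload_bytes:
        raise PayloadSizeError(
            f"device {frame.device_id} expects {desc.sample_payload_bytes} payload "
            f"bytes, got {len(frame.payload)}"
        )
    return desc


def encode_frame(frame: Frame, device_map: DeviceMap) -> bytes:
    """Serialize one frame: 14-byte little-endian header + payload."""
    _validate_payload(frame, device_map)
    header = HEADER_STRUCT.pack(frame.device_id, frame.timestamp_ticks, len(frame.payload))
    return header + frame.payload


def decode_frame(buf: bytes, device_map: DeviceMap) -> tuple[Frame, int]:
    """Parse one frame from the start of ``buf``.

    Returns the frame and the number of bytes consumed so streams can be
    parsed incrementally.  Raises :class:`IncompleteFrameError` when the
    buffer ends mid-frame (recoverable: the caller may wait for more bytes).
    """
    if len(buf) < HEADER_BYTES:
        raise IncompleteFrameError(
            f"need {HEADER_BYTES} header bytes, have {len(buf)}"
        )
    device_id, timestamp, length = HEADER_STRUCT.unpack_from(buf)
    end = HEADER_BYTES + length
    if len(buf) < end:
        raise IncompleteFrameError(
            f"need {end} bytes for frame, have {len(buf)}"
        )
    frame = Frame(device_id, timestamp, bytes(buf[HEADER_BYTES:end]))
    _validate_payload(frame, device_map)
    return frame, end


def decode_stream(buf: bytes, device_map: DeviceMap) -> list[Frame]:
    """Parse a concatenation of encoded frames; input must end on a boundary."""
    frames: list[Frame] = []
    offset = 0
    view = memoryview(buf)
    while offset < len(buf):
        frame, consumed = decode_frame(bytes(view[offset:]), device_map)
        frames.append(frame)
        offset += consumed
    return frames


def multiplex(
    streams: Iterable[Sequence[Frame]], device_map: DeviceMap | None = None
) -> list[Frame]:
    """Merge per-device time-ordered streams into one globally ordered stream.

    Sort key: timestamp, then device_id, then per-device arrival order.  The
    sort is stable with respect to every input stream, and the output is a
    frame-for-frame permutation of the inputs.
    """
    tagged: list[tuple[int, int, int, Frame]] = []
    for stream in streams:
        prev: dict[int, int] = {}
        for arrival, frame in enumerate(stream):
            if device_map is not None and frame.device_id not in device_map:
                raise UnknownDeviceError(f"device_id {frame.device_id} not in map")
            last = prev.get(frame.device_id)
            if last is not None and frame.timestamp_ticks < last:
                raise ValueError(
                    f"stream for device {frame.device_id} is not time-ordered"
                )
            prev[frame.device_id] = frame.timestamp_ticks
            tagged.append((frame.timestamp_ticks, frame.device_id, arrival, frame))
    tagged.sort(key=lambda t: t[:3])
    return [t[3] for t in tagged]
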