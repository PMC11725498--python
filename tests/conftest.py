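import numpy as np
import pytest

from tetherlab.behavior import ArenaSpec
from tetherlab.protocol import DeviceDescriptor, DeviceKind, DeviceMap, Direction, Frame


@pytest.fixture
def device_map() -> DeviceMap:
    return DeviceMap(
        devices=[
            DeviceDescriptor(1, DeviceKind.HEARTBEAT_SOURCE, Direction.READ, 8, 10.0),
            DeviceDescriptor(2, DeviceKind.EPHYS_SOURCE, Direction.READ, 8, 30_000.0),
            DeviceDescriptor(3, DeviceKind.GENERIC, Direction.READ, 0, 0.0),
            DeviceDescriptor(16, DeviceKind.STIMULATOR_SINK, Direction.WRITE, 16, 0.0),
        ],
        clock_hz=30_000.0,
    )


@pytest.fixture
def arena() -> ArenaSpec:
    return ArenaSpec()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_frames(rng, device_map, n, max_payload=64):
    """Valid random frames, per-device non-decreasing timestamps."""
    frames = []
    last = {d.device_id: 0 for d in device_map}
    variable = [d for d in device_map if not d.fixed_size]
    fixed = [d for d in device_map if d.fixed_size]
    for _ in range(n):
        if variable and rng.random() < 0.3:
            d = variable[rng.integers(len(variable))]
            payload = rng.bytes(int(rng.integers(0, max_payload + 1)))
        else:
            d = fixed[rng.integers(len(fixed))]
            payload = rng.bytes(d.sample_payload_bytes)
        t = last[d.device_id] + int(rng.integers(0, 10))
        last[d.device_id] = t
        frames.append(Frame(d.device_id, t, payload))
    return frames
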