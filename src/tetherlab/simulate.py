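"""Seeded device simulators producing protocol frames.

Every generator is deterministic given its configuration and seed, and the
frame streams it emits satisfy the protocol invariants (fixed payload sizes,
non-decreasing per-device timestamps).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from tetherlab.errors import DomainError
from tetherlab.pose import PoseEstimate, StationPose, SweepEvent, wrap_angle_rad
from tetherlab.protocol import (
    DEFAULT_CLOCK_HZ,
    DeviceDescriptor,
    DeviceKind,
    DeviceMap,
    Direction,
    Frame,
)

I16_MIN, I16_MAX = -32768, 32767

EPHYS_DEVICE_ID = 0
ORIENTATION_DEVICE_ID = 1
LIGHTHOUSE_DEVICE_ID = 2
HEARTBEAT_DEVICE_ID = 3
STIM_DEVICE_ID = 16
LED_DEVICE_ID = 17


def default_spike_template(n_samples: int = 30) -> np.ndarray:
    """Biphasic unit-peak waveform, 1 ms at 30 kHz.

    Detectors must not depend on this exact shape.
    """
    t = np.arange(n_samples)
    wave = np.sin(2.0 * np.pi * t / n_samples) * np.hanning(n_samples)
    return wave / np.max(np.abs(wave))


@dataclass
class EphysSimConfig:
    """Multichannel extracellular signal generator parameters."""

    n_channels: int = 4
    sample_rate_hz: float = 30_000.0
    noise_sd_uV: float = 10.0
    spike_amplitude_uV: float = -200.0
    spike_rate_hz: float = 2.0  # per channel
    spike_template: np.ndarray = field(default_factory=default_spike_template)
    adc_uV_per_count: float = 0.195
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.noise_sd_uV < 0 or self.spike_rate_hz < 0:
            raise ValueError("rates and noise sd must be nonnegative")
        if self.adc_uV_per_count <= 0:
            raise ValueError("adc_uV_per_count must be positive")
        self.spike_template = np.asarray(self.spike_template, dtype=float)

    @property
    def payload_bytes(self) -> int:
        return 2 * self.n_channels

    def descriptor(self, device_id: int = EPHYS_DEVICE_ID) -> DeviceDescriptor:
        return DeviceDescriptor(
            device_id=device_id,
            kind=DeviceKind.EPHYS_SOURCE,
            direction=Direction.READ,
            sample_payload_bytes=self.payload_bytes,
            nominal_rate_hz=self.sample_rate_hz,
            description=f"{self.n_channels}-channel simulated bioamplifier",
        )


@dataclass
class OrientationScript:
    """Piecewise-constant head-rotation script for the orientation simulator.

    Each segment is (duration_s, yaw_rate_deg_per_s, pitch_deg, roll_deg).
    """

    segments: Sequence[tuple[float, float, float, float]]
    sample_rate_hz: float = 100.0
    noise_sd_deg: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if any(seg[0] <= 0 for seg in self.segments):
            raise ValueError("segment durations must be positive")
        if self.noise_sd_deg < 0:
            raise ValueError("noise_sd_deg must be nonnegative")

    @property
    def total_duration_s(self) -> float:
        return sum(seg[0] for seg in self.segments)

    def descriptor(self, device_id: int = ORIENTATION_DEVICE_ID) -> DeviceDescriptor:
        return DeviceDescriptor(
            device_id=device_id,
            kind=DeviceKind.ORIENTATION_SOURCE,
            direction=Direction.READ,
            sample_payload_bytes=16,  # quaternion, 4 x float32 (x, y, z, w)
            nominal_rate_hz=self.sample_rate_hz,
            description="simulated absolute-orientation sensor",
        )


@dataclass(frozen=True)
class StimCommand:
    """One stimulation pulse command (electrical mA or LED level 0-7)."""

    onset_tick: int
    pulse_width_ticks: int
    amplitude: float
    kind: str = "electrical"  # "electrical" | "led"

    #: hardware envelope of the simulated stimulator circuits
    MAX_CURRENT_MA = 1.5
    LED_LEVELS = 8
    PAYLOAD_BYTES = 16  # onset u64 + width u32 + amplitude f32

    def __post_init__(self) -> None:
        if not 0 <= self.onset_tick < 2**64:
            raise ValueError("onset_tick must fit an unsigned 64-bit counter")
        if self.pulse_width_ticks < 1:
            raise ValueError("pulse_width_ticks must be >= 1")
        if self.kind == "electrical":
            if abs(self.amplitude) > self.MAX_CURRENT_MA:
                raise ValueError(
                    f"electrical amplitude must lie within +/-{self.MAX_CURRENT_MA} mA"
                )
        elif self.kind == "led":
            if self.amplitude != int(self.amplitude) or not (
                0 <= self.amplitude < self.LED_LEVELS
            ):
                raise ValueError("LED level must be an integer in 0..7")
        else:
            raise ValueError("kind must be 'electrical' or 'led'")

    def to_frame(self, device_id: int = STIM_DEVICE_ID) -> Frame:
        import struct

        payload = struct.pack(
            "<QIf", self.onset_tick, self.pulse_width_ticks, self.amplitude
        )
        return Frame(device_id, self.onset_tick, payload)


def stimulator_descriptor(device_id: int = STIM_DEVICE_ID) -> DeviceDescriptor:
    return DeviceDescriptor(
        device_id=device_id,
        kind=DeviceKind.STIMULATOR_SINK,
        direction=Direction.WRITE,
        sample_payload_bytes=StimCommand.PAYLOAD_BYTES,
        nominal_rate_hz=0.0,
        description="simulated constant-current stimulator",
    )


def _ticks_for_samples(n: int, sample_rate_hz: float, clock_hz: float) -> np.ndarray:
    return np.round(np.arange(n) * (clock_hz / sample_rate_hz)).astype(np.uint64)


def generate_ephys_signal(
    config: EphysSimConfig,
    duration_s: float,
    spike_times: Sequence[float] | None = None,
) -> tuple[np.ndarray, dict[int, np.ndarray], int]:
    """Simulate channel traces in ADC counts.

    Returns (counts array of shape (n_samples, n_channels) int16,
    ground-truth spike times per channel in seconds, saturated-sample count).
    Spikes are template-shaped deflections at Poisson times per channel, or
    at the explicit ``spike_times`` applied to every channel.
    """
    if duration_s <= 0:
        raise DomainError("duration_s must be positive")
    rng = np.random.default_rng(config.seed)
    n = int(round(duration_s * config.sample_rate_hz))
    sig_uV = rng.normal(0.0, config.noise_sd_uV, size=(n, config.n_channels))

    truth: dict[int, np.ndarray] = {}
    template = config.spike_template * config.spike_amplitude_uV
    for ch in range(config.n_channels):
        if spike_times is not None:
            times = np.asarray(sorted(spike_times), dtype=float)
        elif config.spike_rate_hz > 0:
            n_spikes = rng.poisson(config.spike_rate_hz * duration_s)
            times = np.sort(rng.uniform(0.0, duration_s, size=n_spikes))
        else:
            times = np.empty(0)
        # Drop spikes whose waveform would run off the end of the trace.
        onsets = np.round(times * config.sample_rate_hz).astype(int)
        ok = onsets + template.size <= n
        onsets, times = onsets[ok], times[ok]
        for onset in onsets:
            sig_uV[onset : onset + template.size, ch] += template
        truth[ch] = times

    counts = np.round(sig_uV / config.adc_uV_per_count)
    saturated = int(np.count_nonzero((counts < I16_MIN) | (counts > I16_MAX)))
    counts = np.clip(counts, I16_MIN, I16_MAX).astype(np.int16)
    return counts, truth, saturated


def generate_ephys_frames(
    config: EphysSimConfig,
    duration_s: float,
    spike_times: Sequence[float] | None = None,
    device_id: int = EPHYS_DEVICE_ID,
    clock_hz: float = DEFAULT_CLOCK_HZ,
) -> tuple[list[Frame], dict[int, np.ndarray], int]:
    """One frame per sample period carrying little-endian int16 counts."""
    counts, truth, saturated = generate_ephys_signal(config, duration_s, spike_times)
    ticks = _ticks_for_samples(counts.shape[0], config.sample_rate_hz, clock_hz)
    le = counts.astype("<i2")
    frames = [
        Frame(device_id, int(ticks[i]), le[i].tobytes()) for i in range(counts.shape[0])
    ]
    return frames, truth, saturated


def frames_to_ephys_counts(frames: Sequence[Frame], n_channels: int) -> np.ndarray:
    """Inverse of the ephys payload packing: (n_frames, n_channels) int16."""
    buf = b"".join(f.payload for f in frames)
    return np.frombuffer(buf, dtype="<i2").reshape(len(frames), n_channels)


def generate_orientation_samples(
    script: OrientationScript, duration_s: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate the orientation sensor as (times, quaternions, true unwrapped yaw).

    Yaw integrates each segment's rate; pitch/roll are held per segment;
    beyond the scripted timeline the final segment's attitude persists with
    zero yaw rate.  Quaternions are scalar-last and include angular noise;
    the returned cumulative yaw is noise-free ground truth in degrees.
    """
    if duration_s <= 0:
        raise DomainError("duration_s must be positive")
    rng = np.random.default_rng(script.seed)
    dt = 1.0 / script.sample_rate_hz
    n = int(round(duration_s * script.sample_rate_hz))
    times = np.arange(n) * dt

    yaw = np.zeros(n)
    pitch = np.zeros(n)
    roll = np.zeros(n)
    cumulative = 0.0
    seg_iter = iter(script.segments)
    seg = next(seg_iter, None)
    seg_end = seg[0] if seg is not None else 0.0
    seg_start = 0.0
    for i, t in enumerate(times):
        while seg is not None and t >= seg_end:
            cumulative += seg[1] * (seg_end - seg_start)
            seg_start = seg_end
            nxt = next(seg_iter, None)
            if nxt is None:
                seg = (math.inf, 0.0, seg[2], seg[3])
                seg_end = math.inf
            else:
                seg = nxt
                seg_end = seg_start + seg[0]
        yaw[i] = cumulative + seg[1] * (t - seg_start)
        pitch[i] = seg[2]
        roll[i] = seg[3]

    noisy = np.column_stack([yaw, pitch, roll])
    if script.noise_sd_deg > 0:
        noisy = noisy + rng.normal(0.0, script.noise_sd_deg, size=noisy.shape)
    quats = Rotation.from_euler("ZYX", noisy, degrees=True).as_quat()
    return times, quats, yaw


def generate_orientation_frames(
    script: OrientationScript,
    duration_s: float,
    device_id: int = ORIENTATION_DEVICE_ID,
    clock_hz: float = DEFAULT_CLOCK_HZ,
) -> tuple[list[Frame], np.ndarray]:
    """Frame stream of unit quaternions (4 x float32 LE) + true cumulative yaw."""
    times, quats, true_yaw = generate_orientation_samples(script, duration_s)
    ticks = _ticks_for_samples(times.size, script.sample_rate_hz, clock_hz)
    q32 = quats.astype("<f4")
    frames = [
        Frame(device_id, int(ticks[i]), q32[i].tobytes()) for i in range(times.size)
    ]
    return frames, true_yaw


def frames_to_quaternions(frames: Sequence[Frame]) -> np.ndarray:
    buf = b"".join(f.payload for f in frames)
    return np.frombuffer(buf, dtype="<f4").reshape(len(frames), 4).astype(float)


def generate_lighthouse_events(
    trajectory: Sequence[PoseEstimate],
    stations: Sequence[StationPose],
    timing_jitter_s: float = 0.0,
    seed: int = 0,
    occlusion_intervals: Sequence[tuple[float, float]] = (),
) -> tuple[list[SweepEvent], dict[int, dict[str, int]]]:
    """Forward model of the sweep geometry: pose samples -> pulse timings.

    For every pose sample and station, emits an azimuth and an elevation
    sweep event whose pulse offsets encode the true direction to the target
    (angle = 2*pi * offset / period) plus Gaussian timing jitter.  Poses
    behind a station are silently omitted and counted in the visibility
    report, as are samples inside occlusion intervals.
    """
    if timing_jitter_s < 0:
        raise DomainError("timing_jitter_s must be nonnegative")
    if len(stations) < 2:
        raise DomainError("need >= 2 stations for 3D recovery")
    rng = np.random.default_rng(seed)
    events: list[SweepEvent] = []
    report = {
        s.station_id: {"visible": 0, "behind": 0, "occluded": 0} for s in stations
    }
    for pose in trajectory:
        t = pose.time_s
        occluded = any(a <= t < b for a, b in occlusion_intervals)
        for st in stations:
            if occluded:
                report[st.station_id]["occluded"] += 1
                continue
            d = st.rotation.inv().apply(pose.position - st.position)
            if d[0] <= 0:
                report[st.station_id]["behind"] += 1
                continue
            az = math.atan2(d[1], d[0])
            el = math.atan2(d[2], d[0])
            report[st.station_id]["visible"] += 1
            for axis, angle in (("azimuth", az), ("elevation", el)):
                offset = (angle % (2.0 * math.pi)) / (2.0 * math.pi) * st.sweep_period_s
                if timing_jitter_s > 0:
                    offset = (offset + rng.normal(0.0, timing_jitter_s)) % st.sweep_period_s
                if offset >= st.sweep_period_s:  # float fold-back at the seam
                    offset = 0.0
                events.append(SweepEvent(st.station_id, axis, float(offset), t))
    return events, report


def events_to_angles(
    events: Sequence[SweepEvent],
    stations: Sequence[StationPose],
    sample_time_s: float,
) -> dict[int, tuple[float, float]]:
    """Collect the (azimuth, elevation) pair of each station at one pose sample."""
    from tetherlab.pose import sweep_to_angles

    by_id = {s.station_id: s for s in stations}
    pairs: dict[int, dict[str, SweepEvent]] = {}
    for ev in events:
        if ev.sample_time_s == sample_time_s:
            pairs.setdefault(ev.station_id, {})[ev.axis] = ev
    out = {}
    for sid, evs in pairs.items():
        if "azimuth" in evs and "elevation" in evs:
            out[sid] = sweep_to_angles(evs["azimuth"], evs["elevation"], by_id[sid])
    return out


def heartbeat_frames(
    duration_s: float,
    rate_hz: float = 10.0,
    device_id: int = HEARTBEAT_DEVICE_ID,
    clock_hz: float = DEFAULT_CLOCK_HZ,
) -> list[Frame]:
    """Simple 8-byte time-stamping device: payload is the tick count itself."""
    import struct

    n = int(round(duration_s * rate_hz))
    ticks = _ticks_for_samples(n, rate_hz, clock_hz)
    return [
        Frame(device_id, int(t), struct.pack("<Q", int(t))) for t in ticks
    ]


def heartbeat_descriptor(
    device_id: int = HEARTBEAT_DEVICE_ID, rate_hz: float = 10.0
) -> DeviceDescriptor:
    return DeviceDescriptor(
        device_id=device_id,
        kind=DeviceKind.HEARTBEAT_SOURCE,
        direction=Direction.READ,
        sample_payload_bytes=8,
        nominal_rate_hz=rate_hz,
        description="8-byte time-stamping device",
    )


def build_device_map(
    descriptors: Sequence[DeviceDescriptor], clock_hz: float = DEFAULT_CLOCK_HZ
) -> DeviceMap:
    return DeviceMap(devices=list(descriptors), clock_hz=clock_hz)
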