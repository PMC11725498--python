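"""Closed-loop harness in simulated time.

A threshold detector watches one ephys channel; each detection triggers a
stimulator command.  The end-to-end loop latency of an event decomposes
additively as

    (block delivery time - sample production time)   downstream wait+transit
  + processing_delay_s                               host computation
  + upstream command transit                         command frame write path

with every term nonnegative.  The upstream path uses its own link
configuration whose block holds exactly one command frame, mirroring a
low-bandwidth control back-channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from tetherlab.errors import DomainError
from tetherlab.link import LinkConfig, transfer_schedule
from tetherlab.protocol import DeviceMap, Frame, HEADER_BYTES
from tetherlab.simulate import (
    EphysSimConfig,
    StimCommand,
    build_device_map,
    frames_to_ephys_counts,
    generate_ephys_frames,
    stimulator_descriptor,
)

#: encoded size of one stimulator command frame
COMMAND_FRAME_BYTES = HEADER_BYTES + StimCommand.PAYLOAD_BYTES


def default_uplink(downstream: LinkConfig) -> LinkConfig:
    """Command back-channel: one command frame per transfer."""
    return LinkConfig(
        link_bandwidth_bytes_per_s=downstream.link_bandwidth_bytes_per_s,
        block_size_bytes=COMMAND_FRAME_BYTES,
        per_transfer_overhead_s=downstream.per_transfer_overhead_s,
    )


@dataclass
class LoopConfig:
    """Detector + link parameters for one closed-loop run."""

    detect_channel: int = 0
    threshold_counts: int = -500
    refractory_s: float = 0.002
    processing_delay_s: float = 0.0
    link: LinkConfig = field(
        default_factory=lambda: LinkConfig(150e6, 8192, 0.0)
    )
    uplink: LinkConfig | None = None

    def __post_init__(self) -> None:
        if self.refractory_s < 0 or self.processing_delay_s < 0:
            raise ValueError("refractory_s and processing_delay_s must be >= 0")
        if self.threshold_counts == 0:
            raise ValueError("threshold_counts must be nonzero")
        if self.uplink is None:
            self.uplink = default_uplink(self.link)


def detect_crossings(
    frames: Sequence[Frame],
    channel: int,
    threshold: int,
    refractory_s: float,
    n_channels: int,
    clock_hz: float,
) -> np.ndarray:
    """Tick of the first sample of each threshold excursion.

    The sign of ``threshold`` selects polarity.  Re-triggers within the
    refractory window are suppressed.
    """
    if threshold == 0:
        raise DomainError("threshold must be nonzero")
    if channel >= n_channels:
        raise DomainError(f"channel {channel} out of range for {n_channels} channels")
    if len(frames) == 0:
        return np.empty(0, dtype=np.uint64)
    counts = frames_to_ephys_counts(frames, n_channels)[:, channel].astype(int)
    ticks = np.array([f.timestamp_ticks for f in frames], dtype=np.uint64)
    beyond = counts >= threshold if threshold > 0 else counts <= threshold
    onsets = np.flatnonzero(beyond & ~np.concatenate([[False], beyond[:-1]]))
    detections: list[int] = []
    refractory_ticks = refractory_s * clock_hz
    last = -math.inf
    for i in onsets:
        tick = int(ticks[i])
        if tick - last >= refractory_ticks:
            detections.append(tick)
            last = tick
    return np.asarray(detections, dtype=np.uint64)


def percentile_nearest_rank(values: Sequence[float], q: float) -> float:
    """Nearest-rank empirical percentile, q in (0, 100]."""
    if not 0 < q <= 100:
        raise DomainError("q must lie in (0, 100]")
    ordered = sorted(values)
    if not ordered:
        raise DomainError("empty sample")
    rank = max(1, math.ceil(q / 100.0 * len(ordered)))
    return float(ordered[rank - 1])


@dataclass
class LoopResult:
    latencies_s: np.ndarray
    components: dict[str, np.ndarray]
    detection_ticks: np.ndarray
    commands: list[StimCommand]
    summary: dict

    @property
    def empty(self) -> bool:
        return self.latencies_s.size == 0


def run_loop(
    ephys_config: EphysSimConfig,
    loop_config: LoopConfig,
    duration_s: float,
    spike_times: Sequence[float] | None = None,
) -> LoopResult:
    """Simulate one closed-loop session and account per-event latency."""
    clock_hz = ephys_config.sample_rate_hz  # one tick per ephys sample period
    device_map = build_device_map(
        [ephys_config.descriptor(), stimulator_descriptor()], clock_hz=clock_hz
    )
    frames, truth, _ = generate_ephys_frames(
        ephys_config, duration_s, spike_times=spike_times, clock_hz=clock_hz
    )
    delivery = np.asarray(transfer_schedule(frames, loop_config.link, device_map))
    ticks = np.array([f.timestamp_ticks for f in frames], dtype=np.uint64)

    detections = detect_crossings(
        frames,
        loop_config.detect_channel,
        loop_config.threshold_counts,
        loop_config.refractory_s,
        ephys_config.n_channels,
        clock_hz,
    )

    uplink = loop_config.uplink
    upstream_transit = uplink.block_transit_s + uplink.per_transfer_overhead_s

    downstream = []
    commands = []
    for tick in detections:
        idx = int(np.searchsorted(ticks, tick))
        produced = tick / clock_hz
        downstream.append(delivery[idx] - produced)
        onset = int(math.ceil((delivery[idx] + loop_config.processing_delay_s
                               + upstream_transit) * clock_hz))
        commands.append(StimCommand(onset_tick=onset, pulse_width_ticks=30, amplitude=0.5))
    downstream_arr = np.asarray(downstream)
    processing_arr = np.full(downstream_arr.shape, loop_config.processing_delay_s)
    upstream_arr = np.full(downstream_arr.shape, upstream_transit)
    latencies = downstream_arr + processing_arr + upstream_arr

    if latencies.size:
        summary = {
            "n_events": int(latencies.size),
            "median_s": percentile_nearest_rank(latencies, 50.0),
            "p999_s": percentile_nearest_rank(latencies, 99.9),
            "empty": False,
        }
    else:
        summary = {"n_events": 0, "median_s": None, "p999_s": None, "empty": True}

    return LoopResult(
        latencies_s=latencies,
        components={
            "downstream_s": downstream_arr,
            "processing_s": processing_arr,
            "upstream_s": upstream_arr,
        },
        detection_ticks=detections,
        commands=commands,
        summary=summary,
    )
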