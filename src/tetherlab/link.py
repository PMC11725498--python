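"""Host-side block-transfer channel model.

Data moves host-ward in fixed-size blocks; each transfer costs a fixed
overhead on top of the transit time, so block size trades real-time
responsivity against overall bandwidth.  Latency figures are expressed in
sample periods (convert to seconds with an explicit sample rate) and use the
worst case: the oldest sample in a block waits for the whole block to fill.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from tetherlab.errors import BlockOverflowError, DomainError
from tetherlab.protocol import DeviceMap, Frame, encode_frame

#: Hardware ceilings kept as named configuration constants (not computed).
PCIE_GEN2_X4_BYTES_PER_S = 2.0e9
MAX_THEORETICAL_BYTES_PER_S = 1.6e9
TETHER_BYTES_PER_S = 150.0e6


@dataclass(frozen=True)
class LinkConfig:
    """Block-transfer channel parameters.

    flush_timeout_s: when set, an underfull block is forced out this long
    after its first byte was produced (disabled by default).
    """

    link_bandwidth_bytes_per_s: float
    block_size_bytes: int
    per_transfer_overhead_s: float = 0.0
    flush_timeout_s: float | None = None

    def __post_init__(self) -> None:
        if self.link_bandwidth_bytes_per_s <= 0:
            raise DomainError("link_bandwidth_bytes_per_s must be positive")
        if self.block_size_bytes < 1:
            raise DomainError("block_size_bytes must be >= 1")
        if self.per_transfer_overhead_s < 0:
            raise DomainError("per_transfer_overhead_s must be >= 0")
        if self.flush_timeout_s is not None and self.flush_timeout_s < 0:
            raise DomainError("flush_timeout_s must be >= 0 when set")

    @property
    def block_transit_s(self) -> float:
        return self.block_size_bytes / self.link_bandwidth_bytes_per_s


def block_latency_samples(block_size_bytes: int, aggregate_sample_bytes: int) -> float:
    """Worst-case acquisition latency, in sample periods, of a full block.

    ``aggregate_sample_bytes`` is the total payload produced per sample
    period by all devices whose latency is being assessed.  The oldest
    sample in a block waits ``block / aggregate`` periods before the block
    fills and becomes transferable.
    """
    if block_size_bytes < 1 or aggregate_sample_bytes < 1:
        raise DomainError("block size and aggregate sample size must be >= 1")
    return block_size_bytes / aggregate_sample_bytes


def effective_bandwidth(config: LinkConfig) -> float:
    """Achievable throughput given per-transfer overhead.

    ``block / (block / link_bandwidth + overhead)``: monotonically
    non-decreasing in block size and asymptoting to the link bandwidth.
    """
    return config.block_size_bytes / (
        config.block_transit_s + config.per_transfer_overhead_s
    )


def channel_capacity(
    bandwidth_bytes_per_s: float, sample_rate_hz: float, bytes_per_sample: int
) -> int:
    """Number of channels at the given rate/sample size that fit the bandwidth."""
    if bandwidth_bytes_per_s <= 0 or sample_rate_hz <= 0 or bytes_per_sample <= 0:
        raise DomainError("all channel_capacity arguments must be positive")
    return math.floor(bandwidth_bytes_per_s / (sample_rate_hz * bytes_per_sample))


def transfer_schedule(
    frames: Sequence[Frame], config: LinkConfig, device_map: DeviceMap
) -> list[float]:
    """Delivery time (seconds) of each frame under greedy block packing.

    Encoded frames are packed in order into blocks of ``block_size_bytes``.
    A block is delivered at (production time of its last byte) + block
    transit + per-transfer overhead, and every frame in the block inherits
    that delivery time.  A trailing underfull block is flushed at end of
    input; with ``flush_timeout_s`` set, an underfull block is also forced
    out once its first frame has aged past the timeout.
    """
    delivery: list[float] = []
    clock_hz = device_map.clock_hz

    block_frames: list[int] = []  # indices into `frames`
    block_bytes = 0
    block_first_time = 0.0
    block_last_time = 0.0

    def close_block(forced_at: float | None = None) -> None:
        nonlocal block_frames, block_bytes
        if not block_frames:
            return
        ready = block_last_time if forced_at is None else forced_at
        done = ready + config.block_transit_s + config.per_transfer_overhead_s
        for _ in block_frames:
            delivery.append(done)
        block_frames = []
        block_bytes = 0

    prev_time = -math.inf
    for i, frame in enumerate(frames):
        size = len(encode_frame(frame, device_map))
        if size > config.block_size_bytes:
            raise BlockOverflowError(
                f"encoded frame of {size} bytes exceeds block size "
                f"{config.block_size_bytes}"
            )
        t = frame.timestamp_ticks / clock_hz
        if t < prev_time:
            raise ValueError("frames must be time-ordered")
        prev_time = t
        if (
            block_frames
            and config.flush_timeout_s is not None
            and t - block_first_time > config.flush_timeout_s
        ):
            close_block(forced_at=block_first_time + config.flush_timeout_s)
        if block_bytes + size > config.block_size_bytes:
            close_block()
        if not block_frames:
            block_first_time = t
        block_frames.append(i)
        block_bytes += size
        block_last_time = t
    close_block()

    # Delivery must be monotone even when a forced flush lands late.
    for i in range(1, len(delivery)):
        if delivery[i] < delivery[i - 1]:
            delivery[i] = delivery[i - 1]
    return delivery
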