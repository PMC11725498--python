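"""Persistence: raw frame streams, pose CSVs, ephys exports, run manifests.

Raw stream format: 4-byte ASCII magic ``ONIS`` followed by a flat binary
concatenation of encoded frames; the device map travels in a JSON sidecar at
``<path>.json``.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from tetherlab.errors import IncompleteFrameError, StreamFormatError, TetherlabError
from tetherlab.pose import PoseEstimate
from tetherlab.protocol import (
    HEADER_BYTES,
    HEADER_STRUCT,
    DeviceKind,
    DeviceMap,
    Frame,
    encode_frame,
)

STREAM_MAGIC = b"ONIS"
STREAM_SUFFIX = ".onis"

POSE_CSV_COLUMNS = [
    "time_s",
    "x_m",
    "y_m",
    "z_m",
    "yaw_deg",
    "pitch_deg",
    "roll_deg",
    "position_source",
    "residual_m",
]


def sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".json")


def write_stream(
    device_map: DeviceMap, frames: Iterable[Frame], path: str | Path
) -> int:
    """Write magic + encoded frames; device map goes to the JSON sidecar.

    Returns the number of frames written.
    """
    path = Path(path)
    n = 0
    with open(path, "wb") as fh:
        fh.write(STREAM_MAGIC)
        for frame in frames:
            fh.write(encode_frame(frame, device_map))
            n += 1
    device_map.to_json(sidecar_path(path))
    return n


def iter_stream(
    path: str | Path, device_map: DeviceMap, chunk_bytes: int = 1 << 16
) -> Iterator[Frame]:
    """Stream frames from disk with bounded memory.

    A truncated tail raises a warning reporting the frame count and stops.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(len(STREAM_MAGIC))
        if magic != STREAM_MAGIC:
            raise StreamFormatError(f"bad magic {magic!r}; expected {STREAM_MAGIC!r}")
        buf = b""
        n = 0
        while True:
            chunk = fh.read(chunk_bytes)
            if not chunk and not buf:
                return
            buf += chunk
            while len(buf) >= HEADER_BYTES:
                _, _, length = HEADER_STRUCT.unpack_from(buf)
                end = HEADER_BYTES + length
                if len(buf) < end:
                    break
                from tetherlab.protocol import decode_frame

                frame, consumed = decode_frame(buf[:end], device_map)
                buf = buf[consumed:]
                n += 1
                yield frame
            if not chunk:
                if buf:
                    warnings.warn(
                        f"truncated stream tail of {len(buf)} bytes after "
                        f"{n} complete frames",
                        stacklevel=2,
                    )
                return


def read_stream(path: str | Path) -> tuple[DeviceMap, Iterator[Frame]]:
    """Open a stream file; the device map is loaded from the sidecar."""
    device_map = DeviceMap.from_json(sidecar_path(path))
    return device_map, iter_stream(path, device_map)


def write_pose_csv(poses: Sequence[PoseEstimate], path: str | Path) -> None:
    rows = [
        {
            "time_s": p.time_s,
            "x_m": p.position[0],
            "y_m": p.position[1],
            "z_m": p.position[2],
            "yaw_deg": p.yaw_deg,
            "pitch_deg": p.pitch_deg,
            "roll_deg": p.roll_deg,
            "position_source": p.position_source,
            "residual_m": p.residual_m,
        }
        for p in poses
    ]
    pd.DataFrame(rows, columns=POSE_CSV_COLUMNS).to_csv(path, index=False)


def read_pose_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("time_s", "x_m", "y_m", "z_m") if c not in df.columns]
    if missing:
        raise StreamFormatError(f"pose CSV missing columns: {missing}")
    return df


def export_ephys_binary(
    frames: Sequence[Frame],
    device_map: DeviceMap,
    path: str | Path,
    uV_per_count: float = 1.0,
) -> Path:
    """Flat interleaved little-endian int16 export + JSON sidecar.

    Sample-major, channel-interleaved: sample0ch0, sample0ch1, ...
    """
    ephys = [
        d for d in device_map if d.kind == DeviceKind.EPHYS_SOURCE
    ]
    if not ephys:
        raise TetherlabError("nothing to export: no ephys device in map")
    desc = ephys[0]
    n_channels = desc.sample_payload_bytes // 2
    path = Path(path)
    n_samples = 0
    with open(path, "wb") as fh:
        for frame in frames:
            if frame.device_id != desc.device_id:
                continue
            fh.write(frame.payload)
            n_samples += 1
    sidecar = {
        "n_channels": n_channels,
        "sample_rate_hz": desc.nominal_rate_hz,
        "uV_per_count": uV_per_count,
        "dtype": "<i2",
        "order": "sample-major channel-interleaved",
        "n_samples": n_samples,
    }
    sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def import_ephys_binary(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read back an exported flat int16 file as (n_samples, n_channels)."""
    meta = json.loads(sidecar_path(path).read_text())
    raw = np.fromfile(path, dtype="<i2")
    return raw.reshape(-1, meta["n_channels"]), meta


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    config_dict: dict,
    seed: int,
    inputs: Sequence[str | Path] = (),
) -> Path:
    """Record everything needed to reproduce a run bit-identically."""
    import scipy

    import tetherlab

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": seed,
        "config": config_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()
        ).hexdigest(),
        "versions": {
            "tetherlab": tetherlab.__version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "input_digests": {str(p): file_digest(p) for p in inputs},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
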