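"""Lighthouse sweep-timing triangulation and IMU/optical pose fusion.

Conventions: world frame is right-handed with z up, positions in meters,
arena origin at the arena center.  A station's body frame has +x along its
optical axis and +z up; azimuth is the rotation of the swept vertical plane
about the station's z axis, elevation the rotation of the swept horizontal
plane about its y axis.  Euler angles are intrinsic yaw-pitch-roll
(Z-Y'-X''), yaw in [-180, 180) degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation, Slerp

from tetherlab.errors import DomainError, IllConditionedError, InsufficientDataError

#: Rays closer to parallel than this (degrees) are rejected as ill-conditioned.
MIN_RAY_ANGLE_DEG = 0.5


@dataclass(frozen=True)
class StationPose:
    """A fixed tracking station emitting rotating laser-plane sweeps."""

    station_id: int
    position: np.ndarray
    orientation: np.ndarray  # unit quaternion, scalar-last (x, y, z, w), world frame
    sweep_period_s: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        quat = np.asarray(self.orientation, dtype=float)
        if pos.shape != (3,):
            raise ValueError("station position must be a 3-vector")
        if quat.shape != (4,):
            raise ValueError("station orientation must be a quaternion (x, y, z, w)")
        norm = float(np.linalg.norm(quat))
        if not math.isclose(norm, 1.0, rel_tol=0, abs_tol=1e-6):
            raise ValueError("station orientation must be unit-norm")
        if self.sweep_period_s <= 0:
            raise ValueError("sweep_period_s must be positive")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "orientation", quat / norm)

    @property
    def rotation(self) -> Rotation:
        return Rotation.from_quat(self.orientation)

    @classmethod
    def looking_at(
        cls,
        station_id: int,
        position: Sequence[float],
        target: Sequence[float],
        sweep_period_s: float = 1.0 / 60.0,
    ) -> "StationPose":
        """Station at ``position`` with its optical axis aimed at ``target``."""
        position = np.asarray(position, dtype=float)
        target = np.asarray(target, dtype=float)
        x = target - position
        n = np.linalg.norm(x)
        if n == 0:
            raise ValueError("target coincides with station position")
        x = x / n
        up = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(x, up)) > 0.999:
            up = np.array([0.0, 1.0, 0.0])
        y = np.cross(up, x)
        y /= np.linalg.norm(y)
        z = np.cross(x, y)
        rot = Rotation.from_matrix(np.column_stack([x, y, z]))
        return cls(station_id, position, rot.as_quat(), sweep_period_s)


@dataclass(frozen=True)
class SweepEvent:
    """One detected laser-sweep pulse."""

    station_id: int
    axis: str  # "azimuth" | "elevation"
    pulse_offset_s: float  # within [0, sweep_period)
    sample_time_s: float

    def __post_init__(self) -> None:
        if self.axis not in ("azimuth", "elevation"):
            raise ValueError("axis must be 'azimuth' or 'elevation'")


@dataclass
class PoseEstimate:
    """Fused 6-d.f. head pose at one instant."""

    time_s: float
    position: np.ndarray
    yaw_deg: float
    pitch_deg: float
    roll_deg: float
    position_source: str = "fused"  # "optical" | "fused" | "imu_only"
    residual_m: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if not -90.0 <= self.pitch_deg <= 90.0:
            raise ValueError("pitch_deg must lie in [-90, 90]")
        if not -180.0 <= self.yaw_deg < 180.0:
            raise ValueError("yaw_deg must lie in [-180, 180)")
        if self.residual_m < 0:
            raise ValueError("residual_m must be >= 0")
        if self.position_source not in ("optical", "fused", "imu_only"):
            raise ValueError("invalid position_source")


def wrap_angle_rad(angle: float) -> float:
    """Map an angle to (-pi, pi]."""
    a = angle % (2.0 * math.pi)
    if a > math.pi:
        a -= 2.0 * math.pi
    return a


def sweep_to_angles(
    az_event: SweepEvent, el_event: SweepEvent, station: StationPose
) -> tuple[float, float]:
    """Convert a pair of sweep pulse offsets to (azimuth, elevation) radians.

    angle = 2*pi * pulse_offset / sweep_period, mapped to (-pi, pi].
    """
    if az_event.station_id != el_event.station_id:
        raise DomainError("events must come from the same station")
    if az_event.axis != "azimuth" or el_event.axis != "elevation":
        raise DomainError("expected one azimuth and one elevation event")
    period = station.sweep_period_s
    angles = []
    for ev in (az_event, el_event):
        if not 0.0 <= ev.pulse_offset_s < period:
            raise DomainError(
                f"pulse_offset_s {ev.pulse_offset_s} outside [0, {period})"
            )
        angles.append(wrap_angle_rad(2.0 * math.pi * ev.pulse_offset_s / period))
    return angles[0], angles[1]


def angles_to_direction(azimuth_rad: float, elevation_rad: float) -> np.ndarray:
    """Station-frame unit ray satisfying both swept-plane constraints.

    The vertical plane constrains atan2(y, x) = azimuth, the horizontal one
    atan2(z, x) = elevation; both require the target in front of the station
    (|angle| < pi/2).
    """
    if abs(azimuth_rad) >= math.pi / 2 or abs(elevation_rad) >= math.pi / 2:
        raise DomainError("sweep angles must lie within (-pi/2, pi/2) (target in front)")
    d = np.array([1.0, math.tan(azimuth_rad), math.tan(elevation_rad)])
    return d / np.linalg.norm(d)


def direction_to_angles(direction: np.ndarray) -> tuple[float, float]:
    """Inverse of :func:`angles_to_direction` (station frame, x > 0)."""
    x, y, z = direction
    if x <= 0:
        raise DomainError("target is behind the station")
    return math.atan2(y, x), math.atan2(z, x)


def triangulate(
    angles_by_station: Mapping[int, tuple[float, float]],
    stations: Sequence[StationPose],
) -> tuple[np.ndarray, float]:
    """Recover a world position from per-station sweep angles.

    Each station's (azimuth, elevation) defines a world-frame ray; the
    returned point is the midpoint of the shortest segment between two rays
    (the least-squares point for more than two) with the miss distance as
    residual.
    """
    by_id = {s.station_id: s for s in stations}
    origins = []
    dirs = []
    for sid, (az, el) in angles_by_station.items():
        if sid not in by_id:
            raise DomainError(f"unknown station_id {sid}")
        st = by_id[sid]
        d_station = angles_to_direction(az, el)
        dirs.append(st.rotation.apply(d_station))
        origins.append(st.position)
    if len(origins) < 2:
        raise InsufficientDataError("triangulation needs at least 2 stations")

    dirs_arr = np.asarray(dirs)
    origins_arr = np.asarray(origins)

    if len(dirs) == 2:
        cos_angle = abs(float(np.dot(dirs_arr[0], dirs_arr[1])))
        if cos_angle > math.cos(math.radians(MIN_RAY_ANGLE_DEG)):
            raise IllConditionedError(
                f"rays within {MIN_RAY_ANGLE_DEG} degrees of parallel"
            )

    # Least squares: sum_i (I - d_i d_i^T) p = sum_i (I - d_i d_i^T) o_i
    A = np.zeros((3, 3))
    b = np.zeros(3)
    projectors = []
    for o, d in zip(origins_arr, dirs_arr):
        P = np.eye(3) - np.outer(d, d)
        projectors.append(P)
        A += P
        b += P @ o
    if np.linalg.cond(A) > 1e8:
        raise IllConditionedError("triangulation system is ill-conditioned")
    point = np.linalg.solve(A, b)

    # Perpendicular distance from the solution to each ray.
    dists = [float(np.linalg.norm(P @ (point - o))) for P, o in zip(projectors, origins_arr)]
    if len(dists) == 2:
        residual = dists[0] + dists[1]  # miss distance between the two rays
    else:
        residual = float(np.sqrt(np.mean(np.square(dists))))
    return point, residual


def _yaw_pitch_roll_deg(rotations: Rotation) -> np.ndarray:
    """Intrinsic Z-Y'-X'' Euler angles in degrees, yaw mapped to [-180, 180)."""
    angles = np.atleast_2d(rotations.as_euler("ZYX", degrees=True))
    angles[:, 0] = np.where(angles[:, 0] >= 180.0, angles[:, 0] - 360.0, angles[:, 0])
    return angles


def fuse_pose(
    optical_times_s: np.ndarray,
    optical_positions: np.ndarray,
    imu_times_s: np.ndarray,
    imu_quaternions: np.ndarray,
    output_rate_hz: float = 100.0,
    max_gap_s: float = 0.2,
    optical_residuals_m: np.ndarray | None = None,
) -> list[PoseEstimate]:
    """Resample optical position and IMU orientation onto one uniform grid.

    Position is linearly interpolated, orientation spherically interpolated,
    at ``output_rate_hz`` over the overlap of the two input time ranges.
    Grid points farther than ``max_gap_s`` from any optical sample hold the
    last optical position and are flagged ``imu_only``.  Yaw always comes
    from the IMU stream (absolute sensor).
    """
    t_opt = np.asarray(optical_times_s, dtype=float)
    p_opt = np.asarray(optical_positions, dtype=float)
    t_imu = np.asarray(imu_times_s, dtype=float)
    q_imu = np.asarray(imu_quaternions, dtype=float)
    if t_opt.size == 0 or t_imu.size == 0:
        return []
    if np.any(np.diff(t_opt) < 0) or np.any(np.diff(t_imu) < 0):
        raise ValueError("input timestamps must be non-decreasing")
    if output_rate_hz <= 0:
        raise DomainError("output_rate_hz must be positive")

    t0 = max(t_opt[0], t_imu[0])
    t1 = min(t_opt[-1], t_imu[-1])
    if t1 < t0:
        return []
    n = int(math.floor((t1 - t0) * output_rate_hz)) + 1
    grid = t0 + np.arange(n) / output_rate_hz

    pos = np.column_stack([np.interp(grid, t_opt, p_opt[:, k]) for k in range(3)])
    if optical_residuals_m is not None:
        res = np.interp(grid, t_opt, np.asarray(optical_residuals_m, dtype=float))
    else:
        res = np.zeros(n)

    # Distance from each grid point to the nearest optical sample.
    idx = np.searchsorted(t_opt, grid)
    left = np.clip(idx - 1, 0, t_opt.size - 1)
    right = np.clip(idx, 0, t_opt.size - 1)
    nearest = np.minimum(np.abs(grid - t_opt[left]), np.abs(t_opt[right] - grid))
    dropout = nearest > max_gap_s

    # Hold the last in-coverage position through a dropout.
    last_idx = np.clip(np.searchsorted(t_opt, grid, side="right") - 1, 0, t_opt.size - 1)
    pos[dropout] = p_opt[last_idx[dropout]]
    res[dropout] = 0.0

    # Slerp requires strictly increasing key times; deduplicate.
    keep = np.concatenate([[True], np.diff(t_imu) > 0])
    slerp = Slerp(t_imu[keep], Rotation.from_quat(q_imu[keep]))
    angles = _yaw_pitch_roll_deg(slerp(np.clip(grid, t_imu[keep][0], t_imu[keep][-1])))

    out = []
    for i in range(n):
        out.append(
            PoseEstimate(
                time_s=float(grid[i]),
                position=pos[i],
                yaw_deg=float(angles[i, 0]),
                pitch_deg=float(np.clip(angles[i, 1], -90.0, 90.0)),
                roll_deg=float(angles[i, 2]),
                position_source="imu_only" if dropout[i] else "fused",
                residual_m=float(res[i]),
            )
        )
    return out
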