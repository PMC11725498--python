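"""Freely-moving-behavior quantification.

Pipeline (order is fixed and test-pinned): stationary-speed filter →
histogram → home-bin exclusion → normalization.  Occupancy uses a 20 x 20
grid over the arena, heading a 40 x 40 grid over yaw 0-360 deg and pitch
+/-45 deg.  Dwell distributions are summarized by Shannon entropy in bits,
optionally normalized by the uniform-distribution entropy with the same
number of included bins, with confidence intervals from a block bootstrap
over ~1-minute time bins.

Also provides the auxiliary long-recording measures (band power, activity
level) and the seeded synthetic trajectory generator used as the module's
test fixture.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from tetherlab.errors import DomainError, InsufficientDataError

log = logging.getLogger(__name__)

#: smoothed-speed cutoff below which the animal counts as stationary
DEFAULT_STATIONARY_THRESHOLD_M_S = 0.02
DEFAULT_SPEED_WINDOW_S = 0.25
DEFAULT_OCCUPANCY_BINS = (20, 20)
DEFAULT_HEADING_BINS = (40, 40)
DEFAULT_TIME_BIN_S = 60.0
DEFAULT_N_BOOT = 1000

TRAJECTORY_COLUMNS = ("time_s", "x_m", "y_m", "z_m", "yaw_deg", "pitch_deg")


# --------------------------------------------------------------------------
# arena fixture


@dataclass
class ArenaSpec:
    """Hexagonal arena with variable-height floor tiles and a home position.

    ``diameter_m`` is the vertex-to-vertex width of the regular hexagon.
    ``tile_height`` maps (x, y) to floor height in meters.
    """

    diameter_m: float = 1.6
    home_xy: tuple[float, float] = (0.55, 0.0)
    tile_height: Callable[[float, float], float] | None = None

    def __post_init__(self) -> None:
        if self.diameter_m <= 0:
            raise ValueError("diameter_m must be positive")
        if self.tile_height is None:
            self.tile_height = self._default_height

    @property
    def circumradius_m(self) -> float:
        return self.diameter_m / 2.0

    @property
    def apothem_m(self) -> float:
        return self.circumradius_m * math.sqrt(3.0) / 2.0

    def _default_height(self, x: float, y: float) -> float:
        # Smooth deterministic terrain standing in for randomized tiles.
        return 0.12 * (
            math.sin(2.0 * math.pi * x / 0.9)
            + math.cos(2.0 * math.pi * y / 0.7)
            + 2.0
        ) / 4.0 * 2.0

    def _support(self, x: float, y: float) -> float:
        # Support function of the hexagon (edge normals at 30 + 60k deg).
        best = 0.0
        for k in range(6):
            phi = math.radians(30.0 + 60.0 * k)
            best = max(best, x * math.cos(phi) + y * math.sin(phi))
        return best

    def contains(self, x: float, y: float) -> bool:
        return self._support(x, y) <= self.apothem_m + 1e-12

    def clamp(self, x: float, y: float) -> tuple[float, float]:
        """Pull a point radially inside the hexagon boundary."""
        h = self._support(x, y)
        if h <= self.apothem_m:
            return x, y
        scale = self.apothem_m / h * 0.999
        return x * scale, y * scale

    @property
    def extent(self) -> tuple[tuple[float, float], tuple[float, float]]:
        r = self.circumradius_m
        return ((-r, r), (-r, r))


# --------------------------------------------------------------------------
# histograms and entropy


@dataclass
class OccupancyGrid:
    """Binned dwell counts with exclusions applied before normalization."""

    counts: np.ndarray  # (n_bins_x, n_bins_y) nonnegative ints
    x_edges: np.ndarray
    y_edges: np.ndarray
    excluded_bins: set = field(default_factory=set)  # {(i, j), ...}
    dwell_seconds_total: float = 0.0
    empty: bool = False
    n_clipped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def included_mask(self) -> np.ndarray:
        mask = np.ones(self.counts.shape, dtype=bool)
        for ij in self.excluded_bins:
            mask[ij] = False
        return mask

    @property
    def n_included_bins(self) -> int:
        return int(self.included_mask.sum())


def _check_uniform(time_s: np.ndarray) -> float:
    dt = np.diff(time_s)
    if dt.size == 0:
        raise InsufficientDataError("need at least 2 samples")
    if np.any(dt <= 0):
        raise ValueError("time_s must be strictly increasing")
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("trajectory must be uniformly sampled")
    return float(dt[0])


def compute_speed(
    trajectory: pd.DataFrame, smoothing_window_s: float = DEFAULT_SPEED_WINDOW_S
) -> np.ndarray:
    """Boxcar-smoothed 3D speed from centered differences, m/s.

    Output length matches the input; the smoothing window is truncated at
    the edges.
    """
    if len(trajectory) < 3:
        raise InsufficientDataError("speed needs at least 3 samples")
    dt = _check_uniform(trajectory["time_s"].to_numpy())
    pos = trajectory[["x_m", "y_m", "z_m"]].to_numpy(dtype=float)
    vel = np.gradient(pos, dt, axis=0)
    speed = np.linalg.norm(vel, axis=1)
    w = max(1, int(round(smoothing_window_s / dt)))
    if w > 1:
        kernel = np.ones(w)
        speed = np.convolve(speed, kernel, mode="same") / np.convolve(
            np.ones_like(speed), kernel, mode="same"
        )
    return speed


def occupancy_histogram(
    trajectory: pd.DataFrame,
    n_bins: tuple[int, int] = DEFAULT_OCCUPANCY_BINS,
    extent: tuple[tuple[float, float], tuple[float, float]] | None = None,
    stationary_speed_threshold: float = DEFAULT_STATIONARY_THRESHOLD_M_S,
    exclude_home: bool = True,
    speed: np.ndarray | None = None,
    smoothing_window_s: float = DEFAULT_SPEED_WINDOW_S,
) -> OccupancyGrid:
    """Spatial dwell histogram over the arena.

    Stationary samples (smoothed speed below threshold) are dropped before
    binning; with ``exclude_home`` the single highest-count bin (the home
    position) is excluded from subsequent normalization.
    """
    dt = _check_uniform(trajectory["time_s"].to_numpy())
    if speed is None:
        speed = compute_speed(trajectory, smoothing_window_s)
    moving = np.asarray(speed) >= stationary_speed_threshold
    x = trajectory["x_m"].to_numpy(dtype=float)[moving]
    y = trajectory["y_m"].to_numpy(dtype=float)[moving]
    if extent is None:
        allx = trajectory["x_m"].to_numpy(dtype=float)
        ally = trajectory["y_m"].to_numpy(dtype=float)
        extent = ((allx.min(), allx.max()), (ally.min(), ally.max()))
    counts, x_edges, y_edges = np.histogram2d(x, y, bins=n_bins, range=extent)
    counts = counts.astype(int)
    grid = OccupancyGrid(
        counts=counts,
        x_edges=x_edges,
        y_edges=y_edges,
        dwell_seconds_total=float(moving.sum() * dt),
        empty=not bool(moving.any()),
    )
    if exclude_home and counts.sum() > 0:
        home_bin = np.unravel_index(int(np.argmax(counts)), counts.shape)
        grid.excluded_bins.add(tuple(int(v) for v in home_bin))
    return grid


def heading_histogram(
    trajectory: pd.DataFrame, n_bins: tuple[int, int] = DEFAULT_HEADING_BINS
) -> OccupancyGrid:
    """Heading dwell histogram: yaw 0-360 deg x pitch +/-45 deg, linear bins.

    Yaw is wrapped into [0, 360); pitch outside +/-45 deg is clipped into
    the end bins and the clipped count is logged.
    """
    _check_uniform(trajectory["time_s"].to_numpy())
    yaw = trajectory["yaw_deg"].to_numpy(dtype=float) % 360.0
    pitch = trajectory["pitch_deg"].to_numpy(dtype=float)
    n_clipped = int(np.count_nonzero((pitch < -45.0) | (pitch > 45.0)))
    if n_clipped:
        log.info("heading_histogram: clipped %d pitch samples into end bins", n_clipped)
    pitch = np.clip(pitch, -45.0, 45.0)
    counts, yaw_edges, pitch_edges = np.histogram2d(
        yaw, pitch, bins=n_bins, range=((0.0, 360.0), (-45.0, 45.0))
    )
    return OccupancyGrid(
        counts=counts.astype(int),
        x_edges=yaw_edges,
        y_edges=pitch_edges,
        n_clipped=n_clipped,
    )


def shannon_entropy_bits(grid: OccupancyGrid, normalized: bool = False) -> float:
    """H = -sum p log2 p over included bins; optionally / log2(#included bins)."""
    mask = grid.included_mask
    counts = grid.counts[mask].astype(float)
    total = counts.sum()
    if total <= 0:
        raise DomainError("entropy undefined: no mass in included bins")
    p = counts / total
    nz = p > 0
    h = float(-np.sum(p[nz] * np.log2(p[nz])))
    if normalized:
        h /= math.log2(grid.n_included_bins)
    return h


# --------------------------------------------------------------------------
# block bootstrap


@dataclass
class BootstrapResult:
    median: float
    ci_low: float
    ci_high: float
    replicates: np.ndarray
    n_boot: int
    time_bin_s: float
    seed: int


def bootstrap_entropy(
    trajectory: pd.DataFrame,
    histogram: str = "occupancy",
    time_bin_s: float = DEFAULT_TIME_BIN_S,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    normalized: bool = False,
    n_bins: tuple[int, int] | None = None,
    extent: tuple[tuple[float, float], tuple[float, float]] | None = None,
    stationary_speed_threshold: float = DEFAULT_STATIONARY_THRESHOLD_M_S,
    exclude_home: bool = True,
    smoothing_window_s: float = DEFAULT_SPEED_WINDOW_S,
) -> BootstrapResult:
    """Entropy with a 95% CI from resampling contiguous time bins.

    The trajectory is cut into bins of ``time_bin_s`` (a truncated final bin
    is dropped).  Each replicate draws bins with replacement, rebuilds the
    histogram with the stationary filter and home exclusion re-applied, and
    recomputes the (optionally normalized) entropy.  Deterministic given the
    inputs and seed.
    """
    if histogram not in ("occupancy", "heading"):
        raise DomainError("histogram must be 'occupancy' or 'heading'")
    time_s = trajectory["time_s"].to_numpy(dtype=float)
    dt = _check_uniform(time_s)
    bin_len = int(round(time_bin_s / dt))
    if bin_len < 1:
        raise DomainError("time_bin_s shorter than one sample period")
    n_time_bins = len(trajectory) // bin_len
    if n_time_bins < 2:
        raise InsufficientDataError(
            f"need >= 2 time bins of {time_bin_s} s, have {n_time_bins}"
        )

    if histogram == "occupancy":
        if n_bins is None:
            n_bins = DEFAULT_OCCUPANCY_BINS
        speed = compute_speed(trajectory, smoothing_window_s)
        keep = speed >= stationary_speed_threshold
        u = trajectory["x_m"].to_numpy(dtype=float)
        v = trajectory["y_m"].to_numpy(dtype=float)
        if extent is None:
            extent = ((u.min(), u.max()), (v.min(), v.max()))
    else:
        if n_bins is None:
            n_bins = DEFAULT_HEADING_BINS
        keep = np.ones(len(trajectory), dtype=bool)
        u = trajectory["yaw_deg"].to_numpy(dtype=float) % 360.0
        v = np.clip(trajectory["pitch_deg"].to_numpy(dtype=float), -45.0, 45.0)
        extent = ((0.0, 360.0), (-45.0, 45.0))
        exclude_home = False

    # Per-time-bin histograms; a replicate is a sum of resampled blocks.
    block_counts = np.zeros((n_time_bins, n_bins[0], n_bins[1]))
    for b in range(n_time_bins):
        sl = slice(b * bin_len, (b + 1) * bin_len)
        m = keep[sl]
        h, _, _ = np.histogram2d(u[sl][m], v[sl][m], bins=n_bins, range=extent)
        block_counts[b] = h

    rng = np.random.default_rng(seed)
    replicates = np.empty(n_boot)
    for r in range(n_boot):
        chosen = rng.integers(0, n_time_bins, size=n_time_bins)
        counts = block_counts[chosen].sum(axis=0)
        grid = OccupancyGrid(
            counts=counts.astype(int),
            x_edges=np.array([]),
            y_edges=np.array([]),
        )
        if exclude_home and counts.sum() > 0:
            grid.excluded_bins.add(
                tuple(int(k) for k in np.unravel_index(int(np.argmax(counts)), counts.shape))
            )
        replicates[r] = shannon_entropy_bits(grid, normalized=normalized)

    lo, hi = np.percentile(replicates, [2.5, 97.5])
    return BootstrapResult(
        median=float(np.median(replicates)),
        ci_low=float(lo),
        ci_high=float(hi),
        replicates=replicates,
        n_boot=n_boot,
        time_bin_s=time_bin_s,
        seed=seed,
    )


# --------------------------------------------------------------------------
# long-recording auxiliary measures


def band_power(
    sig: np.ndarray,
    sample_rate_hz: float,
    bands: Sequence[tuple[float, float]] = ((6.0, 10.0), (30.0, 50.0)),
    window_s: float = 10.0,
) -> tuple[np.ndarray, dict[tuple[float, float], np.ndarray]]:
    """Mean squared amplitude per band in non-overlapping windows.

    Zero-phase 4th-order Butterworth band-pass per band.  Returns the window
    start times and a band -> power-series mapping.
    """
    sig = np.asarray(sig, dtype=float)
    w = int(round(window_s * sample_rate_hz))
    if sig.size < w or w < 1:
        raise InsufficientDataError("signal shorter than one window")
    nyquist = sample_rate_hz / 2.0
    out: dict[tuple[float, float], np.ndarray] = {}
    n_windows = sig.size // w
    for lo, hi in bands:
        if not 0 < lo < hi < nyquist:
            raise DomainError(f"band ({lo}, {hi}) invalid for Nyquist {nyquist}")
        sos = sp_signal.butter(4, (lo, hi), btype="bandpass", fs=sample_rate_hz, output="sos")
        filtered = sp_signal.sosfiltfilt(sos, sig)
        trimmed = filtered[: n_windows * w].reshape(n_windows, w)
        out[(lo, hi)] = np.mean(trimmed**2, axis=1)
    times = np.arange(n_windows) * window_s
    return times, out


def activity_level(
    acceleration: np.ndarray,
    sample_rate_hz: float,
    output_rate_hz: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Norm of the 3D acceleration, boxcar-smoothed and decimated.

    Returns (times_s, activity) at ``output_rate_hz``.
    """
    acc = np.asarray(acceleration, dtype=float)
    if acc.ndim != 2 or acc.shape[1] != 3:
        raise ValueError("acceleration must have shape (n, 3)")
    norm = np.linalg.norm(acc, axis=1)
    w = max(1, int(round(sample_rate_hz / output_rate_hz)))
    n_out = norm.size // w
    activity = norm[: n_out * w].reshape(n_out, w).mean(axis=1)
    times = (np.arange(n_out) + 0.5) * (w / sample_rate_hz)
    return times, activity


# --------------------------------------------------------------------------
# synthetic trajectory fixture


@dataclass
class MobilityParams:
    """Locomotion statistics driving the synthetic trajectory generator."""

    median_speed_m_s: float = 0.15
    max_speed_m_s: float = 0.6
    home_dwell_fraction: float = 0.2
    heading_diffusion_rad2_s: float = 1.5
    explore_bout_mean_s: float = 30.0
    speed_log_sd: float = 0.5
    speed_tau_s: float = 2.0

    def __post_init__(self) -> None:
        if self.median_speed_m_s < 0 or self.max_speed_m_s < 0:
            raise ValueError("speeds must be nonnegative")
        if not 0.0 <= self.home_dwell_fraction < 1.0:
            raise ValueError("home_dwell_fraction must lie in [0, 1)")
        if self.heading_diffusion_rad2_s < 0:
            raise ValueError("heading_diffusion must be nonnegative")


#: presets differing ~2x in median speed, emulating a light vs. heavy tether
MOBILITY_PRESETS: dict[str, MobilityParams] = {
    "free": MobilityParams(
        median_speed_m_s=0.16,
        max_speed_m_s=0.6,
        home_dwell_fraction=0.15,
        heading_diffusion_rad2_s=1.5,
        explore_bout_mean_s=45.0,
    ),
    "restricted": MobilityParams(
        median_speed_m_s=0.08,
        max_speed_m_s=0.3,
        home_dwell_fraction=0.75,
        heading_diffusion_rad2_s=6.0,
        explore_bout_mean_s=4.0,
    ),
}


def synthetic_trajectory(
    arena: ArenaSpec,
    mobility: MobilityParams | str,
    duration_s: float,
    seed: int = 0,
    sample_rate_hz: float = 100.0,
    condition_label: str | None = None,
) -> pd.DataFrame:
    """Seeded correlated random walk in the hexagonal arena.

    Alternates exploratory bouts (heading diffusion, log-OU speed matched to
    the mobility medians) with dwell episodes at the home position; yaw
    follows the heading of motion and pitch couples to floor-height
    transitions.  Positions never leave the hexagon.
    """
    if isinstance(mobility, str):
        condition_label = condition_label or mobility
        mobility = MOBILITY_PRESETS[mobility]
    if duration_s <= 0:
        raise DomainError("duration_s must be positive")
    rng = np.random.default_rng(seed)
    dt = 1.0 / sample_rate_hz
    n = int(round(duration_s * sample_rate_hz))

    hx, hy = arena.home_xy
    if mobility.max_speed_m_s == 0 or mobility.median_speed_m_s == 0:
        # Degenerate stationary case: parked at home.
        times = np.arange(n) * dt
        z = np.array([arena.tile_height(hx, hy)] * n)
        return pd.DataFrame(
            {
                "time_s": times,
                "x_m": np.full(n, hx),
                "y_m": np.full(n, hy),
                "z_m": z,
                "yaw_deg": np.zeros(n),
                "pitch_deg": np.zeros(n),
                "condition_label": condition_label or "",
            }
        )

    f = mobility.home_dwell_fraction
    dwell_mean_s = mobility.explore_bout_mean_s * f / (1.0 - f) if f > 0 else 0.0

    heading_noise = rng.normal(
        0.0, math.sqrt(mobility.heading_diffusion_rad2_s * dt), size=n
    )
    ou_noise = rng.normal(0.0, 1.0, size=n)
    jitter_innov = rng.normal(0.0, 1e-4, size=(n, 2))

    x = np.empty(n)
    y = np.empty(n)
    yaw = np.empty(n)
    speeds = np.empty(n)

    mode = "dwell" if f > 0 else "explore"
    remaining = (
        rng.exponential(dwell_mean_s) if mode == "dwell" else rng.exponential(mobility.explore_bout_mean_s)
    )
    px, py = hx, hy
    heading = rng.uniform(-math.pi, math.pi)
    ou = 0.0  # log-speed deviation, OU process
    alpha = dt / mobility.speed_tau_s
    jx = jy = 0.0  # slow sub-threshold wander while dwelling at home

    for i in range(n):
        if mode == "dwell":
            jx += -0.05 * jx + jitter_innov[i, 0]
            jy += -0.05 * jy + jitter_innov[i, 1]
            px = hx + jx
            py = hy + jy
            speed = 0.0
            remaining -= dt
            if remaining <= 0:
                mode = "explore"
                remaining = rng.exponential(mobility.explore_bout_mean_s)
        else:
            if mode == "return":
                heading = math.atan2(hy - py, hx - px)
            else:
                heading += heading_noise[i]
                remaining -= dt
                if remaining <= 0 and f > 0:
                    mode = "return"
            ou += -alpha * ou + math.sqrt(2.0 * alpha) * mobility.speed_log_sd * ou_noise[i]
            speed = min(
                mobility.median_speed_m_s * math.exp(ou), mobility.max_speed_m_s
            )
            px += speed * dt * math.cos(heading)
            py += speed * dt * math.sin(heading)
            if not arena.contains(px, py):
                px, py = arena.clamp(px, py)
                heading = math.atan2(-py, -px) + rng.normal(0.0, 0.3)
            if mode == "return" and math.hypot(px - hx, py - hy) < 0.03:
                mode = "dwell"
                remaining = rng.exponential(dwell_mean_s) if dwell_mean_s > 0 else 0.0
        x[i] = px
        y[i] = py
        speeds[i] = speed
        yaw[i] = math.degrees(heading) % 360.0

    z = np.array([arena.tile_height(xi, yi) for xi, yi in zip(x, y)])
    dz = np.gradient(z, dt)
    horizontal = np.maximum(speeds, 1e-6)
    pitch = np.degrees(np.arctan2(dz, horizontal))
    pitch[speeds < 1e-9] = 0.0
    pitch = np.clip(pitch + rng.normal(0.0, 2.0, size=n), -45.0, 45.0)

    return pd.DataFrame(
        {
            "time_s": np.arange(n) * dt,
            "x_m": x,
            "y_m": y,
            "z_m": z,
            "yaw_deg": yaw,
            "pitch_deg": pitch,
            "condition_label": condition_label or "",
        }
    )


def behavior_report(
    trajectory: pd.DataFrame,
    arena_extent: tuple[tuple[float, float], tuple[float, float]] | None = None,
    stationary_speed_threshold: float = DEFAULT_STATIONARY_THRESHOLD_M_S,
    time_bin_s: float = DEFAULT_TIME_BIN_S,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> dict:
    """Summary metrics of one trajectory: speeds plus entropy statistics.

    Raw and normalized entropies are both reported.
    """
    speed = compute_speed(trajectory)
    occ = occupancy_histogram(
        trajectory,
        extent=arena_extent,
        stationary_speed_threshold=stationary_speed_threshold,
        speed=speed,
    )
    head = heading_histogram(trajectory)
    boot = bootstrap_entropy(
        trajectory,
        histogram="occupancy",
        time_bin_s=time_bin_s,
        n_boot=n_boot,
        seed=seed,
        normalized=True,
        extent=arena_extent,
        stationary_speed_threshold=stationary_speed_threshold,
    )
    moving = speed[speed >= stationary_speed_threshold]
    return {
        "median_speed": float(np.median(moving)) if moving.size else 0.0,
        "max_speed": float(speed.max()),
        "occupancy_entropy_bits": shannon_entropy_bits(occ),
        "occupancy_entropy_normalized": shannon_entropy_bits(occ, normalized=True),
        "heading_entropy_bits": shannon_entropy_bits(head),
        "heading_entropy_normalized": shannon_entropy_bits(head, normalized=True),
        "ci_low": boot.ci_low,
        "ci_high": boot.ci_high,
        "n_boot": n_boot,
        "seed": seed,
    }
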