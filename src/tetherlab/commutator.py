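"""Torque-free active commutation.

The controller never sees torque: it accumulates tether twist purely from
the animal's absolute heading (a wrapped angle sensor) and commands stepper
rotations to cancel it.  The bookkeeping identity

    unwrapped_heading_deg == motor_angle_deg + residual_twist_turns * 360

holds exactly at every step.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from tetherlab.errors import DomainError

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD_TURNS = 0.25
DEFAULT_STEP_DEG = 1.8  # typical stepper full-step

#: |delta| beyond this (deg) suggests the shortest-path assumption is at risk.
UNWRAP_WARN_DEG = 170.0


@dataclass(frozen=True)
class TwistState:
    """Cumulative twist bookkeeping between animal heading and motor angle."""

    unwrapped_heading_deg: float = 0.0
    motor_angle_deg: float = 0.0
    last_wrapped_heading_deg: float = 0.0

    def __post_init__(self) -> None:
        if not -180.0 <= self.last_wrapped_heading_deg < 180.0:
            raise ValueError("last_wrapped_heading_deg must lie in [-180, 180)")

    @property
    def residual_twist_turns(self) -> float:
        return (self.unwrapped_heading_deg - self.motor_angle_deg) / 360.0

    @classmethod
    def initial(cls, wrapped_heading_deg: float) -> "TwistState":
        """Start with zero twist at the given heading."""
        return cls(
            unwrapped_heading_deg=wrapped_heading_deg,
            motor_angle_deg=wrapped_heading_deg,
            last_wrapped_heading_deg=wrapped_heading_deg,
        )


def unwrap_step(prev_wrapped_deg: float, new_wrapped_deg: float) -> float:
    """Signed heading change under the shortest-path assumption, in (-180, 180].

    Valid only while the animal rotates < 180 degrees between consecutive
    samples; near-limit deltas are logged as a violated-assumption warning.
    """
    for v in (prev_wrapped_deg, new_wrapped_deg):
        if not -180.0 <= v < 180.0:
            raise DomainError(f"wrapped heading {v} outside [-180, 180)")
    delta = (new_wrapped_deg - prev_wrapped_deg) % 360.0
    if delta > 180.0:
        delta -= 360.0
    if abs(delta) >= UNWRAP_WARN_DEG:
        log.warning(
            "heading step of %.1f deg approaches the 180-deg unwrap limit", delta
        )
    return delta


def update_twist(state: TwistState, new_wrapped_heading_deg: float) -> TwistState:
    """Advance the unwrapped heading by one sensor sample (pure function)."""
    delta = unwrap_step(state.last_wrapped_heading_deg, new_wrapped_heading_deg)
    return replace(
        state,
        unwrapped_heading_deg=state.unwrapped_heading_deg + delta,
        last_wrapped_heading_deg=new_wrapped_heading_deg,
    )


def motor_policy(
    state: TwistState,
    threshold_turns: float = DEFAULT_THRESHOLD_TURNS,
    step_deg: float = DEFAULT_STEP_DEG,
    max_slew_deg_per_update: float | None = None,
) -> tuple[float, TwistState]:
    """Command a quantized cancellation rotation once twist exceeds threshold.

    Below threshold no command is issued (hysteresis: nothing happens until
    the threshold is re-exceeded).  The command magnitude is |residual| * 360
    rounded down to whole stepper steps and clipped to the slew limit; its
    sign follows the residual, so the motor always unwinds the tether.
    """
    if threshold_turns <= 0:
        raise DomainError("threshold_turns must be positive")
    if step_deg <= 0 or not math.isclose(360.0 % step_deg, 0.0, abs_tol=1e-9) and not math.isclose(
        360.0 % step_deg, step_deg, abs_tol=1e-9
    ):
        raise DomainError("step_deg must be positive and divide 360")
    residual = state.residual_twist_turns
    if abs(residual) < threshold_turns:
        return 0.0, state
    magnitude = math.floor(abs(residual) * 360.0 / step_deg + 1e-9) * step_deg
    if max_slew_deg_per_update is not None:
        magnitude = min(magnitude, max_slew_deg_per_update)
    command = math.copysign(magnitude, residual)
    return command, replace(state, motor_angle_deg=state.motor_angle_deg + command)


def run_commutation(
    wrapped_headings_deg: Sequence[float],
    times_s: Sequence[float] | None = None,
    threshold_turns: float = DEFAULT_THRESHOLD_TURNS,
    step_deg: float = DEFAULT_STEP_DEG,
    max_slew_deg_per_update: float | None = None,
) -> "np.ndarray":
    """Drive the policy over a heading series.

    Returns a structured record array with fields time_s, wrapped_deg,
    residual_turns (post-command), command_deg, motor_angle_deg.
    """
    headings = np.asarray(wrapped_headings_deg, dtype=float)
    if headings.size == 0:
        return np.empty(
            0,
            dtype=[
                ("time_s", float),
                ("wrapped_deg", float),
                ("residual_turns", float),
                ("command_deg", float),
                ("motor_angle_deg", float),
            ],
        )
    t = (
        np.asarray(times_s, dtype=float)
        if times_s is not None
        else np.arange(headings.size, dtype=float)
    )
    state = TwistState.initial(float(headings[0]))
    out = np.empty(
        headings.size,
        dtype=[
            ("time_s", float),
            ("wrapped_deg", float),
            ("residual_turns", float),
            ("command_deg", float),
            ("motor_angle_deg", float),
        ],
    )
    for i, h in enumerate(headings):
        state = update_twist(state, float(h))
        command, state = motor_policy(
            state, threshold_turns, step_deg, max_slew_deg_per_update
        )
        out[i] = (t[i], h, state.residual_twist_turns, command, state.motor_angle_deg)
    return out


def wrap_to_180(angle_deg: "np.ndarray | float"):
    """Map degrees to [-180, 180) (commutation convention)."""
    return (np.asarray(angle_deg, dtype=float) + 180.0) % 360.0 - 180.0


def wrap_to_360(angle_deg: "np.ndarray | float"):
    """Map degrees to [0, 360) (heading-histogram convention)."""
    return np.asarray(angle_deg, dtype=float) % 360.0
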