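"""Minimum-jerk submovement primitives and their summation into command trajectories.

A reach command is modelled as a start position plus a linear superposition of
discrete minimum-jerk submovements, each an error correction launched by the
controller.  The commanded goal is piecewise constant: the start position plus
the amplitudes of every submovement launched so far (the endpoint the command
stream is currently aiming at).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "Submovement",
    "CommandState",
    "Workspace",
    "InvalidSubmovementError",
    "evaluate_submovement",
    "sum_commands",
    "clamp_to_workspace",
]


class InvalidSubmovementError(ValueError):
    """Raised for a submovement with non-positive duration or non-finite amplitude."""


def _as_vec3(x) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {v.shape}")
    return v


@dataclass(frozen=True)
class Submovement:
    """One minimum-jerk correction.

    Parameters
    ----------
    t0 : float
        Onset time (s).
    td : float
        Duration (s); must be positive.
    d : array-like
        3D amplitude (cm): total displacement contributed by this submovement.
    """

    t0: float
    td: float
    d: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "d", _as_vec3(self.d))
        if not np.isfinite(self.td) or self.td <= 0:
            raise InvalidSubmovementError(f"duration must be positive, got {self.td}")
        if not np.all(np.isfinite(self.d)) or not np.isfinite(self.t0):
            raise InvalidSubmovementError("submovement parameters must be finite")


@dataclass(frozen=True)
class CommandState:
    """Commanded kinematics and goal at one instant."""

    pos: np.ndarray  # cm
    vel: np.ndarray  # cm/s
    acc: np.ndarray  # cm/s^2
    goal: np.ndarray  # cm
    t: float = 0.0  # s

    def __post_init__(self):
        for name in ("pos", "vel", "acc", "goal"):
            object.__setattr__(self, name, _as_vec3(getattr(self, name)))

    def as_state_vector(self) -> np.ndarray:
        """Stack into the 12-vector [pos, vel, acc, goal] used by the decoder."""
        return np.concatenate([self.pos, self.vel, self.acc, self.goal])


@dataclass(frozen=True)
class Workspace:
    """Axis-aligned box (cm) that commanded positions and goals must stay inside."""

    low: np.ndarray
    high: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "low", _as_vec3(self.low))
        object.__setattr__(self, "high", _as_vec3(self.high))
        if not np.all(self.low < self.high):
            raise ValueError("workspace must satisfy low < high componentwise")
        if np.max(self.high - self.low) >= 100.0:
            raise ValueError("workspace longest edge must be below 100 cm")

    @property
    def longest_edge(self) -> float:
        return float(np.max(self.high - self.low))

    def contains(self, p) -> bool:
        p = _as_vec3(p)
        return bool(np.all(p >= self.low) and np.all(p <= self.high))

    def clip(self, p) -> np.ndarray:
        return np.clip(_as_vec3(p), self.low, self.high)


def evaluate_submovement(sm: Submovement, t: float):
    """Evaluate one minimum-jerk submovement at time ``t``.

    The position profile is the quintic ``d * (6 tau^5 - 15 tau^4 + 10 tau^3)``
    with ``tau = (t - t0) / td`` on ``[t0, t0 + td]``; zero before onset and
    equal to ``d`` after completion.  Velocity and acceleration are the analytic
    first and second time derivatives, zero outside the active interval.

    Returns
    -------
    (pos, vel, acc) : tuple of 3-vectors in cm, cm/s, cm/s^2.
    """
    if not np.isfinite(t):
        raise ValueError("time must be finite")
    zero = np.zeros(3)
    if t < sm.t0:
        return zero, zero.copy(), zero.copy()
    if t > sm.t0 + sm.td:
        return sm.d.copy(), zero, zero.copy()
    tau = (t - sm.t0) / sm.td
    p = 6 * tau**5 - 15 * tau**4 + 10 * tau**3
    v = (30 * tau**4 - 60 * tau**3 + 30 * tau**2) / sm.td
    a = (120 * tau**3 - 180 * tau**2 + 60 * tau) / sm.td**2
    return sm.d * p, sm.d * v, sm.d * a


def sum_commands(active: list[Submovement], start_pos, t: float) -> CommandState:
    """Superpose submovements into the command state at time ``t``.

    Position is the start position plus every submovement's position profile;
    velocity and acceleration are the plain sums of derivatives.  The goal is
    the start position plus the full amplitude of every submovement whose onset
    has passed (the currently intended endpoint), so it is piecewise constant
    and jumps only at onsets.
    """
    start_pos = _as_vec3(start_pos)
    pos = start_pos.copy()
    vel = np.zeros(3)
    acc = np.zeros(3)
    goal = start_pos.copy()
    for sm in active:
        p, v, a = evaluate_submovement(sm, t)
        pos += p
        vel += v
        acc += a
        if t >= sm.t0:
            goal += sm.d
    return CommandState(pos=pos, vel=vel, acc=acc, goal=goal, t=t)


def clamp_to_workspace(cs: CommandState, ws: Workspace) -> CommandState:
    """Clip commanded position and goal into the workspace box.

    Velocity and acceleration pass through unchanged: they are derivatives of
    the unclamped profile, and clipping them would break the analytic
    derivative relationship without keeping anything inside the box.
    """
    return replace(cs, pos=ws.clip(cs.pos), goal=ws.clip(cs.goal))
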