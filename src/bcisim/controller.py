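"""Multiple-submovement reach controllers.

The closed-loop controller watches the discrepancy between the target and the
endpoint implied by all submovements launched so far, and fires a corrective
minimum-jerk submovement whenever that predicted error is large enough and the
refractory period since the last correction has elapsed.  Corrections
deliberately undershoot (gain < 1), mirroring the tendency of natural reaches
to undershoot and then correct.  The open-loop baseline simply holds the
position and goal commands at the target.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .submovements import CommandState, Submovement, _as_vec3

if TYPE_CHECKING:  # pragma: no cover
    from .experiments import ReachTask

__all__ = [
    "ControllerInput",
    "ControllerConfig",
    "DegeneratePlanError",
    "should_trigger",
    "plan_submovement",
    "constant_command",
    "SubmovementPolicy",
]


class DegeneratePlanError(ValueError):
    """Raised when a submovement is requested but the correction amplitude is zero."""


@dataclass(frozen=True)
class ControllerInput:
    """Everything the trigger/planning rules may look at on one timestep.

    ``predicted_endpoint`` is the command-side endpoint ``start_pos + sum(d_i)``
    over all launched submovements.  ``decoded`` carries the decoder's current
    state mean (12-vector); ``cmd_pos`` is the commanded position the
    controller last emitted.  Together they let the policy predict where the
    *decoded* position will end up once the in-flight submovements finish:
    ``decoded_pos + (predicted_endpoint - cmd_pos)``.  When ``cmd_pos`` is
    omitted the policy falls back to the command-side endpoint alone
    (equivalent to assuming ideal feedback, decoded == commanded).
    """

    start_pos: np.ndarray
    target_pos: np.ndarray
    decoded: np.ndarray
    predicted_endpoint: np.ndarray
    t: float
    n_launched: int
    last_onset: float = -np.inf
    cmd_pos: np.ndarray | None = None

    def __post_init__(self):
        for name in ("start_pos", "target_pos", "predicted_endpoint"):
            object.__setattr__(self, name, _as_vec3(getattr(self, name)))
        object.__setattr__(self, "decoded", np.asarray(self.decoded, dtype=float))
        if self.cmd_pos is not None:
            object.__setattr__(self, "cmd_pos", _as_vec3(self.cmd_pos))
        if self.n_launched < 0:
            raise ValueError("n_launched must be non-negative")

    def predicted_error(self) -> np.ndarray:
        """Target miss predicted once all launched submovements complete.

        Closed-loop form: the decoded position plus the commanded displacement
        still in flight is where the decoded position is headed; the error is
        the target minus that point.  Without ``cmd_pos`` (or a decoded state)
        this reduces to ``target - predicted_endpoint``.
        """
        if self.cmd_pos is not None and self.decoded.size >= 3:
            headed_for = self.decoded[0:3] + (self.predicted_endpoint - self.cmd_pos)
        else:
            headed_for = self.predicted_endpoint
        return self.target_pos - headed_for


@dataclass(frozen=True)
class ControllerConfig:
    """Rule parameters for the reference submovement policy.

    Defaults: a correction fires when the predicted endpoint misses the target
    by more than 1 cm and at least 0.15 s have passed since the last onset; the
    correction covers 90% of the remaining error; its duration grows with
    amplitude as 0.35 s + 0.01 s/cm, clipped to [0.2, 1.5] s.
    """

    trigger_threshold: float = 1.0  # cm
    refractory: float = 0.15  # s
    undershoot_gain: float = 0.9  # in (0, 1]
    duration_base: float = 0.35  # s
    duration_slope: float = 0.01  # s per cm of amplitude
    td_min: float = 0.2  # s
    td_max: float = 1.5  # s
    max_submovements: int = 30
    max_time: float = 3.0  # s

    def __post_init__(self):
        if not (0.0 < self.undershoot_gain <= 1.0):
            raise ValueError("undershoot_gain must be in (0, 1]")
        if self.max_submovements <= 0:
            raise ValueError("max_submovements must be positive")

    @classmethod
    def short_reach(cls, **kw) -> "ControllerConfig":
        """Stop rules for time-limited reaches: 3 s or 30 submovements."""
        return cls(max_time=3.0, max_submovements=30, **kw)

    @classmethod
    def long_reach(cls, **kw) -> "ControllerConfig":
        """Stop rules for unconstrained reaches: 30 s or 300 submovements."""
        return cls(max_time=30.0, max_submovements=300, **kw)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "ControllerConfig":
        return cls(**d)


def should_trigger(inp: ControllerInput, cfg: ControllerConfig) -> bool:
    """Decide whether a corrective submovement launches on this timestep.

    The first submovement always launches at the start of the reach; after
    that a correction requires the refractory period elapsed, the predicted
    endpoint error above threshold, and the submovement budget not exhausted.
    """
    if inp.n_launched >= cfg.max_submovements:
        return False
    if inp.n_launched == 0:
        return True
    err = float(np.linalg.norm(inp.predicted_error()))
    return (inp.t - inp.last_onset >= cfg.refractory) and err > cfg.trigger_threshold


def plan_submovement(inp: ControllerInput, cfg: ControllerConfig) -> Submovement:
    """Plan the correction: undershoot the remaining predicted error.

    Amplitude is ``undershoot_gain`` times the predicted miss of the decoded
    position (``target - predicted_endpoint`` under ideal feedback); duration
    scales with amplitude and is clipped to [td_min, td_max]; onset is now.
    """
    d = cfg.undershoot_gain * inp.predicted_error()
    mag = float(np.linalg.norm(d))
    if mag == 0.0:
        raise DegeneratePlanError("triggered with zero correction amplitude")
    td = float(np.clip(cfg.duration_base + cfg.duration_slope * mag, cfg.td_min, cfg.td_max))
    return Submovement(t0=inp.t, td=td, d=d)


def constant_command(task: "ReachTask", t: float) -> CommandState:
    """Open-loop baseline: position and goal pinned to the target, zero kinematics."""
    target = _as_vec3(task.target_pos)
    return CommandState(
        pos=target.copy(),
        vel=np.zeros(3),
        acc=np.zeros(3),
        goal=target.copy(),
        t=t,
    )


class SubmovementPolicy:
    """Adapter pairing a trigger rule with a planner.

    The default instance wraps :func:`should_trigger` / :func:`plan_submovement`;
    learned predictors with the same signatures can be substituted.
    """

    def __init__(self, cfg: ControllerConfig, trigger=should_trigger, planner=plan_submovement):
        self.cfg = cfg
        self._trigger = trigger
        self._planner = planner

    def step(self, inp: ControllerInput) -> Submovement | None:
        """Return a newly launched submovement, or None if no correction fires."""
        if self._trigger(inp, self.cfg):
            return self._planner(inp, self.cfg)
        return None
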