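"""Goal-augmented Extended Kalman Filter over a 12-D reach state.

The state is [position (3), velocity (3), acceleration (3), goal (3)].  The
linear trajectory model (transition matrix plus process-noise covariance) is
fitted by least squares to command trajectories whose goal component is the
running endpoint of all submovements launched so far.  The measurement model
is the encoder itself (the ideal-decoder assumption): expected rates are the
ensemble's saturated tuning curves evaluated at the state mean, linearized
analytically for the EKF update.  Measurement noise is diagonal and
state-dependent, matching the generative spiking model: the variance of a
rate estimate from a Poisson (or Fano-scaled normal) count in one bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .encoder import Ensemble

__all__ = [
    "STATE_DIM",
    "DecoderState",
    "TrajectoryModel",
    "DecoderNumericalError",
    "SingularFitError",
    "fit_trajectory_model",
    "init_state",
    "predict",
    "measurement_fn",
    "measurement_jacobian",
    "update",
]

STATE_DIM = 12
#: rate floor (Hz) for the measurement-noise diagonal; avoids zero variance
RATE_FLOOR = 1.0

# initial per-axis covariances, as configured: position, velocity and
# acceleration are known at start (tiny uncertainty); the goal is unknown
# (variance far exceeding the workspace extent).
INIT_COV_POS = 0.001
INIT_COV_VEL = 0.001
INIT_COV_ACC = 0.001
INIT_COV_GOAL = 1000.0


class DecoderNumericalError(RuntimeError):
    """EKF update produced a non-finite quantity; carries a diagnostic dump."""

    def __init__(self, message: str, state=None):
        super().__init__(message)
        self.state = state


class SingularFitError(ValueError):
    """Trajectory-model regression matrix is rank deficient beyond repair."""


@dataclass
class DecoderState:
    """Gaussian belief over the 12-D state: mean and covariance."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float).reshape(STATE_DIM)
        self.cov = np.asarray(self.cov, dtype=float).reshape(STATE_DIM, STATE_DIM)

    @property
    def pos(self) -> np.ndarray:
        return self.mean[0:3]

    @property
    def vel(self) -> np.ndarray:
        return self.mean[3:6]

    @property
    def acc(self) -> np.ndarray:
        return self.mean[6:9]

    @property
    def goal(self) -> np.ndarray:
        return self.mean[9:12]

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "cov": self.cov.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "DecoderState":
        return cls(mean=np.array(d["mean"]), cov=np.array(d["cov"]))


@dataclass
class TrajectoryModel:
    """Linear state-transition model: next = A @ state, residual covariance W."""

    A: np.ndarray
    W: np.ndarray

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float).reshape(STATE_DIM, STATE_DIM)
        self.W = np.asarray(self.W, dtype=float).reshape(STATE_DIM, STATE_DIM)

    def to_dict(self) -> dict:
        return {"A": self.A.tolist(), "W": self.W.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "TrajectoryModel":
        return cls(A=np.array(d["A"]), W=np.array(d["W"]))


def _symmetrize(M: np.ndarray) -> np.ndarray:
    return 0.5 * (M + M.T)


def fit_trajectory_model(training_traces, ridge: float = 1e-8) -> TrajectoryModel:
    """Least-squares fit of the one-step transition over consecutive state pairs.

    ``training_traces`` is a list of (T, 12) arrays (or sequences of
    CommandState, whose goal component is already the running submovement
    endpoint).  A minimizes the summed squared one-step prediction error with
    a tiny ridge term for conditioning; W is the maximum-likelihood covariance
    of the residuals.
    """
    mats = []
    for tr in training_traces:
        arr = np.asarray([
            s.as_state_vector() if hasattr(s, "as_state_vector") else s for s in tr
        ], dtype=float)
        if arr.ndim != 2 or arr.shape[1] != STATE_DIM:
            raise ValueError("each trace must be a (T, 12) state sequence")
        if arr.shape[0] >= 2:
            mats.append(arr)
    if len(mats) < 1 or sum(m.shape[0] - 1 for m in mats) < STATE_DIM:
        raise SingularFitError("not enough state pairs to fit a 12-D transition")
    X = np.vstack([m[:-1] for m in mats])
    Y = np.vstack([m[1:] for m in mats])
    G = X.T @ X + ridge * np.eye(STATE_DIM)
    try:
        A = np.linalg.solve(G, X.T @ Y).T
    except np.linalg.LinAlgError as exc:  # pragma: no cover - ridge prevents this
        raise SingularFitError("rank-deficient regressor matrix") from exc
    resid = Y - X @ A.T
    W = _symmetrize(resid.T @ resid / resid.shape[0])
    return TrajectoryModel(A=A, W=W)


def init_state(task, goal_prior_mean=None) -> DecoderState:
    """Initial belief: known start kinematics, uninformative goal.

    Position is set to the task's start position with per-axis covariance
    0.001; velocity and acceleration to zero with covariance 0.001; the goal
    mean defaults to the workspace origin (the centroid of the target volume
    — with per-axis covariance 1000 the exact value is inconsequential).
    """
    if goal_prior_mean is None:
        goal_prior_mean = np.zeros(3)
    mean = np.concatenate([
        np.asarray(task.start_pos, dtype=float),
        np.zeros(3),
        np.zeros(3),
        np.asarray(goal_prior_mean, dtype=float),
    ])
    cov = np.diag(
        [INIT_COV_POS] * 3 + [INIT_COV_VEL] * 3 + [INIT_COV_ACC] * 3 + [INIT_COV_GOAL] * 3
    )
    return DecoderState(mean=mean, cov=cov)


def predict(ds: DecoderState, tm: TrajectoryModel) -> DecoderState:
    """Time update: propagate mean and covariance through the trajectory model."""
    mean = tm.A @ ds.mean
    cov = _symmetrize(tm.A @ ds.cov @ tm.A.T + tm.W)
    return DecoderState(mean=mean, cov=cov)


def measurement_fn(mean, ens: Ensemble) -> np.ndarray:
    """Expected (saturated, noise-free) rate vector at a state mean.

    Identical to the encoder's pre-noise rate computation — the ideal-decoder
    assumption.
    """
    return ens.expected_rates(mean)


def measurement_jacobian(mean, ens: Ensemble) -> np.ndarray:
    """(n_neurons, 12) Jacobian of the expected rates at a state mean.

    Chain rule: the saturation derivative at each nominal rate times the
    analytic gradient of the tuning function; columns for state blocks a
    neuron is not tuned to are exactly zero.  Delegates to the measurement
    model so non-saturating (e.g. purely linear) models stay exact.
    """
    return ens.expected_jacobian(mean)


def measurement_noise_diag(expected: np.ndarray, ens: Ensemble, dt: float,
                           rate_floor: float = RATE_FLOOR) -> np.ndarray:
    """Diagonal of R: variance of a rate estimate from one noisy count bin.

    Poisson neurons: var(count)/dt^2 = rate/dt; normal-noise neurons scale by
    the Fano factor.  The floor keeps silent neurons from claiming infinite
    precision.  A measurement model may override this by providing its own
    ``noise_diag(expected, dt)``.
    """
    if hasattr(ens, "noise_diag"):
        return ens.noise_diag(expected, dt)
    base = np.maximum(expected, rate_floor) / dt
    return np.where(ens._poisson_mask, base, ens._fano * base)


def update(ds: DecoderState, observed, ens: Ensemble, dt: float) -> DecoderState:
    """EKF measurement update with Joseph-form covariance propagation.

    ``ens`` may be any measurement model exposing ``expected_rates``,
    ``nominal_rates``/``nominal_jacobian`` (via :func:`measurement_jacobian`)
    and the Poisson/Fano masks used for the noise diagonal; in the linear
    no-saturation limit this reduces exactly to the textbook Kalman update.
    """
    observed = np.asarray(observed, dtype=float)
    if len(observed) != len(ens):
        raise ValueError("observation length must equal ensemble size")
    if len(observed) == 0:
        return DecoderState(mean=ds.mean.copy(), cov=ds.cov.copy())
    expected = measurement_fn(ds.mean, ens)
    innovation = observed - expected
    if not np.all(np.isfinite(innovation)):
        raise DecoderNumericalError(
            "non-finite innovation in EKF update",
            state={"mean": ds.mean.copy(), "cov": ds.cov.copy(),
                   "observed": observed, "expected": expected},
        )
    H = measurement_jacobian(ds.mean, ens)
    R = measurement_noise_diag(expected, ens, dt)
    PHt = ds.cov @ H.T
    S = _symmetrize(H @ PHt + np.diag(R))
    try:
        cf = cho_factor(S, lower=True)
        K = cho_solve(cf, PHt.T).T
    except np.linalg.LinAlgError as exc:
        raise DecoderNumericalError(
            "innovation covariance not positive definite",
            state={"mean": ds.mean.copy(), "cov": ds.cov.copy()},
        ) from exc
    mean = ds.mean + K @ innovation
    IKH = np.eye(STATE_DIM) - K @ H
    cov = _symmetrize(IKH @ ds.cov @ IKH.T + (K * R) @ K.T)
    if not np.all(np.isfinite(mean)):
        raise DecoderNumericalError(
            "non-finite posterior mean in EKF update",
            state={"mean": mean, "cov": cov},
        )
    return DecoderState(mean=mean, cov=cov)
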