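"""Neural encoding: tuned nominal firing rates, saturation, and spiking noise.

Three tuning families are modelled:

* gain-modulated cosine (linear) tuning of position, velocity, or intended
  goal: ``f = f_base * (1 + f_depth * (preferred_direction . x))`` with the
  preferred direction given by spherical angles;
* joint position+velocity tuning: the sum of a position and a velocity cosine
  component with the overall baseline corrected to the mean of the two
  component baselines;
* radial Gaussian goal tuning: ``f = f_min + f_amp * exp(-|goal - q_pos|^2 /
  (2 q_std^2))`` around a preferred spatial location.

Nominal rates (which may be negative) pass through a fixed generalized-logistic
saturation squashing them into (0, 150) Hz, and then through spiking noise:
Poisson counts in the 30 ms bin, or a normal approximation with configurable
Fano factor, truncated at zero counts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .geometry import default_workspace

__all__ = [
    "SATURATION_CEILING",
    "LinearTuning",
    "NeuronSpec",
    "Ensemble",
    "EnsembleParams",
    "M1_COMPOSITION",
    "saturate",
    "saturate_deriv",
    "linear_tuning_rate",
    "pv_tuning_rate",
    "gaussian_goal_rate",
    "nominal_rate",
    "sample_noisy_rate",
    "sample_ensemble",
    "sample_population",
    "m1_composition_counts",
]

SATURATION_CEILING = 150.0  # Hz
_SAT_A = 9.305
_SAT_B = 0.01602
_SAT_C = 190.0
_SAT_NU = 6.015

#: M1 population mix: fraction velocity-only, position+velocity, position-only.
M1_COMPOSITION = (("velocity", 0.50), ("pos_vel", 0.37), ("position", 0.13))


def saturate(x):
    """Squash nominal rates into (0, 150) Hz with the generalized logistic curve.

    ``g(x) = 150 / (1 + 9.305 exp(-0.01602 (x + 190)))**6.015`` — monotone,
    near-identity for moderate rates, 0 for large negative and 150 Hz for
    large positive nominal input.  Computed in log space so extreme inputs do
    not overflow.
    """
    x = np.asarray(x, dtype=float)
    log_s = np.log(_SAT_A) - _SAT_B * (x + _SAT_C)
    out = SATURATION_CEILING * np.exp(-_SAT_NU * np.logaddexp(0.0, log_s))
    return out if out.ndim else float(out)

def saturate_deriv(x):
    """Analytic derivative of :func:`saturate`, overflow-safe at both tails."""
    x = np.asarray(x, dtype=float)
    log_s = np.log(_SAT_A) - _SAT_B * (x + _SAT_C)
    log_g = (
        np.log(SATURATION_CEILING * _SAT_NU * _SAT_B)
        + log_s
        - (_SAT_NU + 1.0) * np.logaddexp(0.0, log_s)
    )
    out = np.exp(log_g)
    return out if out.ndim else float(out)


def _direction(q_theta: float, q_phi: float) -> np.ndarray:
    st = np.sin(q_theta)
    return np.array([st * np.cos(q_phi), st * np.sin(q_phi), np.cos(q_theta)])


@dataclass(frozen=True)
class LinearTuning:
    """One cosine-tuned component: preferred direction angles, baseline, depth."""

    q_theta: float  # polar angle of preferred direction (rad)
    q_phi: float  # azimuth of preferred direction (rad)
    f_base: float  # baseline rate (Hz)
    f_depth: float  # fractional modulation per cm (or cm/s)

    @property
    def preferred_direction(self) -> np.ndarray:
        return _direction(self.q_theta, self.q_phi)

    def rate(self, x) -> float:
        x = np.asarray(x, dtype=float)
        return float(self.f_base * (1.0 + self.f_depth * self.preferred_direction @ x))


@dataclass(frozen=True)
class NeuronSpec:
    """Full description of one simulated neuron: tuning kind, parameters, noise.

    ``kind`` selects the tuning family; ``tuning`` holds the cosine component
    for the position / velocity / goal_linear kinds, while pos_vel neurons
    carry separate ``pos_tuning`` and ``vel_tuning`` components.  Gaussian goal
    neurons use ``q_pos`` (preferred location, cm), ``q_std`` (tuning width,
    cm), floor ``f_min`` and amplitude ``f_amp`` (Hz).
    """

    kind: str  # position | velocity | pos_vel | goal_linear | goal_gaussian
    tuning: LinearTuning | None = None
    pos_tuning: LinearTuning | None = None
    vel_tuning: LinearTuning | None = None
    q_pos: np.ndarray | None = None
    q_std: float | None = None
    f_min: float = 0.0
    f_amp: float = 100.0
    noise: str = "poisson"  # poisson | gaussian
    fano: float = 1.0

    def __post_init__(self):
        kinds = {"position", "velocity", "pos_vel", "goal_linear", "goal_gaussian"}
        if self.kind not in kinds:
            raise ValueError(f"unknown neuron kind {self.kind!r}")
        if self.noise not in {"poisson", "gaussian"}:
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.kind == "goal_gaussian":
            if self.q_pos is None or self.q_std is None:
                raise ValueError("goal_gaussian neurons need q_pos and q_std")
            if self.q_std <= 0:
                raise ValueError("q_std must be positive")
            object.__setattr__(self, "q_pos", np.asarray(self.q_pos, dtype=float))
            if self.f_amp < 0 or self.f_min < 0:
                raise ValueError("f_min and f_amp must be non-negative")
        elif self.kind == "pos_vel":
            if self.pos_tuning is None or self.vel_tuning is None:
                raise ValueError("pos_vel neurons need pos_tuning and vel_tuning")
        elif self.tuning is None:
            raise ValueError(f"{self.kind} neurons need a tuning component")


def linear_tuning_rate(x, spec: NeuronSpec) -> float:
    """Nominal rate of a cosine-tuned neuron at input ``x`` (may be negative)."""
    if spec.kind not in {"position", "velocity", "goal_linear"}:
        raise ValueError(f"linear_tuning_rate does not apply to kind {spec.kind!r}")
    return spec.tuning.rate(x)


def pv_tuning_rate(pos, vel, spec: NeuronSpec) -> float:
    """Nominal rate of a joint position+velocity neuron (baseline-corrected sum)."""
    if spec.kind != "pos_vel":
        raise ValueError("pv_tuning_rate applies only to pos_vel neurons")
    f_pos = spec.pos_tuning.rate(pos)
    f_vel = spec.vel_tuning.rate(vel)
    return f_pos + f_vel - 0.5 * (spec.pos_tuning.f_base + spec.vel_tuning.f_base)


def gaussian_goal_rate(goal, spec: NeuronSpec) -> float:
    """Nominal rate of a Gaussian goal neuron at the intended goal location."""
    if spec.kind != "goal_gaussian":
        raise ValueError("gaussian_goal_rate applies only to goal_gaussian neurons")
    r2 = float(np.sum((np.asarray(goal, dtype=float) - spec.q_pos) ** 2))
    return spec.f_min + spec.f_amp * np.exp(-r2 / (2.0 * spec.q_std**2))


def nominal_rate(spec: NeuronSpec, pos, vel, goal) -> float:
    """Dispatch to the neuron's tuning family (pre-saturation, pre-noise)."""
    if spec.kind == "position":
        return linear_tuning_rate(pos, spec)
    if spec.kind == "velocity":
        return linear_tuning_rate(vel, spec)
    if spec.kind == "goal_linear":
        return linear_tuning_rate(goal, spec)
    if spec.kind == "pos_vel":
        return pv_tuning_rate(pos, vel, spec)
    return gaussian_goal_rate(goal, spec)


def sample_noisy_rate(nominal: float, spec: NeuronSpec, dt: float, rng) -> float:
    """Draw one noisy observed rate (Hz) from a saturated nominal rate.

    Poisson neurons emit ``Poisson(nominal * dt)`` counts; Gaussian neurons a
    normal approximation with variance ``fano * nominal * dt`` truncated at
    zero counts.  The observed rate is count / dt.
    """
    if dt <= 0:
        raise ValueError("bin width dt must be positive")
    lam = nominal * dt
    if spec.noise == "poisson":
        return float(rng.poisson(lam)) / dt
    count = rng.normal(lam, np.sqrt(spec.fano * lam)) if lam > 0 else 0.0
    return max(count, 0.0) / dt


# ---------------------------------------------------------------------------
# Ensembles


@dataclass(frozen=True)
class EnsembleParams:
    """Population-level sampling distributions (configurable literature stand-ins).

    Baselines are exponential with mean ``f_base_mean``; tuning depths are
    gamma with shape ``f_depth_shape`` and mean ``f_depth_mean``.  The default
    depth mean (0.1 per cm or per cm/s) makes a 30 cm or 30 cm/s excursion
    along the preferred direction modulate the rate by ~3x baseline — with
    exponential(10 Hz) baselines that is a swing of tens of Hz at naturalistic
    reach speeds, the modulation scale reported for well-tuned M1 cells and
    the scale needed for the 30 ms-bin spike counts to carry usable kinematic
    information.  ``poisson_fraction`` of neurons get Poisson noise, the rest
    truncated-normal noise with Fano factor ``fano``.  Gaussian goal centres
    are uniform in ``goal_box``.
    """

    f_base_mean: float = 10.0  # Hz
    f_depth_shape: float = 2.0
    f_depth_mean: float = 0.1  # per cm or per cm/s
    poisson_fraction: float = 0.5
    fano: float = 1.0
    f_min: float = 0.0  # Hz, Gaussian goal floor
    f_amp: float = 100.0  # Hz, Gaussian goal amplitude
    goal_box: tuple | None = None  # ((low3), (high3)); default workspace box

    def goal_bounds(self):
        if self.goal_box is not None:
            return np.asarray(self.goal_box[0], float), np.asarray(self.goal_box[1], float)
        ws = default_workspace()
        return ws.low, ws.high


class Ensemble:
    """A fixed collection of neurons with vectorized rate evaluation.

    The linear part of every neuron's nominal rate is precomputed as an offset
    plus a row of a (n, 12) matrix acting on the state vector
    [pos, vel, acc, goal]; Gaussian goal neurons contribute a radial term on
    the goal block.  This makes both the encoder-side rate stream and the
    decoder-side measurement model (and its Jacobian) cheap.
    """

    def __init__(self, neurons: list[NeuronSpec], seed: int | None = None,
                 composition: dict[str, int] | None = None):
        self.neurons = list(neurons)
        self.seed = seed
        if composition is None:
            composition = {}
            for sp in self.neurons:
                composition[sp.kind] = composition.get(sp.kind, 0) + 1
        if sum(composition.values()) != len(self.neurons):
            raise ValueError("composition counts must sum to ensemble size")
        self.composition = composition
        self._build()

    def _build(self):
        n = len(self.neurons)
        self._offset = np.zeros(n)
        self._B = np.zeros((n, 12))
        gauss_idx, q_pos, q_std, f_min, f_amp = [], [], [], [], []
        for i, sp in enumerate(self.neurons):
            if sp.kind == "goal_gaussian":
                gauss_idx.append(i)
                q_pos.append(sp.q_pos)
                q_std.append(sp.q_std)
                f_min.append(sp.f_min)
                f_amp.append(sp.f_amp)
                self._offset[i] = sp.f_min
            elif sp.kind == "pos_vel":
                pt, vt = sp.pos_tuning, sp.vel_tuning
                self._offset[i] = 0.5 * (pt.f_base + vt.f_base)
                self._B[i, 0:3] = pt.f_base * pt.f_depth * pt.preferred_direction
                self._B[i, 3:6] = vt.f_base * vt.f_depth * vt.preferred_direction
            else:
                tun = sp.tuning
                sl = {"position": slice(0, 3), "velocity": slice(3, 6),
                      "goal_linear": slice(9, 12)}[sp.kind]
                self._offset[i] = tun.f_base
                self._B[i, sl] = tun.f_base * tun.f_depth * tun.preferred_direction
        self._gauss_idx = np.asarray(gauss_idx, dtype=int)
        self._gauss_qpos = np.asarray(q_pos, dtype=float).reshape(-1, 3)
        self._gauss_inv2s2 = (
            1.0 / (2.0 * np.asarray(q_std, dtype=float) ** 2)
            if q_std else np.empty(0)
        )
        self._gauss_famp = np.asarray(f_amp, dtype=float)
        self._poisson_mask = np.array([sp.noise == "poisson" for sp in self.neurons],
                                      dtype=bool)
        self._fano = np.array([sp.fano for sp in self.neurons], dtype=float)

    def __len__(self) -> int:
        return len(self.neurons)

    def nominal_rates(self, state12) -> np.ndarray:
        """Pre-saturation nominal rates at a 12-D state [pos, vel, acc, goal]."""
        s = np.asarray(state12, dtype=float)
        rates = self._offset + self._B @ s
        if self._gauss_idx.size:
            diff = s[9:12] - self._gauss_qpos
            r2 = np.einsum("ij,ij->i", diff, diff)
            rates[self._gauss_idx] += self._gauss_famp * np.exp(-r2 * self._gauss_inv2s2)
        return rates

    def expected_rates(self, state12) -> np.ndarray:
        """Saturated (noise-free) rates: what the decoder's ideal model predicts."""
        return saturate(self.nominal_rates(state12))

    def nominal_jacobian(self, state12) -> np.ndarray:
        """(n, 12) gradient of the nominal rates with respect to the state."""
        J = self._B.copy()
        if self._gauss_idx.size:
            s = np.asarray(state12, dtype=float)
            diff = s[9:12] - self._gauss_qpos
            r2 = np.einsum("ij,ij->i", diff, diff)
            coef = -2.0 * self._gauss_inv2s2 * self._gauss_famp * np.exp(-r2 * self._gauss_inv2s2)
            J[self._gauss_idx, 9:12] += coef[:, None] * diff
        return J

    def expected_jacobian(self, state12) -> np.ndarray:
        """(n, 12) Jacobian of the saturated rates: chain rule through saturation."""
        nominal = self.nominal_rates(state12)
        return saturate_deriv(nominal)[:, None] * self.nominal_jacobian(state12)

    def sample_rates(self, expected: np.ndarray, dt: float, rng) -> np.ndarray:
        """Vectorized spiking noise on a vector of saturated rates (Hz)."""
        if dt <= 0:
            raise ValueError("bin width dt must be positive")
        lam = np.asarray(expected, dtype=float) * dt
        counts = np.empty_like(lam)
        pm = self._poisson_mask
        if pm.any():
            counts[pm] = rng.poisson(lam[pm])
        if (~pm).any():
            mu = lam[~pm]
            counts[~pm] = np.maximum(rng.normal(mu, np.sqrt(self._fano[~pm] * mu)), 0.0)
        return counts / dt

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        def spec_dict(sp: NeuronSpec) -> dict:
            d = {"kind": sp.kind, "noise": sp.noise, "fano": sp.fano}
            if sp.tuning is not None:
                d["tuning"] = asdict(sp.tuning)
            if sp.pos_tuning is not None:
                d["pos_tuning"] = asdict(sp.pos_tuning)
                d["vel_tuning"] = asdict(sp.vel_tuning)
            if sp.kind == "goal_gaussian":
                d.update(q_pos=sp.q_pos.tolist(), q_std=sp.q_std,
                         f_min=sp.f_min, f_amp=sp.f_amp)
            return d

        return {
            "seed": self.seed,
            "composition": self.composition,
            "neurons": [spec_dict(sp) for sp in self.neurons],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Ensemble":
        neurons = []
        for nd in d["neurons"]:
            nd = dict(nd)
            for key in ("tuning", "pos_tuning", "vel_tuning"):
                if key in nd:
                    nd[key] = LinearTuning(**nd[key])
            neurons.append(NeuronSpec(**nd))
        return cls(neurons, seed=d.get("seed"), composition=dict(d.get("composition") or {}) or None)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "Ensemble":
        return cls.from_dict(json.loads(s))


def m1_composition_counts(n: int) -> dict[str, int]:
    """Split n M1 neurons 50/37/13% into velocity / pos_vel / position kinds.

    Largest-remainder rounding; remainder ties go to velocity, then pos_vel,
    then position.
    """
    quotas = [(kind, n * frac) for kind, frac in M1_COMPOSITION]
    counts = {kind: int(np.floor(q)) for kind, q in quotas}
    short = n - sum(counts.values())
    remainders = sorted(
        ((q - np.floor(q), -i, kind) for i, (kind, q) in enumerate(quotas)),
        reverse=True,
    )
    for _, _, kind in remainders[:short]:
        counts[kind] += 1
    return counts


def _sample_direction_angles(rng) -> tuple[float, float]:
    # area-uniform on the sphere: cos(theta) ~ U(-1, 1), phi ~ U(0, 2*pi)
    z = rng.uniform(-1.0, 1.0)
    return float(np.arccos(z)), float(rng.uniform(0.0, 2.0 * np.pi))


def _sample_linear_tuning(params: EnsembleParams, rng) -> LinearTuning:
    q_theta, q_phi = _sample_direction_angles(rng)
    f_base = rng.exponential(params.f_base_mean)
    f_depth = rng.gamma(params.f_depth_shape,
                        params.f_depth_mean / params.f_depth_shape)
    return LinearTuning(q_theta=q_theta, q_phi=q_phi, f_base=f_base, f_depth=f_depth)


def _assign_noise(n: int, params: EnsembleParams, rng) -> list[str]:
    n_poisson = int(round(n * params.poisson_fraction))
    labels = np.array(["poisson"] * n_poisson + ["gaussian"] * (n - n_poisson))
    rng.shuffle(labels)
    return labels.tolist()


def _build_neurons(kinds: list[str], goal_kind: str, q_std: float,
                   params: EnsembleParams, rng) -> list[NeuronSpec]:
    glow, ghigh = params.goal_bounds()
    noise = _assign_noise(len(kinds), params, rng)
    neurons = []
    for kind, nz in zip(kinds, noise):
        if kind == "pos_vel":
            sp = NeuronSpec(kind="pos_vel",
                            pos_tuning=_sample_linear_tuning(params, rng),
                            vel_tuning=_sample_linear_tuning(params, rng),
                            noise=nz, fano=params.fano)
        elif kind == "goal_gaussian":
            sp = NeuronSpec(kind="goal_gaussian",
                            q_pos=rng.uniform(glow, ghigh),
                            q_std=q_std, f_min=params.f_min, f_amp=params.f_amp,
                            noise=nz, fano=params.fano)
        else:
            sp = NeuronSpec(kind=kind, tuning=_sample_linear_tuning(params, rng),
                            noise=nz, fano=params.fano)
        neurons.append(sp)
    return neurons


def sample_ensemble(n_m1: int, n_goal: int, goal_kind: str = "goal_gaussian",
                    q_std: float = 20.0, params: EnsembleParams | None = None,
                    rng=None, seed: int | None = None) -> Ensemble:
    """Sample a mixed ensemble: an M1 subset (50/37/13 velocity / pos_vel /
    position) plus a goal-tuned subset of the requested kind.

    Preferred directions are area-uniform on the sphere; baselines and depths
    come from the exponential/gamma families in ``params``; Gaussian goal
    centres are uniform in the goal box.
    """
    if n_m1 < 0 or n_goal < 0:
        raise ValueError("neuron counts must be non-negative")
    if goal_kind not in {"goal_gaussian", "goal_linear"}:
        raise ValueError(f"goal_kind must be goal_gaussian or goal_linear, got {goal_kind!r}")
    params = params or EnsembleParams()
    if rng is None:
        rng = np.random.default_rng(seed)
    counts = m1_composition_counts(n_m1)
    kinds = (["velocity"] * counts["velocity"] + ["pos_vel"] * counts["pos_vel"]
             + ["position"] * counts["position"] + [goal_kind] * n_goal)
    neurons = _build_neurons(kinds, goal_kind, q_std, params, rng)
    composition = {k: v for k, v in counts.items() if v} if n_m1 else {}
    if n_goal:
        composition[goal_kind] = n_goal
    return Ensemble(neurons, seed=seed, composition=composition or None)


def sample_population(kind: str, n: int, q_std: float = 20.0,
                      params: EnsembleParams | None = None, rng=None,
                      seed: int | None = None) -> Ensemble:
    """Sample a single-kind population (e.g. 50 velocity-only neurons)."""
    if n < 0:
        raise ValueError("neuron count must be non-negative")
    params = params or EnsembleParams()
    if rng is None:
        rng = np.random.default_rng(seed)
    neurons = _build_neurons([kind] * n, kind, q_std, params, rng)
    return Ensemble(neurons, seed=seed, composition={kind: n} if n else None)
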