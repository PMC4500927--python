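"""Reach tasks, closed-loop simulation, and the two neuron-comparison analyses.

Analysis 1 crosses the number of M1 (position/velocity-mixed) neurons with the
number of goal-tuned neurons on short (3 s) reaches.  Analysis 2 compares
single-kind populations (position-only, velocity-only, linear goal, Gaussian
goal at several tuning widths) on long reaches, both under the submovement
controller and under a constant command pinned at the target.  Every reach is
scored with the MATR dwell metric on the decoded position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import decoder as dec
from .controller import (
    ControllerConfig,
    ControllerInput,
    SubmovementPolicy,
    constant_command,
)
from .encoder import Ensemble, EnsembleParams, sample_ensemble, sample_population
from .geometry import default_start_pos, default_target_volume, default_workspace
from .metrics import DistanceTrace, aggregate, matr, movement_time
from .submovements import CommandState, Workspace, clamp_to_workspace, sum_commands

__all__ = [
    "DT",
    "ReachTask",
    "SimulationTrace",
    "generate_targets",
    "open_loop_commands",
    "fit_reference_trajectory_model",
    "run_reach",
    "distance_trace",
    "run_analysis1",
    "run_analysis2",
    "matr_tp_table",
]

DT = 0.03  # s, simulation step size
#: shortest simulated duration (s) that still admits one dwell window plus
#: the excluded first/last half second of the MATR metric
MIN_TRACE_TIME = 2.0


@dataclass(frozen=True)
class ReachTask:
    """One reach: start, target, and stop rules."""

    start_pos: np.ndarray
    target_pos: np.ndarray
    max_time: float = 3.0  # s
    max_submovements: int = 30
    dt: float = DT

    def __post_init__(self):
        object.__setattr__(self, "start_pos", np.asarray(self.start_pos, dtype=float))
        object.__setattr__(self, "target_pos", np.asarray(self.target_pos, dtype=float))
        if self.max_time <= MIN_TRACE_TIME:
            raise ValueError(f"max_time must exceed {MIN_TRACE_TIME} s for the dwell metric")


@dataclass
class SimulationTrace:
    """Per-timestep record of one simulated reach."""

    task: ReachTask
    t: np.ndarray  # (T,)
    commanded: np.ndarray  # (T, 12) clamped command states
    decoded_mean: np.ndarray  # (T, 12) posterior means
    decoded_var: np.ndarray  # (T, 12) posterior variances (cov diagonal)
    expected_rates: np.ndarray | None  # (T, n) saturated pre-noise rates
    observed_rates: np.ndarray | None  # (T, n) noisy rates
    submovements: list
    t_stop: float
    aborted: bool = False


def generate_targets(n: int = 33, volume: Workspace | None = None,
                     start_pos=None, rng=None, seed: int | None = None) -> np.ndarray:
    """Quasi-uniform targets in the target volume (stratified random sampling).

    The volume is sliced into ceil(n/3) strata along its longest axis with
    (up to) three uniform draws per stratum, spreading targets across the
    volume while keeping their distance-to-start statistics close to the
    reference reach set (mean near 48 cm, range roughly 28-69 cm for the
    default 33-target geometry).  The same fixed-seed set is reused across
    all parameter combinations of an analysis.
    """
    if n < 1:
        raise ValueError("need at least one target")
    volume = volume or default_target_volume()
    if rng is None:
        rng = np.random.default_rng(seed)
    axis = int(np.argmax(volume.high - volume.low))
    n_strata = int(np.ceil(n / 3))
    edges = np.linspace(volume.low[axis], volume.high[axis], n_strata + 1)
    targets = []
    for i in range(n):
        s = i % n_strata
        lo, hi = volume.low.copy(), volume.high.copy()
        lo[axis], hi[axis] = edges[s], edges[s + 1]
        targets.append(rng.uniform(lo, hi))
    return np.asarray(targets)


def _policy_input(task: ReachTask, decoded_mean, endpoint, t, n_launched, last_onset,
                  cmd_pos=None):
    return ControllerInput(
        start_pos=task.start_pos, target_pos=task.target_pos,
        decoded=decoded_mean, predicted_endpoint=endpoint,
        t=t, n_launched=n_launched, last_onset=last_onset, cmd_pos=cmd_pos,
    )


def open_loop_commands(task: ReachTask, cfg: ControllerConfig,
                       ws: Workspace | None = None) -> np.ndarray:
    """Noiseless command trajectory of one controller-driven reach.

    The controller runs with ideal feedback (decoded state = commanded state)
    and no encoder/decoder in the loop; used to build training trajectories
    for the decoder's linear trajectory model.  Returns a (T, 12) state array
    whose goal component is the running submovement endpoint.
    """
    ws = ws or default_workspace()
    policy = SubmovementPolicy(cfg)
    active: list = []
    endpoint = task.start_pos.copy()
    last_onset = -np.inf
    n_steps = int(round(task.max_time / task.dt))
    states = np.empty((n_steps, dec.STATE_DIM))
    cs = clamp_to_workspace(sum_commands([], task.start_pos, 0.0), ws)
    for k in range(n_steps):
        t = k * task.dt
        inp = _policy_input(task, cs.as_state_vector(), endpoint, t, len(active),
                            last_onset, cmd_pos=cs.pos)
        sm = policy.step(inp)
        if sm is not None:
            active.append(sm)
            endpoint = endpoint + sm.d
            last_onset = t
        cs = clamp_to_workspace(sum_commands(active, task.start_pos, t), ws)
        states[k] = cs.as_state_vector()
    return states


#: per-state-block std of the variability added to training trajectories
#: (cm, cm/s, cm/s^2, cm): emulates the measurement and submovement-
#: decomposition noise of recorded reaches; a perfectly noiseless training set
#: yields a degenerate process-noise estimate (zero position/velocity
#: residuals) that freezes the filter
TRAINING_NOISE_STD = (0.1, 1.0, 10.0, 0.5)
#: samples kept after the last training submovement ends (~0.33 s of hold)
TRAINING_HOLD_STEPS = 11


def fit_reference_trajectory_model(targets, start_pos=None,
                                   cfg: ControllerConfig | None = None,
                                   ws: Workspace | None = None,
                                   dt: float = DT,
                                   noise_std=TRAINING_NOISE_STD,
                                   rng=None, seed: int = 1234) -> dec.TrajectoryModel:
    """Fit the decoder's trajectory model on a synthetic training reach set.

    Training reaches are short (3 s cap) controller-driven point-to-point
    movements with ideal feedback, truncated shortly after the movement ends
    so parked samples do not dominate the regression, with small additive
    kinematic variability standing in for the noise of experimentally
    recorded reaches.  The same short-reach training set serves every
    analysis.
    """
    start_pos = default_start_pos() if start_pos is None else np.asarray(start_pos, float)
    cfg = cfg or ControllerConfig.short_reach()
    train_cfg = ControllerConfig.short_reach(
        trigger_threshold=cfg.trigger_threshold, refractory=cfg.refractory,
        undershoot_gain=cfg.undershoot_gain, duration_base=cfg.duration_base,
        duration_slope=cfg.duration_slope)
    if rng is None:
        rng = np.random.default_rng(seed)
    traces = []
    for tp in np.asarray(targets, dtype=float):
        task = ReachTask(start_pos=start_pos, target_pos=tp,
                         max_time=train_cfg.max_time,
                         max_submovements=train_cfg.max_submovements, dt=dt)
        st = open_loop_commands(task, train_cfg, ws)
        moving = np.linalg.norm(st[:, 3:6], axis=1) > 1e-9
        k_end = int(np.flatnonzero(moving)[-1]) if moving.any() else st.shape[0] - 1
        st = st[:min(k_end + TRAINING_HOLD_STEPS, st.shape[0])].copy()
        if noise_std is not None:
            st += rng.normal(0.0, np.repeat(noise_std, 3), size=st.shape)
        traces.append(st)
    return dec.fit_trajectory_model(traces)


def run_reach(task: ReachTask, ens: Ensemble, policy: SubmovementPolicy | None,
              tm: dec.TrajectoryModel, rng, controller: str = "msc",
              record_rates: bool = False) -> SimulationTrace:
    """Simulate one closed-loop reach at 30 ms steps.

    Each step: (1) the controller reads the previous decoded state and may
    launch a corrective submovement; (2) submovements are summed and clamped
    into the workspace; (3) the ensemble emits noisy rates for the commanded
    state; (4) the EKF runs its predict/update cycle.  The loop stops at
    ``task.max_time``, or once the submovement budget is exhausted (but never
    before the minimum duration the dwell metric needs).  ``controller`` is
    "msc" for the submovement policy or "constant" for target-pinned commands.

    A decoder numerical failure aborts the reach; the partial trace is
    returned with ``aborted=True``.
    """
    ws = default_workspace()
    n_steps = int(round(task.max_time / task.dt))
    n_neurons = len(ens)
    ds = dec.init_state(task)
    active: list = []
    endpoint = task.start_pos.copy()
    last_onset = -np.inf
    t_grid = np.arange(n_steps) * task.dt
    commanded = np.empty((n_steps, dec.STATE_DIM))
    decoded_mean = np.empty((n_steps, dec.STATE_DIM))
    decoded_var = np.empty((n_steps, dec.STATE_DIM))
    exp_rates = np.empty((n_steps, n_neurons)) if record_rates else None
    obs_rates = np.empty((n_steps, n_neurons)) if record_rates else None
    aborted = False
    k_stop = n_steps
    cmd_pos_prev = task.start_pos.copy()
    for k in range(n_steps):
        t = t_grid[k]
        if controller == "msc":
            inp = _policy_input(task, ds.mean, endpoint, t, len(active), last_onset,
                                cmd_pos=cmd_pos_prev)
            sm = policy.step(inp)
            if sm is not None:
                active.append(sm)
                endpoint = endpoint + sm.d
                last_onset = t
            cs = clamp_to_workspace(sum_commands(active, task.start_pos, t), ws)
        elif controller == "constant":
            cs = clamp_to_workspace(constant_command(task, t), ws)
        else:
            raise ValueError(f"unknown controller {controller!r}")
        cmd_pos_prev = cs.pos
        state = cs.as_state_vector()
        commanded[k] = state
        expected = ens.expected_rates(state)
        observed = ens.sample_rates(expected, task.dt, rng)
        if record_rates:
            exp_rates[k] = expected
            obs_rates[k] = observed
        try:
            ds = dec.predict(ds, tm)
            ds = dec.update(ds, observed, ens, task.dt)
        except dec.DecoderNumericalError:
            aborted = True
            k_stop = k + 1
            break
        decoded_mean[k] = ds.mean
        decoded_var[k] = np.diag(ds.cov)
        if (controller == "msc" and len(active) >= task.max_submovements
                and t + task.dt >= MIN_TRACE_TIME):
            k_stop = k + 1
            break
    t_stop = k_stop * task.dt
    sl = slice(0, k_stop if not aborted else k_stop - 1)
    return SimulationTrace(
        task=task, t=t_grid[sl], commanded=commanded[sl],
        decoded_mean=decoded_mean[sl], decoded_var=decoded_var[sl],
        expected_rates=exp_rates[sl] if record_rates else None,
        observed_rates=obs_rates[sl] if record_rates else None,
        submovements=active, t_stop=t_stop, aborted=aborted,
    )


def distance_trace(trace: SimulationTrace) -> DistanceTrace:
    """Distance from decoded position to the target centre, per timestep."""
    d = np.linalg.norm(trace.decoded_mean[:, 0:3] - trace.task.target_pos, axis=1)
    return DistanceTrace(t=trace.t, dist=d, t_stop=trace.t_stop)


# ---------------------------------------------------------------------------
# Analyses


def _reach_rows(meta: dict, targets, start_pos, ens, policy, tm, rng,
                cfg: ControllerConfig, controller: str, radii=None) -> list[dict]:
    rows = []
    for ti, tp in enumerate(targets):
        task = ReachTask(start_pos=start_pos, target_pos=tp,
                         max_time=cfg.max_time, max_submovements=cfg.max_submovements)
        trace = run_reach(task, ens, policy, tm, rng, controller=controller)
        row = dict(meta)
        row.update(
            target_id=ti,
            target_distance_cm=float(np.linalg.norm(tp - start_pos)),
            origin_distance_cm=float(np.linalg.norm(tp)),
            aborted=trace.aborted,
            n_submovements=len(trace.submovements),
        )
        if trace.aborted:
            row.update(matr_cm=float("nan"), movement_time_s=float("nan"))
        else:
            dtr = distance_trace(trace)
            m = matr(dtr)
            # time at which the optimal dwell window was reached (dwell excluded)
            row.update(matr_cm=m, movement_time_s=movement_time(dtr, m))
            for r in radii or ():
                mt = movement_time(dtr, r)
                row[f"time_at_{r:g}cm_s"] = float("nan") if mt is None else mt
        rows.append(row)
    return rows


def run_analysis1(n_goal_grid, n_pv_grid, goal_kind: str = "goal_gaussian",
                  q_std: float = 20.0, n_paramsets: int = 30, n_targets: int = 33,
                  seed: int = 0, params: EnsembleParams | None = None,
                  cfg: ControllerConfig | None = None,
                  progress=None) -> pd.DataFrame:
    """Cross goal-neuron and M1-neuron counts on short (3 s) reaches.

    For every (n_goal, n_pv) cell, ``n_targets`` reaches are simulated per
    neuron parameter set; the M1 subset uses the 50/37/13 velocity / pos+vel /
    position composition.  Returns one tidy row per reach.
    """
    cfg = cfg or ControllerConfig.short_reach()
    params = params or EnsembleParams()
    n_goal_grid = list(n_goal_grid)
    n_pv_grid = list(n_pv_grid)
    ss = np.random.SeedSequence(seed)
    targets_seed, tm_seed, *cell_seeds = ss.spawn(2 + n_paramsets)
    start = default_start_pos()
    targets = generate_targets(n_targets, rng=np.random.default_rng(targets_seed))
    tm = fit_reference_trajectory_model(targets, start, cfg,
                                        rng=np.random.default_rng(tm_seed))
    policy = SubmovementPolicy(cfg)
    rows = []
    for p, pseed in enumerate(cell_seeds):
        child = pseed.spawn(len(n_goal_grid) * len(n_pv_grid) * 2)
        ci = 0
        for n_goal in n_goal_grid:
            for n_pv in n_pv_grid:
                ens_rng = np.random.default_rng(child[ci]); ci += 1
                sim_rng = np.random.default_rng(child[ci]); ci += 1
                ens = sample_ensemble(n_pv, n_goal, goal_kind=goal_kind,
                                      q_std=q_std, params=params, rng=ens_rng)
                meta = {"analysis": 1, "n_goal": n_goal, "n_pv": n_pv,
                        "goal_kind": goal_kind, "q_std": q_std,
                        "controller": "msc", "paramset": p}
                rows.extend(_reach_rows(meta, targets, start, ens, policy, tm,
                                        sim_rng, cfg, "msc"))
                if progress is not None:
                    progress(p, n_goal, n_pv)
    return pd.DataFrame(rows)


#: analysis-2 population conditions: (label, neuron kind, Gaussian width or None)
ANALYSIS2_TYPES = (
    ("position", "position", None),
    ("velocity", "velocity", None),
    ("goal_linear", "goal_linear", None),
    ("gg10", "goal_gaussian", 10.0),
    ("gg20", "goal_gaussian", 20.0),
    ("gg30", "goal_gaussian", 30.0),
    ("gg40", "goal_gaussian", 40.0),
)


def run_analysis2(types=ANALYSIS2_TYPES, n_neurons: int = 50, n_paramsets: int = 30,
                  n_targets: int = 33, seed: int = 0,
                  params: EnsembleParams | None = None,
                  cfg: ControllerConfig | None = None,
                  controllers=("msc", "constant"), radii=None,
                  progress=None) -> pd.DataFrame:
    """Compare single-kind populations when movement time is not limiting.

    Each condition simulates ``n_neurons`` neurons of one kind on long
    reaches, under the submovement controller and (except for velocity
    tuning, which a constant command cannot drive to the target) under the
    constant target-pinned command.  Returns one tidy row per reach,
    including the movement time at which the reach's own MATR was attained
    and, when ``radii`` is given, the movement time to each listed target
    radius (NaN where unattained) for radius-vs-time curves.
    """
    cfg = cfg or ControllerConfig.long_reach()
    params = params or EnsembleParams()
    types = list(types)
    ss = np.random.SeedSequence(seed)
    targets_seed, tm_seed, *pseeds = ss.spawn(2 + n_paramsets)
    start = default_start_pos()
    targets = generate_targets(n_targets, rng=np.random.default_rng(targets_seed))
    tm = fit_reference_trajectory_model(targets, start, cfg,
                                        rng=np.random.default_rng(tm_seed))
    policy = SubmovementPolicy(cfg)
    rows = []
    for p, pseed in enumerate(pseeds):
        child = pseed.spawn(len(types) * (1 + len(controllers)))
        ci = 0
        for label, kind, q_std in types:
            ens_rng = np.random.default_rng(child[ci]); ci += 1
            ens = sample_population(kind, n_neurons, q_std=q_std or 20.0,
                                    params=params, rng=ens_rng)
            for controller in controllers:
                sim_rng = np.random.default_rng(child[ci]); ci += 1
                if controller == "constant" and kind == "velocity":
                    continue  # constant commanded velocities cannot reach the target
                meta = {"analysis": 2, "neuron_type": label, "kind": kind,
                        "q_std": q_std, "n_neurons": n_neurons,
                        "controller": controller, "paramset": p}
                rows.extend(_reach_rows(meta, targets, start, ens, policy, tm,
                                        sim_rng, cfg, controller, radii=radii))
                if progress is not None:
                    progress(p, label, controller)
    return pd.DataFrame(rows)


def matr_tp_table(df: pd.DataFrame, group_cols) -> pd.DataFrame:
    """Collapse per-reach rows into MATR-TP (and 95% CI) per condition group."""
    out = []
    for key, g in df.groupby(list(group_cols), dropna=False):
        key = key if isinstance(key, tuple) else (key,)
        M = g.pivot_table(index="target_id", columns="paramset", values="matr_cm")
        res = aggregate(M.to_numpy())
        out.append({**dict(zip(group_cols, key)), "matr_tp_cm": res.matr_tp,
                    "ci_lo": res.ci95[0], "ci_hi": res.ci95[1],
                    "n_aborted": int(g["aborted"].sum())})
    return pd.DataFrame(out)
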