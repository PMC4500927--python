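"""Dwell-based reach performance metrics.

The headline metric is the Minimum Attainable Target Radius (MATR): the
smallest target radius such that the decoded position enters and stays inside
it for a continuous 1 s dwell window.  On the sampled grid this is the minimum
over admissible window centres of the within-window maximum of the distance-
to-target trace; the first and last half second of each simulation are
excluded from the set of admissible centres.  Aggregations average MATR over
targets (MATR-T) and additionally over neuron parameter sets (MATR-TP, with a
Student-t 95% confidence interval across parameter sets).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

__all__ = [
    "DistanceTrace",
    "MATRResult",
    "UndefinedMATRError",
    "matr",
    "movement_time",
    "aggregate",
    "radius_vs_time",
    "distance_regression",
]

_EPS = 1e-9


class UndefinedMATRError(ValueError):
    """Trace too short to contain one dwell window plus the edge exclusions."""


@dataclass(frozen=True)
class DistanceTrace:
    """Distance-to-target samples on a uniform time grid, with a stop time."""

    t: np.ndarray  # s, uniform spacing (30 ms by default)
    dist: np.ndarray  # cm, >= 0
    t_stop: float  # s

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        d = np.asarray(self.dist, dtype=float)
        if t.ndim != 1 or t.shape != d.shape:
            raise ValueError("t and dist must be matching 1-D arrays")
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            raise ValueError("t must be strictly increasing")
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "dist", d)

    @property
    def step(self) -> float:
        return float(self.t[1] - self.t[0])


@dataclass(frozen=True)
class MATRResult:
    """Aggregated MATR: per-target values, per-paramset means, and grand mean."""

    per_target: np.ndarray  # (targets, paramsets) cm
    matr_t: np.ndarray  # per-paramset mean over targets (cm)
    matr_tp: float  # mean of matr_t over paramsets (cm)
    ci95: tuple[float, float]  # Student-t CI of matr_tp across paramsets


def _window_maxima(trace: DistanceTrace, dwell: float, edge_exclusion: float):
    """Within-window distance maxima for every admissible window centre.

    Returns (centre_times, maxima).  Window membership is closed on the grid
    (samples exactly half a dwell away are included); admissible centres lie
    in [edge_exclusion, t_stop - edge_exclusion].
    """
    if edge_exclusion < dwell / 2 - _EPS:
        raise ValueError("edge_exclusion must be at least half the dwell time")
    t, d = trace.t, trace.dist
    if t.size < 2:
        raise UndefinedMATRError("trace has fewer than two samples")
    step = trace.step
    # closed window membership on the grid: samples at exactly +/- dwell/2 are
    # included, samples strictly beyond are not (floor, not round)
    half = int(np.floor((dwell / 2) / step + _EPS))
    w = 2 * half + 1
    if t.size < w:
        raise UndefinedMATRError("trace shorter than one dwell window")
    centers = t[half:t.size - half]
    maxima = sliding_window_view(d, w).max(axis=1)
    keep = (centers >= edge_exclusion - _EPS) & (centers <= trace.t_stop - edge_exclusion + _EPS)
    if not keep.any():
        raise UndefinedMATRError("no admissible window centres inside the trace")
    return centers[keep], maxima[keep]


def matr(trace: DistanceTrace, dwell: float = 1.0, edge_exclusion: float = 0.5) -> float:
    """Minimum attainable target radius (cm) of one distance trace."""
    _, maxima = _window_maxima(trace, dwell, edge_exclusion)
    return float(maxima.min())


def movement_time(trace: DistanceTrace, radius: float, dwell: float = 1.0,
                  edge_exclusion: float = 0.5) -> float | None:
    """Earliest dwell-window start (s) whose window stays within ``radius``.

    Movement time excludes the dwell itself: it is the window start, not the
    window end.  Returns None when no admissible window fits inside the radius.
    """
    centers, maxima = _window_maxima(trace, dwell, edge_exclusion)
    ok = maxima <= radius + _EPS
    if not ok.any():
        return None
    return float(centers[ok][0] - dwell / 2)


def aggregate(per_target_per_paramset, confidence: float = 0.95) -> MATRResult:
    """Average a (targets, paramsets) MATR matrix into MATR-T and MATR-TP.

    The confidence interval is a Student-t interval of the mean across
    paramsets; with a single paramset it is flagged unavailable (NaN bounds).
    """
    M = np.asarray(per_target_per_paramset, dtype=float)
    if M.ndim != 2:
        raise ValueError("expected a (targets, paramsets) matrix")
    matr_t = M.mean(axis=0)
    matr_tp = float(matr_t.mean())
    n = matr_t.size
    if n >= 2:
        sem = matr_t.std(ddof=1) / np.sqrt(n)
        if sem == 0:
            ci = (matr_tp, matr_tp)
        else:
            lo, hi = stats.t.interval(confidence, df=n - 1, loc=matr_tp, scale=sem)
            ci = (float(lo), float(hi))
    else:
        ci = (float("nan"), float("nan"))
    return MATRResult(per_target=M, matr_t=matr_t, matr_tp=matr_tp, ci95=ci)


def _mean_ci(values: np.ndarray, confidence: float = 0.95):
    values = np.asarray(values, dtype=float)
    m = float(values.mean())
    if values.size >= 2:
        sem = values.std(ddof=1) / np.sqrt(values.size)
        if sem == 0:
            return m, m, m
        lo, hi = stats.t.interval(confidence, df=values.size - 1, loc=m, scale=sem)
        return m, float(lo), float(hi)
    return m, float("nan"), float("nan")


def radius_vs_time(traces, radii, dwell: float = 1.0, edge_exclusion: float = 0.5,
                   target_ids=None, paramset_ids=None) -> pd.DataFrame:
    """Mean movement time (s) to reach and hold each target radius.

    For each radius, movement times are computed per trace, averaged over
    targets within each paramset, then averaged over paramsets with a 95%
    Student-t CI (mean of means, matching the MATR-TP convention).  Traces for
    which a radius is unattainable are excluded and counted in ``n_undefined``.

    Returns a tidy frame with columns radius_cm, mean_time_s, ci_lo, ci_hi,
    n_defined, n_undefined.
    """
    radii = np.asarray(radii, dtype=float)
    if np.any(np.diff(radii) < 0):
        raise ValueError("radii must be sorted ascending")
    n = len(traces)
    target_ids = np.zeros(n, dtype=int) if target_ids is None else np.asarray(target_ids)
    paramset_ids = np.zeros(n, dtype=int) if paramset_ids is None else np.asarray(paramset_ids)
    rows = []
    for r in radii:
        times = np.array([
            movement_time(tr, r, dwell, edge_exclusion) for tr in traces
        ], dtype=object)
        defined = np.array([x is not None for x in times])
        per_paramset = []
        for ps in np.unique(paramset_ids):
            sel = defined & (paramset_ids == ps)
            if sel.any():
                per_paramset.append(np.array([times[i] for i in np.flatnonzero(sel)],
                                             dtype=float).mean())
        if per_paramset:
            m, lo, hi = _mean_ci(np.array(per_paramset))
        else:
            m, lo, hi = float("nan"), float("nan"), float("nan")
        rows.append({
            "radius_cm": float(r), "mean_time_s": m, "ci_lo": lo, "ci_hi": hi,
            "n_defined": int(defined.sum()), "n_undefined": int((~defined).sum()),
        })
    return pd.DataFrame(rows)


def distance_regression(per_target_matr_p) -> tuple[float, float]:
    """OLS slope of per-target MATR-P against target distance, with p-value.

    ``per_target_matr_p`` is a sequence of (distance_from_origin_cm, matr_cm)
    pairs; returns (slope, two-sided p-value for slope == 0).
    """
    pts = np.asarray(per_target_matr_p, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (distance, MATR) pairs")
    res = stats.linregress(pts[:, 0], pts[:, 1])
    return float(res.slope), float(res.pvalue)
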