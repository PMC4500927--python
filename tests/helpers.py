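"""Independent oracles used by the test suite.

These deliberately avoid the library's own implementations: the MATR oracle is
an exhaustive double loop over (window centre, offset) pairs, and the Kalman
filter oracle is the textbook update written directly from the standard
equations.
"""

from __future__ import annotations

import numpy as np


def brute_force_matr(t, dist, t_stop, dwell=1.0, edge_exclusion=0.5):
    """Exhaustive O(n^2) scan: min over admissible centres of within-window max."""
    t = np.asarray(t, float)
    dist = np.asarray(dist, float)
    eps = 1e-9
    best = None
    for i, tc in enumerate(t):
        if tc < edge_exclusion - eps or tc > t_stop - edge_exclusion + eps:
            continue
        wmax = 0.0
        for j, tj in enumerate(t):
            if abs(tj - tc) <= dwell / 2 + eps:
                wmax = max(wmax, dist[j])
        best = wmax if best is None else min(best, wmax)
    return best


def textbook_kf_update(mean, cov, H, R, observed, offset=0.0):
    """Standard Kalman measurement update: K = P H' (H P H' + R)^-1."""
    S = H @ cov @ H.T + R
    K = cov @ H.T @ np.linalg.inv(S)
    innov = observed - (H @ mean + offset)
    mean_new = mean + K @ innov
    P_new = (np.eye(len(mean)) - K @ H) @ cov
    return mean_new, P_new


class LinearMeasurement:
    """Linear, non-saturating measurement model with fixed diagonal noise.

    Implements the protocol the EKF update expects, so the update can be
    compared against :func:`textbook_kf_update` in the linear-Gaussian limit.
    """

    def __init__(self, H, noise_var):
        self.H = np.asarray(H, float)
        self.noise_var = np.asarray(noise_var, float)

    def __len__(self):
        return self.H.shape[0]

    def expected_rates(self, state):
        return self.H @ np.asarray(state, float)

    def expected_jacobian(self, state):
        return self.H.copy()

    def noise_diag(self, expected, dt):
        return self.noise_var.copy()
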