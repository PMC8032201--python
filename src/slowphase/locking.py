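"""Phase-map iteration, phase-locked states and the locking boundary.

Under a periodic pulse train with inter-stimulus interval T_s the phase just
before each pulse obeys the circle map

    theta_{i+1} = theta_i + PRC(A, theta_i) + T_s / T   (mod 1),

whose fixed points PRC(theta) = -T_s/T are the phase-locked states.  The
seizure-suppressing lock sits on the delaying (pre-discontinuity) piece of
the PRC: each pulse buys back exactly the phase the system advances between
pulses, pinning the trajectory to the interictal branch.  The critical
interval T_s* = T |max delay| bounds the locking wedge in the (A, T_s)
plane; for jittered trains the probability of an interval exceeding T_s* is
the breakdown heuristic.

Stability of a fixed point uses the standard circle-map criterion
|1 + PRC'(theta)| < 1 with PRC' from central differences on the sampled
curve, never across the discontinuity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .phase import PhaseResponseCurve, wrap_phase

__all__ = [
    "PhaseMapModel",
    "FixedPoint",
    "LockingBoundary",
    "phase_map_iterate",
    "find_fixed_points",
    "locking_boundary",
    "robustness_to_jitter",
]


@dataclass
class PhaseMapModel:
    """Stroboscopic phase map of a periodically kicked oscillator."""

    prc: PhaseResponseCurve
    period: float
    interval: float

    def step(self, theta: float) -> float:
        return (theta + self.prc(theta) + self.interval / self.period) % 1.0


def phase_map_iterate(pm: PhaseMapModel, theta0: float, n_steps: int):
    """Iterate the phase map; returns the n_steps + 1 visited phases."""
    out = np.empty(n_steps + 1)
    out[0] = theta0 % 1.0
    for i in range(n_steps):
        out[i + 1] = pm.step(out[i])
    return out


@dataclass
class FixedPoint:
    theta: float
    stable: bool
    suppressing: bool
    slope: float


def _pieces(prc: PhaseResponseCurve):
    """Index ranges of the PRC grid forming continuous pieces (split at theta*)."""
    n = len(prc.theta_grid)
    if prc.theta_star is None:
        # periodic: include the wrap-around segment
        return [np.concatenate([np.arange(n), [0]])]
    ts = prc.theta_star % 1.0
    start = int(np.searchsorted(prc.theta_grid, ts))
    order = (np.arange(n) + start) % n
    return [order]  # one piece: the grid unrolled to start just after theta*


def find_fixed_points(pm: PhaseMapModel) -> Sequence[FixedPoint]:
    """All roots of PRC(theta) + T_s/T on each continuous piece of the PRC.

    Roots on the advancing (post-discontinuity) piece are reported but
    flagged non-suppressing: such locks let the oscillation complete, so
    they do not prevent seizures.
    """
    prc, T, Ts = pm.prc, pm.period, pm.interval
    target = -Ts / T
    grid, vals = prc.theta_grid, prc.delta_theta
    n = len(grid)
    ts = prc.theta_star
    fixed = []
    for piece in _pieces(prc):
        g = grid[piece]
        v = vals[piece]
        # unwrap the grid so it is increasing
        g = np.concatenate([[g[0]], g[1:] + (np.cumsum(np.diff(g) < 0))])
        h = v - target
        for i in range(len(g) - 1):
            if h[i] == 0.0 or h[i] * h[i + 1] < 0:
                if h[i + 1] == h[i]:
                    root = g[i]
                else:
                    root = g[i] - h[i] * (g[i + 1] - g[i]) / (h[i + 1] - h[i])
                # local slope by central differences inside the piece
                lo, hi = max(i - 1, 0), min(i + 2, len(g) - 1)
                slope = (v[hi] - v[lo]) / (g[hi] - g[lo])
                stable = abs(1.0 + slope) < 1.0
                root = root % 1.0
                # a lock suppresses seizures only on the delaying
                # (non-crossing) side of the discontinuity
                if prc.crossing_mask is not None:
                    k = int(np.argmin(np.abs(wrap_phase(grid - root))))
                    suppressing = (not prc.crossing_mask[k]) and prc(root) <= 0.0
                else:
                    suppressing = prc(root) < 0.0
                fixed.append(FixedPoint(root, stable, bool(suppressing),
                                        float(slope)))
    return fixed


@dataclass
class LockingBoundary:
    """Critical inter-pulse interval T_s*(A) from the PRC family's max delays."""

    A_values: np.ndarray
    Ts_star: np.ndarray
    theta_star_delays: np.ndarray

    def ts_star_at(self, A: float) -> float:
        return float(np.interp(A, self.A_values, self.Ts_star))


def locking_boundary(prcs: Sequence[PhaseResponseCurve], T: float) -> LockingBoundary:
    """Boundary of the locking wedge: T_s* = T |most negative PRC value|.

    Intervals T_s < T_s*(A) are predicted locked (the accumulated delays can
    hold the trajectory on the interictal branch); a PRC with no delaying
    part yields T_s* = 0 (no suppression possible at that amplitude).
    """
    A = np.array([p.amplitude for p in prcs], dtype=float)
    delays = np.array([p.max_delay for p in prcs], dtype=float)
    order = np.argsort(A)
    return LockingBoundary(
        A_values=A[order],
        Ts_star=T * np.abs(delays[order]),
        theta_star_delays=delays[order],
    )


def robustness_to_jitter(ts_star: float, Ts: float, sigma: float) -> float:
    """Probability that a jittered interval exceeds the critical T_s*.

    Intervals follow N(T_s, sigma^2); the exceedance probability
    P(t_s > T_s*) is the heuristic for how fragile a deterministic lock is
    to timing noise (0.5 exactly at the boundary, by symmetry).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0.0:
        if Ts < ts_star:
            return 0.0
        if Ts == ts_star:
            return 0.5
        return 1.0
    return float(norm.sf(ts_star, loc=Ts, scale=sigma))
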