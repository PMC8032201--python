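"""Integration, limit-cycle location and slow-manifold geometry.

The limit cycle of a relaxation oscillator is found as a fixed point of a
Poincare map on a one-dimensional section (a line of constant fast
coordinate, crossed in a fixed direction) by a Newton iteration with a
finite-difference map derivative.  For slow-fast systems the cycle is
extraordinarily attracting (its nontrivial characteristic multiplier is of
order exp(-k/eps)), so the iteration typically settles in one or two steps;
the Newton form is kept because it is also correct for mildly attracting
cycles such as the test fixture at moderate stiffness.

The slow manifold {f(x, y) = 0} of a cubic-nullcline system is resolved into
its two attracting branches and the repelling middle branch (classified by
the sign of df/dx) together with the two fold points where df/dx = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, fsolve

from .exceptions import (
    ConvergenceError,
    DomainError,
    IntegrationError,
    SlowPhaseError,
)
from .models import PlanarSlowFastSystem

__all__ = [
    "Trajectory",
    "PoincareSection",
    "LimitCycle",
    "SlowManifoldGeometry",
    "BranchNullclineDistance",
    "integrate",
    "find_limit_cycle",
    "compute_slow_manifold",
    "slow_reduced_flow",
    "branch_nullcline_distance",
]

DEFAULT_CYCLE_TOL = 1e-12
DEFAULT_SWEEP_TOL = 1e-9


@dataclass
class Trajectory:
    """A numerically integrated orbit segment."""

    times: np.ndarray
    states: np.ndarray  # shape (n, 2)
    tol: float
    sol: Optional[object] = None  # scipy dense-output interpolant, if requested

    def __post_init__(self):
        if len(self.times) != len(self.states):
            raise ValueError("times and states must have equal length")

    @property
    def end(self) -> np.ndarray:
        return self.states[-1]


@dataclass(frozen=True)
class PoincareSection:
    """Line of constant fast coordinate, crossed in a fixed direction.

    direction=+1 counts crossings with increasing fast variable, -1 with
    decreasing.
    """

    fast_value: float
    direction: int = +1

    def event(self):
        def ev(t, z):
            return z[0] - self.fast_value

        ev.direction = float(self.direction)
        ev.terminal = False
        return ev


def integrate(
    system: PlanarSlowFastSystem,
    z0,
    t_span: float,
    tol: float = DEFAULT_CYCLE_TOL,
    events=None,
    dense_output: bool = False,
    t_eval=None,
) -> Trajectory:
    """Integrate the full flow for a (possibly negative) duration ``t_span``.

    Uses the 8th-order Dormand-Prince pair (DOP853) with relative tolerance
    ``tol``.  Events and dense output are passed through to the solver.
    Raises IntegrationError naming the time reached on failure.
    """
    if not 0 < tol <= 1e-6:
        raise ValueError(f"tol must lie in (0, 1e-6], got {tol}")
    if not np.isfinite(t_span):
        raise ValueError("t_span must be finite")
    z0 = np.asarray(z0, dtype=float)
    sol = solve_ivp(
        system.rhs,
        (0.0, float(t_span)),
        z0,
        method="DOP853",
        rtol=tol,
        atol=tol * 1e-2,
        events=events,
        dense_output=dense_output,
        t_eval=t_eval,
    )
    if not sol.success:
        raise IntegrationError(
            f"integration failed at t={sol.t[-1]:.6g}: {sol.message}",
            t_reached=sol.t[-1],
        )
    if not np.all(np.isfinite(sol.y)):
        raise IntegrationError(
            f"non-finite state reached by t={sol.t[-1]:.6g}", t_reached=sol.t[-1]
        )
    traj = Trajectory(sol.t, sol.y.T, tol, sol.sol if dense_output else None)
    traj._scipy = sol  # keep events accessible to callers
    return traj


@dataclass
class LimitCycle:
    """An attracting limit cycle with its time-proportional phase chart.

    The phase theta = t/T runs over [0, 1); gamma(theta) is stored as
    ``n_samples`` equispaced snapshots with ``samples[0] == anchor_point``
    (phase zero is anchored at the Poincare-section crossing).
    ``rotation_sense`` is +1 for counter-clockwise motion in the (fast, slow)
    plane, -1 for clockwise; it is measured from the orbit, not assumed.
    """

    anchor_point: np.ndarray
    period: float
    thetas: np.ndarray
    samples: np.ndarray  # shape (n, 2)
    rotation_sense: int
    section: PoincareSection
    tol: float
    residual: float
    system: PlanarSlowFastSystem

    @property
    def n_samples(self) -> int:
        return len(self.thetas)

    def point(self, theta: float, tol: Optional[float] = None) -> np.ndarray:
        """gamma(theta): nearest stored sample refined by a short integration."""
        tol = tol or self.tol
        th = float(theta) % 1.0
        n = self.n_samples
        i = int(np.floor(th * n)) % n
        dt = (th - i / n) * self.period
        if abs(dt) < 1e-13 * self.period:
            return self.samples[i].copy()
        return integrate(self.system, self.samples[i], dt, tol=tol).end

    def points(self, thetas, tol: Optional[float] = None) -> np.ndarray:
        return np.array([self.point(t, tol=tol) for t in np.atleast_1d(thetas)])

    def velocity(self, theta: float) -> np.ndarray:
        """Vector field Z(gamma(theta))."""
        return self.system.rhs(0.0, self.point(theta))

    def distance_to(self, z) -> float:
        """Distance from z to the sampled cycle (coarse, sample resolution)."""
        return float(np.min(np.linalg.norm(self.samples - np.asarray(z), axis=1)))


def _transient_to_section(system, section, guess, tol, max_time):
    """Integrate from the guess until the section is crossed repeatedly."""
    ev = section.event()
    t_total, z = 0.0, np.asarray(guess, dtype=float)
    horizon = max_time / 1024.0
    crossings = []
    while t_total < max_time:
        traj = integrate(system, z, horizon, tol=tol, events=ev)
        sol = traj._scipy
        for tc, zc in zip(sol.t_events[0], sol.y_events[0]):
            crossings.append((t_total + tc, zc))
        z = traj.end
        t_total += horizon
        horizon = min(2 * horizon, max_time - t_total) or horizon
        if len(crossings) >= 3:
            return crossings
    if crossings:
        return crossings
    raise ConvergenceError(
        f"trajectory from {tuple(guess)} never crossed the section "
        f"x={section.fast_value} (direction {section.direction:+d}) "
        f"within t={max_time:g}"
    )


def _return_map(system, section, y_on_section, tol, t_max):
    """One application of the Poincare map: (slow coord) -> (slow coord, time)."""
    ev = section.event()
    ev.terminal = True
    z0 = np.array([section.fast_value, y_on_section])
    # step off the section before arming the terminal event
    dt_escape = 1e-7 * t_max
    z1 = integrate(system, z0, dt_escape, tol=tol).end
    first = solve_ivp(
        system.rhs, (0.0, t_max), z1, method="DOP853", rtol=tol,
        atol=tol * 1e-2, events=ev,
    )
    if not first.success:
        raise IntegrationError(f"Poincare return failed: {first.message}")
    if len(first.t_events[0]) == 0:
        raise ConvergenceError(
            f"Poincare section x={section.fast_value} not re-crossed "
            f"within t={t_max:g}"
        )
    tr = dt_escape + float(first.t_events[0][0])
    zr = first.y_events[0][0]
    return float(zr[1]), tr


def find_limit_cycle(
    system: PlanarSlowFastSystem,
    section: Optional[PoincareSection] = None,
    guess=(0.0, 0.0),
    tol: float = DEFAULT_CYCLE_TOL,
    cycle_tol: float = 1e-9,
    n_samples: int = 2048,
    max_transient: float = 1e6,
    max_newton: int = 20,
) -> LimitCycle:
    """Locate the attracting limit cycle through Newton on a Poincare map.

    If no section is given, a vertical line through the guess's fast
    coordinate is used, with the crossing direction detected from the flow.
    ``tol`` controls the integrator, ``cycle_tol`` the accepted fixed-point
    residual |P(z) - z|.
    """
    guess = np.asarray(guess, dtype=float)
    if section is None:
        direction = 1 if system.fast_rhs(*guess) >= 0 else -1
        section = PoincareSection(guess[0], direction)

    crossings = _transient_to_section(system, section, guess, tol, max_transient)
    # period scale from the last pair of crossings
    if len(crossings) >= 2:
        t_guess = crossings[-1][0] - crossings[-2][0]
    else:
        t_guess = max_transient / 4
    y = float(crossings[-1][1][1])
    t_max = 20.0 * t_guess

    # Newton iteration on the 1-D map y -> P(y)
    residual = np.inf
    period = None
    for _ in range(max_newton):
        Py, period = _return_map(system, section, y, tol, t_max)
        residual = abs(Py - y)
        if residual <= cycle_tol:
            break
        h = max(1e-7 * max(abs(y), 1.0), 1e-10)
        Pp, _ = _return_map(system, section, y + h, tol, t_max)
        Pm, _ = _return_map(system, section, y - h, tol, t_max)
        dP = (Pp - Pm) / (2 * h)
        denom = dP - 1.0
        if denom == 0.0:
            raise ConvergenceError("degenerate Poincare-map derivative", residual)
        step = -(Py - y) / denom
        y = y + step
    else:
        raise ConvergenceError(
            f"Newton on the Poincare map did not reach residual {cycle_tol:g} "
            f"after {max_newton} iterations", residual,
        )
    # recompute residual/period at accepted point
    Py, period = _return_map(system, section, y, tol, t_max)
    residual = abs(Py - y)

    anchor = np.array([section.fast_value, y])
    t_eval = np.linspace(0.0, period, n_samples, endpoint=False)
    traj = integrate(system, anchor, period, tol=tol, t_eval=t_eval)
    samples = traj.states

    # orientation from the signed area of the sampled loop
    x, yv = samples[:, 0], samples[:, 1]
    area = 0.5 * np.sum(x * np.roll(yv, -1) - np.roll(x, -1) * yv)
    rotation = +1 if area > 0 else -1

    return LimitCycle(
        anchor_point=anchor,
        period=float(period),
        thetas=t_eval / period,
        samples=samples,
        rotation_sense=rotation,
        section=section,
        tol=tol,
        residual=residual,
        system=system,
    )


# ---------------------------------------------------------------------------
# Slow-manifold geometry
# ---------------------------------------------------------------------------

@dataclass
class SlowManifoldGeometry:
    """Branches and folds of the cubic slow manifold plus the slow nullcline.

    Branch arrays hold (x, y) rows; ``folds`` holds the two fold states,
    ordered by fast coordinate (lower fold first).
    """

    lower: np.ndarray
    repelling: np.ndarray
    upper: np.ndarray
    folds: np.ndarray
    slow_nullcline: np.ndarray
    y_range: tuple


def _fast_roots(system, y, x_range, scan=400):
    xs = np.linspace(x_range[0], x_range[1], scan)
    fs = np.array([system.fast_rhs(x, y) for x in xs])
    roots = []
    for i in range(len(xs) - 1):
        if fs[i] == 0.0:
            roots.append(xs[i])
        elif fs[i] * fs[i + 1] < 0:
            roots.append(
                brentq(lambda x: system.fast_rhs(x, y), xs[i], xs[i + 1],
                       xtol=1e-14, rtol=8.9e-16)
            )
    return roots


def _dfdx(system, x, y, h=1e-6):
    return (system.fast_rhs(x + h, y) - system.fast_rhs(x - h, y)) / (2 * h)


def compute_slow_manifold(
    system: PlanarSlowFastSystem,
    y_range,
    resolution: int = 400,
    x_range=(-4.0, 4.0),
) -> SlowManifoldGeometry:
    """Classify the branches of {f = 0} over a slow window bracketing the folds."""
    ys = np.linspace(y_range[0], y_range[1], resolution)
    lower, repel, upper = [], [], []
    seen_three = False
    for y in ys:
        roots = sorted(_fast_roots(system, y, x_range))
        if len(roots) >= 3:
            seen_three = True
            lower.append((roots[0], y))
            repel.append((roots[1], y))
            upper.append((roots[-1], y))
        elif len(roots) == 1:
            x = roots[0]
            (lower if _dfdx(system, x, y) < 0 and x < 0 else upper if
             _dfdx(system, x, y) < 0 else repel).append((x, y))
    if not seen_three:
        raise DomainError(
            "no cubic structure: f(., y) never has three roots in the window"
        )

    # folds: solve f = 0, df/dx = 0 seeded from the ends of the repelling branch
    rep = np.array(repel)
    folds = []
    for seed in (rep[np.argmin(rep[:, 0])], rep[np.argmax(rep[:, 0])]):
        with warnings.catch_warnings():
            # the seed sits on a near-degenerate (fold) point by design
            warnings.simplefilter("ignore", RuntimeWarning)
            sol = fsolve(
                lambda p: [system.fast_rhs(p[0], p[1]),
                           _dfdx(system, p[0], p[1])],
                seed, full_output=False, xtol=1e-13,
            )
        folds.append(sol)
    folds = np.array(sorted(folds, key=lambda p: p[0]))

    # slow nullcline over the same window
    nullcline = []
    for y in ys:
        xs = np.linspace(x_range[0], x_range[1], resolution)
        gs = np.array([system.slow_rhs(x, y) for x in xs])
        sign_change = np.nonzero(gs[:-1] * gs[1:] < 0)[0]
        for i in sign_change:
            nullcline.append(
                (brentq(lambda x: system.slow_rhs(x, y), xs[i], xs[i + 1],
                        xtol=1e-14), y)
            )
    return SlowManifoldGeometry(
        lower=np.array(lower),
        repelling=np.array(repel),
        upper=np.array(upper),
        folds=folds,
        slow_nullcline=np.array(nullcline),
        y_range=tuple(y_range),
    )


def slow_reduced_flow(
    system: PlanarSlowFastSystem,
    y: float,
    branch: str,
    x_range=(-4.0, 4.0),
) -> float:
    """Slow rate g(m(y), y) on a branch of the slow manifold.

    ``branch`` is one of 'lower', 'repelling', 'upper'; m(y) is that branch's
    root of f(., y) = 0.  Returns the bare slow_rhs (Eq-6 slow-time rate; for
    models with the timescale absorbed this is the full slow velocity).
    """
    roots = sorted(_fast_roots(system, y, x_range))
    attracting = [x for x in roots if _dfdx(system, x, y) < 0]
    repelling = [x for x in roots if _dfdx(system, x, y) > 0]
    if branch == "lower":
        cands = [x for x in attracting if not repelling or x < min(repelling)]
        if not cands:
            raise DomainError(f"no lower-branch root at {system.slow_var_name}={y}")
        m = min(cands)
    elif branch == "upper":
        cands = [x for x in attracting if not repelling or x > max(repelling)]
        if not cands:
            raise DomainError(f"no upper-branch root at {system.slow_var_name}={y}")
        m = max(cands)
    elif branch == "repelling":
        if not repelling:
            raise DomainError(f"no repelling root at {system.slow_var_name}={y}")
        m = repelling[0]
    else:
        raise ValueError(f"unknown branch {branch!r}")
    return float(system.slow_rhs(m, y))


# ---------------------------------------------------------------------------
# Branch <-> slow-nullcline separation
# ---------------------------------------------------------------------------

@dataclass
class BranchNullclineDistance:
    """Separation between the cycle's lower branch and the slow nullcline.

    Two complementary measures are taken at every lower-branch cycle sample
    (x, y):

    * ``fast_gaps``: the displacement along the pulse (fast) direction from
      the sample to the slow nullcline at the same slow value -- the pulse
      amplitude needed to land exactly on the nullcline from that phase.  Its
      minimum anchors the locking-onset amplitude.
    * ``slow_gaps``: the gap in the slow variable between the branch and the
      nullcline at the same fast value -- the nearly constant visual
      separation of the two curves in the phase plane.
    """

    fast_gaps: np.ndarray
    slow_gaps: np.ndarray
    branch_points: np.ndarray

    @property
    def mean_fast_gap(self) -> float:
        return float(np.mean(self.fast_gaps))

    @property
    def min_fast_gap(self) -> float:
        return float(np.min(self.fast_gaps))

    @property
    def max_fast_gap(self) -> float:
        return float(np.max(self.fast_gaps))

    @property
    def mean_slow_gap(self) -> float:
        return float(np.mean(self.slow_gaps))

    def summary(self) -> dict:
        return {
            "mean_fast_gap": self.mean_fast_gap,
            "min_fast_gap": self.min_fast_gap,
            "max_fast_gap": self.max_fast_gap,
            "mean_slow_gap": self.mean_slow_gap,
            "n_samples": int(len(self.fast_gaps)),
        }


def lower_branch_mask(
    system: PlanarSlowFastSystem,
    lc: LimitCycle,
    manifold: Optional[SlowManifoldGeometry] = None,
    rate_tol: Optional[float] = None,
):
    """Boolean mask of cycle samples sitting on the lower attracting branch.

    A sample is on the branch when its fast coordinate lies below the lower
    fold and its fast velocity is small; ``rate_tol`` defaults to 1% of the
    cycle's peak fast speed, which keeps the slow branch while excluding
    jumps and fold passages across models with different time constants.
    """
    if manifold is None:
        ys = lc.samples[:, 1]
        pad = 0.25 * (ys.max() - ys.min())
        manifold = compute_slow_manifold(
            system, (ys.min() - pad, ys.max() + pad), resolution=64
        )
    x_fold_low = manifold.folds[0, 0]
    x = lc.samples[:, 0]
    fdot = np.array([system.fast_rhs(*z) for z in lc.samples])
    if rate_tol is None:
        rate_tol = 0.01 * float(np.max(np.abs(fdot)))
    return (x < x_fold_low) & (np.abs(fdot) < rate_tol), manifold


def branch_nullcline_distance(
    system: PlanarSlowFastSystem,
    lc: LimitCycle,
    manifold: Optional[SlowManifoldGeometry] = None,
    rate_tol: Optional[float] = None,
    x_range=(-4.0, 4.0),
) -> BranchNullclineDistance:
    """Measure the lower-branch / slow-nullcline separation along the cycle."""
    mask, manifold = lower_branch_mask(system, lc, manifold, rate_tol)
    if not np.any(mask):
        raise DomainError("no cycle samples found on the lower branch")
    pts = lc.samples[mask]
    sgn = 1.0 if system.pulse_direction[0] >= 0 else -1.0
    slow_extent = float(lc.samples[:, 1].max() - lc.samples[:, 1].min())
    half_width = max(2.0, 4.0 * slow_extent)
    fast_gaps, slow_gaps, kept = [], [], []
    for x, y in pts:
        # fast-direction displacement to slow_rhs = 0 at matched slow value
        try:
            lo, hi = (x, x_range[1]) if sgn > 0 else (x_range[0], x)
            if system.slow_rhs(lo, y) * system.slow_rhs(hi, y) > 0:
                raise ValueError
            xn = brentq(lambda xx: system.slow_rhs(xx, y), lo, hi, xtol=1e-14)
        except ValueError:
            warnings.warn(
                f"slow nullcline not reached in the pulse direction from "
                f"({x:.3f}, {y:.3f}); sample excluded"
            )
            continue
        # slow-direction gap at matched fast value
        yspan = np.linspace(y - half_width, y + half_width, 400)
        gs = np.array([system.slow_rhs(x, yy) for yy in yspan])
        idx = np.nonzero(gs[:-1] * gs[1:] < 0)[0]
        if len(idx) == 0:
            warnings.warn(
                f"slow nullcline not bracketed in the slow direction at "
                f"({x:.3f}, {y:.3f}); sample excluded"
            )
            continue
        i = idx[np.argmin(np.abs(yspan[idx] - y))]
        yn = brentq(lambda yy: system.slow_rhs(x, yy), yspan[i], yspan[i + 1],
                    xtol=1e-14)
        fast_gaps.append(sgn * (xn - x))
        slow_gaps.append(abs(y - yn))
        kept.append((x, y))
    if not fast_gaps:
        raise DomainError("no lower-branch sample could be matched to the nullcline")
    return BranchNullclineDistance(
        fast_gaps=np.array(fast_gaps),
        slow_gaps=np.array(slow_gaps),
        branch_points=np.array(kept),
    )
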