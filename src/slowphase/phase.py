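"""Phase response curves, infinitesimal PRCs and isochrons.

The asymptotic phase Theta(z) of a basin point is the phase of the cycle
point its orbit converges to; its level sets are the isochrons.  A delta
pulse of amplitude A applied at phase theta displaces the state across
isochrons, and the phase response curve PRC(A, theta) records the resulting
shift.

PRCs are computed by a continuation Newton method: with
F_A(z) = phi_{T_rel}(z + A d) the relaxed image of the kicked point, the
phase map f_A solves F_A(gamma(theta)) = gamma(f_A(theta)), and
PRC(A, theta) = f_A(theta) - (theta + T_rel/T).  Each Newton step projects
the residual onto the cycle tangent T Z(gamma(f)); curves for growing
amplitudes are continued from the previous amplitude's solution.  A direct
method (kick, relax, read the asymptotic phase) serves as the brute-force
cross-check.

Asymptotic phases are read off at the upward zero crossing of the fast
variable, where the flow is fast: converting a crossing *time* into a phase
divides the position error by the local speed, so anchoring the readout in a
fast region keeps phases accurate to ~1e-10 even though most of the cycle
moves slowly.

The isochron tangent N(theta) along the cycle is the kernel of the phase
gradient; isochrons are globalized by seeding the linearization at a later
phase theta + t/T and flowing backward for time t, which stays on I_theta
while reaching O(1) distances despite the enormous transverse expansion of
the backward flow.  Forward variational and adjoint integration are
deliberately avoided in the primary path (the cycle's characteristic
multiplier is O(e^{-k/eps}) and underflows); a backward adjoint solve along
the stored cycle is provided separately as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .dynamics import LimitCycle, Trajectory, integrate, _fast_roots
from .exceptions import (
    BasinError,
    ConvergenceError,
    DegenerateLinearizationError,
    DomainError,
    PrecisionError,
)
from .models import PlanarSlowFastSystem

__all__ = [
    "PhaseResponseCurve",
    "InfinitesimalPRC",
    "IsochronCurve",
    "IsochronField",
    "asymptotic_phase",
    "default_relax_time",
    "prc_direct",
    "prc_continuation",
    "compute_iprc",
    "iprc_adjoint",
    "isochron_linearization",
    "globalize_isochron",
    "compute_isochron_field",
    "predict_isochron_offset",
    "isochron_slope_sign",
    "wrap_phase",
]


def wrap_phase(x):
    """Wrap phase differences to (-0.5, 0.5]."""
    w = (np.asarray(x, dtype=float) + 0.5) % 1.0 - 0.5
    return np.where(w == -0.5, 0.5, w) if np.ndim(w) else (0.5 if w == -0.5 else float(w))


def _perp(v):
    return np.array([-v[1], v[0]])


# ---------------------------------------------------------------------------
# Phase readout
# ---------------------------------------------------------------------------

def _reference_event(lc: LimitCycle):
    """Event marking the phase reference: upward crossing of fast = 0.

    Falls back to the cycle's own Poincare section if the cycle never
    crosses fast = 0 in the rising direction.
    """
    x = lc.samples[:, 0]
    rising = np.nonzero((x < 0) & (np.roll(x, -1) >= 0))[0]
    if len(rising) > 0:
        def ev(t, z):
            return z[0]
        ev.direction = 1.0
        return ev
    return lc.section.event()


def _reference_phase(lc: LimitCycle) -> float:
    """Phase at which the cycle passes the reference event."""
    if getattr(lc, "_ref_phase", None) is not None:
        return lc._ref_phase
    ev = _reference_event(lc)
    ev.terminal = False
    traj = integrate(lc.system, lc.anchor_point, lc.period, tol=lc.tol, events=ev)
    tev = traj._scipy.t_events[0]
    tev = tev[tev > 1e-9 * lc.period]
    if len(tev) == 0:
        lc._ref_phase = 0.0  # reference is the anchor itself
    else:
        lc._ref_phase = float(tev[0] / lc.period)
    return lc._ref_phase


def asymptotic_phase(
    lc: LimitCycle,
    system: PlanarSlowFastSystem,
    z,
    n_periods: int = 2,
    tol: float = 1e-12,
    conv_tol: float = 1e-6,
) -> float:
    """Asymptotic phase Theta(z) of a basin point.

    Integrates for (n_periods + 1) periods, records the reference-event
    crossings, and converts the last crossing time into a phase.  The last
    two crossings must agree to ``conv_tol`` (one period apart, the phase
    estimate is invariant once the orbit has converged), otherwise the point
    is reported as not (yet) converged to the cycle.
    """
    theta_ref = _reference_phase(lc)
    ev = _reference_event(lc)
    ev.terminal = False
    window = (n_periods + 1) * lc.period
    traj = integrate(system, np.asarray(z, dtype=float), window, tol=tol, events=ev)
    tev = traj._scipy.t_events[0]
    if len(tev) == 0:
        raise BasinError(
            f"no reference crossing within {n_periods + 1} periods from {tuple(z)}"
        )
    est = (theta_ref - tev / lc.period) % 1.0
    if len(est) >= 2:
        d = abs(wrap_phase(est[-1] - est[-2]))
        if d > conv_tol:
            raise BasinError(
                f"phase estimate not converged ({d:.2e} > {conv_tol:.0e}); "
                "increase n_periods"
            )
    return float(est[-1])


def default_relax_time(
    lc: LimitCycle,
    system: PlanarSlowFastSystem,
    delta: float = 1e-8,
    k_max: int = 8,
) -> float:
    """Smallest integer multiple of T after which an off-cycle probe has
    returned to the cycle within ``delta`` (measured by period-map stationarity).
    """
    cache = getattr(lc, "_relax_time", None)
    if cache is None:
        cache = lc._relax_time = {}
    if delta in cache:
        return cache[delta]
    diam = float(np.max(lc.samples.max(0) - lc.samples.min(0)))
    probe = lc.anchor_point + 0.01 * diam * system.pulse_direction
    T = lc.period
    traj = integrate(
        system, probe, (k_max + 1) * T, tol=lc.tol,
        t_eval=np.arange(1, k_max + 2) * T,
    )
    states = traj.states
    for k in range(k_max):
        if np.linalg.norm(states[k + 1] - states[k]) < delta:
            cache[delta] = (k + 1) * T
            return cache[delta]
    raise ConvergenceError(
        f"probe did not return to the cycle within {k_max} periods"
    )


# ---------------------------------------------------------------------------
# Phase response curves
# ---------------------------------------------------------------------------

@dataclass
class PhaseResponseCurve:
    """Sampled PRC for one pulse amplitude and direction.

    ``delta_theta`` holds phase shifts in cycle fractions wrapped to
    (-0.5, 0.5]; ``theta_star`` is the phase at which the kicked point lands
    exactly on the repelling branch (the PRC's jump), if one exists.
    Interpolation never crosses the discontinuity.
    """

    amplitude: float
    direction: np.ndarray
    theta_grid: np.ndarray
    delta_theta: np.ndarray
    theta_star: Optional[float]
    relax_time: float
    period: float
    #: per-sample flag: the kicked point lands beyond the repelling branch
    #: (the advancing side of the discontinuity); None if not evaluated
    crossing_mask: Optional[np.ndarray] = None

    def __call__(self, theta):
        """Piecewise-linear interpolation, split at theta_star (periodic)."""
        theta = np.atleast_1d(np.asarray(theta, dtype=float)) % 1.0
        out = np.empty_like(theta)
        grid, vals = self.theta_grid, self.delta_theta
        if self.theta_star is None:
            gg = np.concatenate([grid, grid[:1] + 1.0])
            vv = np.concatenate([vals, vals[:1]])
            out[:] = np.interp(theta, gg, vv)
        else:
            ts = self.theta_star % 1.0
            # unroll the grid so it starts just after the discontinuity
            shift = (grid - ts) % 1.0
            order = np.argsort(shift)
            gg, vv = shift[order], vals[order]
            th = (theta - ts) % 1.0
            out[:] = np.interp(th, gg, vv)  # flat extrapolation at the jump
        return out if out.size > 1 else float(out[0])

    @property
    def max_delay(self) -> float:
        """Most negative phase shift on the delaying side of the
        discontinuity (0 if the PRC has no delaying part).

        Samples whose kick crosses the repelling branch are excluded: their
        shifts are large advances, which the (-0.5, 0.5] wrap can fold into
        apparent delays.
        """
        vals = self.delta_theta
        if self.crossing_mask is not None:
            vals = vals[~self.crossing_mask]
        if len(vals) == 0:
            return 0.0
        return min(float(np.min(vals)), 0.0)


@dataclass
class InfinitesimalPRC:
    """Phase gradient along the cycle: gradients[j] = grad Theta(gamma(theta_j))."""

    theta_grid: np.ndarray
    gradients: np.ndarray  # (n, 2)
    amplitude_used: float


def prc_direct(
    lc: LimitCycle,
    system: PlanarSlowFastSystem,
    A: float,
    theta,
    T_rel: Optional[float] = None,
    tol: float = 1e-12,
):
    """Brute-force PRC: kick gamma(theta) by A along the pulse direction,
    relax, and read the asymptotic phase.  ``theta`` may be scalar or array.
    """
    if T_rel is None:
        T_rel = default_relax_time(lc, system)
    n_periods = max(1, int(round(T_rel / lc.period)))
    thetas = np.atleast_1d(np.asarray(theta, dtype=float))
    out = np.empty_like(thetas)
    for i, th in enumerate(thetas):
        z = lc.point(th) + A * system.pulse_direction
        n = n_periods
        while True:
            try:
                new = asymptotic_phase(lc, system, z, n_periods=n, tol=tol)
                break
            except BasinError as exc:
                # a kick larger than the relax-time probe may need longer
                n *= 2
                if n > 16 * n_periods:
                    raise BasinError(
                        f"kicked point at theta={th} escaped: {exc}"
                    ) from exc
        out[i] = wrap_phase(new - th)
    return out if np.ndim(theta) else float(out[0])


def _pulse_crosses_repelling(system, lc, theta, A, direction):
    """True if gamma(theta) + A d lands beyond the repelling branch."""
    z = lc.point(theta)
    zk = z + A * direction
    sgn = 1.0 if direction[0] >= 0 else -1.0
    roots = sorted(_fast_roots(system, z[1], (-4.0, 4.0)))
    if len(roots) < 3:
        return False
    mid = roots[1]
    return (sgn * (z[0] - mid) < 0) and (sgn * (zk[0] - mid) >= 0)


def _locate_theta_star(system, lc, A, direction, grid, tol=1e-8, flags=None):
    """Bisection on the event 'kick lands beyond the repelling branch'."""
    if flags is None:
        flags = np.array(
            [_pulse_crosses_repelling(system, lc, th, A, direction)
             for th in grid]
        )
    if not flags.any() or flags.all():
        return None
    # first False -> True transition along increasing theta (periodic)
    idx = np.nonzero(~flags & np.roll(flags, -1))[0]
    if len(idx) == 0:
        return None
    i = idx[0]
    lo, hi = grid[i], grid[(i + 1) % len(grid)]
    if hi < lo:
        hi += 1.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _pulse_crosses_repelling(system, lc, mid % 1.0, A, direction):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi) % 1.0


def _newton_phase_solve(lc, target, f0, tol, maxit=40, step_floor=1e-13):
    """Solve gamma(f) = target for f by tangent-projected Newton.

    Converged when the residual drops below ``tol``, or when the phase
    update stagnates below ``step_floor`` while the residual is already
    tiny (it then sits at the target's own transverse distance from the
    cycle, which no phase can remove).  Stagnation with a large residual is
    a false local minimizer (nearest-point projection onto the wrong arc)
    and is reported as non-convergence so the caller can re-seed.
    """
    T = lc.period
    f = float(f0)
    for _ in range(maxit):
        g = lc.point(f % 1.0)
        E = target - g
        res = float(np.linalg.norm(E))
        if res <= tol:
            return f, res, True
        tang = T * lc.system.rhs(0.0, g)
        step = float(tang @ E / (tang @ tang))
        # cap steps at a quarter turn to keep the iteration on the right arc
        step = np.clip(step, -0.25, 0.25)
        f += step
        if abs(step) <= step_floor:
            g = lc.point(f % 1.0)
            res = float(np.linalg.norm(target - g))
            return f, res, res <= max(1e3 * tol, 1e-6)
    g = lc.point(f % 1.0)
    return f, float(np.linalg.norm(target - g)), False


def _prc_solve_amplitude(lc, system, A, direction, thetas, f_seed, T_rel, tol,
                         int_tol):
    """One amplitude level: relax all kicked points, Newton-solve each phase."""
    n = len(thetas)
    f_new = np.array(f_seed, dtype=float)
    ok = np.zeros(n, dtype=bool)
    for j, th in enumerate(thetas):
        zk = lc.point(th) + A * direction
        target = integrate(system, zk, T_rel, tol=int_tol).end
        f, res, conv = _newton_phase_solve(lc, target, f_seed[j], tol)
        if not conv:
            # re-seed from the nearest stored cycle sample and retry
            i = int(np.argmin(np.linalg.norm(lc.samples - target, axis=1)))
            base = np.floor(f_seed[j]) + lc.thetas[i]
            for cand in (base, base + 1.0, base - 1.0):
                f, res, conv = _newton_phase_solve(lc, target, cand, tol)
                if conv:
                    break
        f_new[j], ok[j] = f, conv
    return f_new, ok


def prc_continuation(
    lc: LimitCycle,
    system: PlanarSlowFastSystem,
    A_target: float,
    n_theta: int = 64,
    delta_A: Optional[float] = None,
    T_rel: Optional[float] = None,
    tol: float = 1e-9,
    int_tol: float = 1e-12,
    direction: Optional[np.ndarray] = None,
    locate_discontinuity: bool = True,
    refine_near_discontinuity: int = 0,
) -> PhaseResponseCurve:
    """PRC by Newton continuation in the pulse amplitude.

    Starts from the exact zero-amplitude solution f(theta) = theta + T_rel/T
    and continues in steps ``delta_A`` (default A_target/20, halved
    adaptively on Newton failure) up to ``A_target``.  ``tol`` is the Newton
    residual |E| in state space.

    The maximal delay concentrates in a narrow spike just below the
    discontinuity; ``refine_near_discontinuity`` adds that many extra
    samples on a geometric ladder approaching theta* from the delaying
    side, so the limiting delay (which sets the locking boundary) is
    resolved beyond the uniform grid.
    """
    if direction is None:
        direction = system.pulse_direction
    direction = np.asarray(direction, dtype=float)
    if T_rel is None:
        T_rel = default_relax_time(
            lc, system, delta=min(1e-8, max(0.1 * tol, 1e-11))
        )
    T = lc.period
    thetas = np.arange(n_theta) / n_theta
    shift = T_rel / T
    f = thetas + shift

    if A_target != 0.0:
        if delta_A is None:
            delta_A = abs(A_target) / 20.0
        delta_A = abs(delta_A) * np.sign(A_target)
        min_step = abs(delta_A) / 64.0
        A_prev, f_prev = 0.0, f.copy()
        A = A_prev + delta_A
        step = delta_A
        while True:
            f_new, ok = _prc_solve_amplitude(
                lc, system, A, direction, thetas, f_prev, T_rel, tol, int_tol
            )
            if ok.all():
                A_prev, f_prev = A, f_new
                if np.isclose(A_prev, A_target):
                    f = f_new
                    break
                step = delta_A
                A = A_prev + step
                if (A - A_target) * np.sign(delta_A) > 0:
                    A = A_target
            else:
                step /= 2.0
                if abs(step) < min_step:
                    bad = thetas[~ok][0]
                    raise ConvergenceError(
                        f"PRC continuation failed at A={A:.4g}, theta={bad:.4f} "
                        f"(minimum amplitude step reached)"
                    )
                A = A_prev + step

    delta = wrap_phase(f - thetas - shift)
    theta_star = None
    crossing = None
    if locate_discontinuity and A_target != 0.0:
        crossing = np.array(
            [_pulse_crosses_repelling(system, lc, th, A_target, direction)
             for th in thetas]
        )
        theta_star = _locate_theta_star(system, lc, A_target, direction,
                                        thetas, flags=crossing)
    if refine_near_discontinuity > 0 and theta_star is not None:
        spacing = 1.0 / n_theta
        eps = np.geomspace(3e-4, 0.5 * spacing, refine_near_discontinuity)
        new_th, new_f = [], []
        # seed from the nearest delay-side grid sample
        j_below = int(np.floor(theta_star * n_theta)) % n_theta
        for e in eps:
            th_new = (theta_star - e) % 1.0
            zk = lc.point(th_new) + A_target * direction
            target = integrate(system, zk, T_rel, tol=int_tol).end
            seed = f[j_below] + (th_new - thetas[j_below])
            fr, _, conv = _newton_phase_solve(lc, target, seed, tol)
            if not conv:
                i = int(np.argmin(np.linalg.norm(lc.samples - target,
                                                 axis=1)))
                fr, _, conv = _newton_phase_solve(
                    lc, target, np.floor(seed) + lc.thetas[i], tol)
            if conv:
                new_th.append(th_new)
                new_f.append(fr)
        if new_th:
            order = np.argsort(new_th)
            new_th = np.asarray(new_th)[order]
            new_f = np.asarray(new_f)[order]
            new_delta = wrap_phase(np.asarray(new_f) - new_th - shift)
            new_cross = np.array(
                [_pulse_crosses_repelling(system, lc, th, A_target, direction)
                 for th in new_th]
            )
            pos = np.searchsorted(thetas, new_th)
            thetas = np.insert(thetas, pos, new_th)
            delta = np.insert(delta, pos, new_delta)
            crossing = np.insert(crossing, pos, new_cross)
    return PhaseResponseCurve(
        amplitude=float(A_target),
        direction=direction,
        theta_grid=thetas,
        delta_theta=np.asarray(delta, dtype=float),
        theta_star=theta_star,
        relax_time=float(T_rel),
        period=T,
        crossing_mask=crossing,
    )


# ---------------------------------------------------------------------------
# Infinitesimal PRC and isochron linearization
# ---------------------------------------------------------------------------

def compute_iprc(
    lc: LimitCycle,
    system: PlanarSlowFastSystem,
    A_small: float = 2e-4,
    n_theta: int = 64,
    T_rel: Optional[float] = None,
    tol: float = 1e-12,
    int_tol: float = 1e-13,
    richardson_tol: float = 1e-3,
    A_floor: float = 1e-7,
) -> InfinitesimalPRC:
    """Phase gradient along the cycle from small-amplitude PRCs.

    For each state-space basis direction the PRC is computed at A, A/2 and
    A/4 and Richardson-extrapolated to second order,
    grad = (PRC(A)/A - 6 PRC(A/2)/(A/2) + 8 PRC(A/4)/(A/4)) / 3, cancelling
    the O(A) and O(A^2) curvature bias.  The finest two quotients must agree
    to ``richardson_tol`` relative to the gradient scale; otherwise A is
    halved, down to ``A_floor``.
    """
    if T_rel is None:
        T_rel = default_relax_time(
            lc, system, delta=min(1e-8, max(0.1 * tol, 1e-11))
        )
    A = float(A_small)
    while True:
        grads = np.empty((n_theta, 2))
        worst = 0.0
        for k, e in enumerate(np.eye(2)):
            r = []
            for a in (A, A / 2, A / 4):
                prc = prc_continuation(
                    lc, system, a, n_theta=n_theta, delta_A=a, T_rel=T_rel,
                    tol=tol, int_tol=int_tol, direction=e,
                    locate_discontinuity=False,
                )
                r.append(prc.delta_theta / a)
            grads[:, k] = (r[0] - 6 * r[1] + 8 * r[2]) / 3.0
            scale = max(np.max(np.abs(grads[:, k])), 1e-12)
            # observed-order check: successive first-order extrapolations
            # must agree (their difference is the residual O(A^2) term)
            e21, e42 = 2 * r[1] - r[0], 2 * r[2] - r[1]
            worst = max(worst, np.max(np.abs(e42 - e21)) / scale)
        if worst <= richardson_tol:
            return InfinitesimalPRC(np.arange(n_theta) / n_theta, grads, A)
        A /= 2.0
        if A < A_floor:
            raise PrecisionError(
                f"Richardson check still off by {worst:.2e} at A={2 * A:.1e}"
            )


def iprc_adjoint(
    lc: LimitCycle,
    system: PlanarSlowFastSystem,
    n_theta: int = 64,
    tol: float = 1e-12,
    max_step: Optional[float] = None,
) -> InfinitesimalPRC:
    """Independent iPRC oracle: backward adjoint integration along the cycle.

    Backward in time the nontrivial adjoint mode *decays* (the cycle is
    attracting), so integrating w' = -J^T w backward over two periods along
    the stored cycle converges to the phase gradient; the first period purges
    the seed, the second is recorded.  Normalized so <grad, Z> = 1/T at the
    anchor; the dot product is a conserved quantity of the adjoint flow.

    The step size is capped so narrow Jacobian layers (a steep threshold
    nonlinearity crossed during the fast jump) are not stepped over.
    """
    T = lc.period
    if max_step is None:
        max_step = T / 8192.0
    fwd = integrate(system, lc.anchor_point, T, tol=tol, dense_output=True)
    gamma = fwd.sol

    def gamma_at(t):
        return gamma(float(t) % T if t % T != 0 else 0.0)

    def rhs_w(t, w):
        J = system.jac(gamma_at(t))
        return -J.T @ w

    Z0 = system.rhs(0.0, lc.anchor_point)
    w = _perp(Z0)  # any seed with a component along the gradient
    sol = solve_ivp(rhs_w, (2 * T, T), w, method="DOP853", rtol=tol,
                    atol=tol * 1e-2, max_step=max_step)
    w = sol.y[:, -1]
    w = w / (T * float(w @ Z0))
    t_grid = np.arange(n_theta) / n_theta * T
    sol = solve_ivp(
        rhs_w, (T, 0.0), w, method="DOP853", rtol=tol, atol=tol * 1e-2,
        max_step=max_step, t_eval=t_grid[::-1] if n_theta > 1 else [0.0],
    )
    grads = sol.y.T[::-1]
    return InfinitesimalPRC(np.arange(n_theta) / n_theta, grads, 0.0)


def isochron_linearization(
    iprc: InfinitesimalPRC,
    lc: LimitCycle,
    system: PlanarSlowFastSystem,
    degenerate_tol: float = 1e-12,
) -> np.ndarray:
    """Unit isochron tangents N(theta): the kernel of the phase gradient.

    The gradient is recovered from N via grad = N_perp / (T <N_perp, Z>),
    which tests use as a round-trip identity.
    """
    N = np.empty_like(iprc.gradients)
    for j, g in enumerate(iprc.gradients):
        ng = np.linalg.norm(g)
        if ng < degenerate_tol:
            raise DegenerateLinearizationError(
                f"phase gradient ~ 0 at theta={iprc.theta_grid[j]:.4f}"
            )
        N[j] = _perp(g) / ng
    return N


# ---------------------------------------------------------------------------
# Isochron globalization
# ---------------------------------------------------------------------------

@dataclass
class IsochronCurve:
    """One globalized isochron: ordered points through gamma(theta)."""

    theta: float
    points: np.ndarray
    truncated: bool = False


@dataclass
class IsochronField:
    """A family of isochrons with the cycle-side linearization."""

    thetas: np.ndarray
    curves: Sequence[IsochronCurve]
    linearization: np.ndarray  # N(theta) on the iPRC grid
    iprc: InfinitesimalPRC


def _interp_periodic_vectors(grid, vecs, theta):
    th = theta % 1.0
    gg = np.concatenate([grid, [grid[0] + 1.0]])
    vv = np.vstack([vecs, vecs[:1]])
    v = np.array([np.interp(th, gg, vv[:, k]) for k in range(vecs.shape[1])])
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def _box_event(box):
    (x0, x1), (y0, y1) = box
    cx, rx = 0.5 * (x0 + x1), 0.5 * (x1 - x0)
    cy, ry = 0.5 * (y0 + y1), 0.5 * (y1 - y0)

    def ev(t, z):
        return max(abs(z[0] - cx) / rx, abs(z[1] - cy) / ry) - 1.0

    ev.terminal = True
    return ev


def globalize_isochron(
    lc: LimitCycle,
    system: PlanarSlowFastSystem,
    theta: float,
    N: np.ndarray,
    length_budget: Optional[float] = None,
    step_control: Optional[dict] = None,
) -> IsochronCurve:
    """Globalize the isochron I_theta from its linear segment at the cycle.

    A seed on the linearization of I_{theta + t/T}, flowed backward for time
    t, lies on I_theta; sweeping t (on both sides of the cycle) traces the
    curve outward until it leaves the domain box, exhausts the arc-length
    budget, or fails the asymptotic-phase membership test (isochron
    curvature grows without bound near the folds, where the linear seed
    stops being accurate; each side is truncated at the first point whose
    measured phase deviates by more than ``validate_tol``).  ``N`` is the
    tangent field on the iPRC theta grid.
    """
    sc = {
        "s": None,            # seed offset from the cycle
        "t_step": None,       # initial backward-time increment
        "max_arc_step": None, # target spacing between stored points
        "t_max": None,        # cap on the backward time
        "box": None,          # ((x0, x1), (y0, y1)) domain box
        "tol": 1e-10,
        "validate_tol": 1e-4, # membership tolerance (None disables)
        "validate_periods": 2,
    }
    if step_control:
        sc.update(step_control)
    T = lc.period
    lo, hi = lc.samples.min(0), lc.samples.max(0)
    diam = float(np.max(hi - lo))
    s = sc["s"] or 1e-4 * diam
    if sc["box"] is None:
        pad = 0.3 * (hi - lo) + 1e-3
        sc["box"] = ((lo[0] - pad[0], hi[0] + pad[0]), (lo[1] - pad[1], hi[1] + pad[1]))
    box_ev = _box_event(sc["box"])
    max_arc = sc["max_arc_step"] or 0.03 * diam
    t_max = sc["t_max"] or 0.5 * T
    grid = np.arange(len(N)) / len(N)
    tol = sc["tol"]

    base = lc.point(theta)
    sides = {}
    truncated = False
    for side in (+1.0, -1.0):
        pts = []
        t, dt = 0.0, sc["t_step"] or 0.02 * T
        prev = base
        while t <= t_max:
            th_seed = (theta + t / T) % 1.0
            n_vec = _interp_periodic_vectors(grid, N, th_seed)
            seed = lc.point(th_seed) + side * s * n_vec
            if t == 0.0:
                z = seed
            else:
                traj = integrate(system, seed, -t, tol=tol, events=box_ev)
                if len(traj._scipy.t_events[0]) > 0 or box_ev(0.0, traj.end) > 0:
                    truncated = True
                    break
                z = traj.end
            gap = np.linalg.norm(z - prev)
            if t > 0.0 and gap > max_arc and dt > 1e-4 * T:
                t -= dt
                dt /= 2.0
                t += dt
                continue
            if sc["validate_tol"] is not None and t > 0.0:
                try:
                    th_meas = asymptotic_phase(
                        lc, system, z, n_periods=sc["validate_periods"],
                        tol=1e-9,
                    )
                except BasinError:
                    truncated = True
                    break
                if abs(wrap_phase(th_meas - theta)) > sc["validate_tol"]:
                    truncated = True
                    break
            pts.append(z)
            prev = z
            if length_budget is not None:
                arc = np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)) if len(pts) > 1 else 0.0
                if arc >= length_budget:
                    break
            if gap < 0.25 * max_arc:
                dt *= 1.5
            t += dt
        sides[side] = pts
    points = np.array(sides[-1.0][::-1] + [base] + sides[+1.0])
    return IsochronCurve(theta=float(theta % 1.0), points=points, truncated=truncated)


def compute_isochron_field(
    lc: LimitCycle,
    system: PlanarSlowFastSystem,
    n_isochrons: int = 16,
    iprc: Optional[InfinitesimalPRC] = None,
    **kwargs,
) -> IsochronField:
    """Equispaced isochrons with their linearization field."""
    if iprc is None:
        iprc = compute_iprc(lc, system, n_theta=max(64, 4 * n_isochrons))
    N = isochron_linearization(iprc, lc, system)
    thetas = np.arange(n_isochrons) / n_isochrons
    curves = [globalize_isochron(lc, system, th, N, **kwargs) for th in thetas]
    return IsochronField(thetas=thetas, curves=curves, linearization=N, iprc=iprc)


# ---------------------------------------------------------------------------
# Slow-field isochron-offset theory
# ---------------------------------------------------------------------------

def _layer_flow(system, z_bar, eta, t_max, tol=1e-12):
    """Fast subsystem with the slow variable frozen, run until |f| <= eta.

    Returns (t_h, x(t) interpolant, quadrature of the slow rate).
    """
    x_bar, y_bar = float(z_bar[0]), float(z_bar[1])

    def rhs(t, s):
        return [system.fast_rhs(s[0], y_bar), system.slow_rate(s[0], y_bar)]

    def ev(t, s):
        return abs(system.fast_rhs(s[0], y_bar)) - eta

    ev.terminal = True
    ev.direction = -1.0
    f0 = system.fast_rhs(x_bar, y_bar)
    if abs(f0) <= eta:
        h = 1e-6
        dfdx = (system.fast_rhs(x_bar + h, y_bar)
                - system.fast_rhs(x_bar - h, y_bar)) / (2 * h)
        if dfdx > 0:
            raise DomainError(
                f"({x_bar:.3f}, {y_bar:.3f}) sits on the repelling branch"
            )
    sol = solve_ivp(rhs, (0.0, t_max), [x_bar, 0.0], method="DOP853",
                    rtol=tol, atol=tol * 1e-2, events=ev, dense_output=True)
    if len(sol.t_events[0]) == 0:
        raise DomainError(
            f"layer trajectory from ({x_bar:.3f}, {y_bar:.3f}) did not reach "
            f"the slow manifold within t={t_max:g} (repelling region?)"
        )
    t_h = float(sol.t_events[0][0])
    q = float(sol.y_events[0][0][1])
    return t_h, sol.sol, q


def predict_isochron_offset(
    system: PlanarSlowFastSystem,
    lc: LimitCycle,
    z_bar,
    eta: Optional[float] = None,
    t_max: Optional[float] = None,
) -> float:
    """Leading-order slow offset of the isochron through z_bar relative to a
    frozen-slow (constant-y) line.

    The kicked point converges under the layer dynamics in a measured time
    t_h; the offset is the difference between the slow displacement of the
    matching cycle point and of the frozen-y layer trajectory over that time.
    A positive value tilts the isochron toward larger slow values at z_bar.
    """
    z_bar = np.asarray(z_bar, dtype=float)
    if eta is None:
        eta = max(system.epsilon, 1e-6)
    if t_max is None:
        t_max = max(100.0, 0.2 * lc.period)
    t_h, layer_sol, q_layer = _layer_flow(system, z_bar, eta, t_max)

    # matching cycle point: same slow value, on the branch the layer flow hits
    x_land = float(layer_sol(t_h)[0])
    diam = float(np.max(lc.samples.max(0) - lc.samples.min(0)))
    near = np.nonzero(np.abs(lc.samples[:, 0] - x_land) < 0.25 * diam)[0]
    if len(near) == 0:
        raise DomainError("no cycle samples near the landing branch")
    i = near[int(np.argmin(np.abs(lc.samples[near, 1] - z_bar[1])))]

    def ev(t, z):
        return z[1] - z_bar[1]

    ev.terminal = True
    start = lc.samples[(i - 1) % lc.n_samples]
    traj = integrate(system, start, 3 * lc.period / lc.n_samples * 4, tol=lc.tol,
                     events=ev)
    base = traj._scipy.y_events[0][0] if len(traj._scipy.t_events[0]) else lc.samples[i]

    def rhs(t, s):
        return np.append(system.rhs(t, s[:2]), system.slow_rate(s[0], s[1]))

    sol = solve_ivp(rhs, (0.0, t_h), np.append(base, 0.0), method="DOP853",
                    rtol=1e-12, atol=1e-14)
    q_cycle = float(sol.y[2, -1])
    return q_cycle - q_layer


def isochron_slope_sign(
    system: PlanarSlowFastSystem,
    z_bar,
    lc: LimitCycle,
    eta: Optional[float] = None,
    n_samples: int = 64,
    rel_tol: float = 1e-3,
) -> Optional[int]:
    """Predicted sign of the isochron slope K at z_bar from the monotonicity
    of the slow field along the layer trajectory.

    If the slow rate g is strictly increasing in the fast variable along the
    approach, the isochron slope is negative (and vice versa); returns +1,
    -1, 0 when the slow field is insensitive to the fast variable, or None
    when g is non-monotone along the trajectory (indeterminate).
    """
    z_bar = np.asarray(z_bar, dtype=float)
    if eta is None:
        eta = max(system.epsilon, 1e-6)
    t_h, layer_sol, _ = _layer_flow(system, z_bar, eta, max(100.0, 0.2 * lc.period))
    ts = np.linspace(0.0, t_h, n_samples)
    y_bar = z_bar[1]
    h = 1e-6
    dgdx = np.array(
        [
            (system.slow_rate(layer_sol(t)[0] + h, y_bar)
             - system.slow_rate(layer_sol(t)[0] - h, y_bar)) / (2 * h)
            for t in ts
        ]
    )
    scale = np.max(np.abs(dgdx))
    if scale == 0.0:
        return 0
    sig = dgdx[np.abs(dgdx) > rel_tol * scale]
    if len(sig) == 0:
        return 0
    if np.all(sig > 0):
        return -1
    if np.all(sig < 0):
        return +1
    return None
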