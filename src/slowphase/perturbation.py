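"""Pulse-train simulation, seizure counting and seizure-rate sweeps.

A train of delta pulses of amplitude A kicks the fast variable at intervals
drawn from N(T_s, sigma^2) (sigma = 0 gives the periodic train).  A seizure
is an upward zero crossing of the fast variable -- the transition to the
seizing upper branch, whose terminating fold sits at v = 0 in both bundled
models.  Crossings are located by the integrator's event detection, with a
short refractory window against grazing double counts; a pulse that itself
carries the state across v = 0 counts as a transition too.

The seizure-rate change Delta divides the perturbed count by the
unperturbed one (one seizure per period), so Delta = 1 is no effect,
Delta > 1 pro-convulsive, and Delta = 0 complete suppression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .dynamics import LimitCycle, Trajectory, integrate
from .exceptions import ConfigurationError, IntegrationError
from .models import PlanarSlowFastSystem

__all__ = [
    "PulseTrainSpec",
    "TrainResult",
    "SweepGrid",
    "generate_intervals",
    "simulate_train",
    "seizure_rate_change",
    "sweep",
    "locking_onset",
]

log = logging.getLogger(__name__)

DEFAULT_REFRACTORY_FRACTION = 0.01


@dataclass
class PulseTrainSpec:
    """Specification of a jittered delta-pulse train.

    ``sigma = 0`` gives the periodic train.  ``initial_state`` is either an
    explicit state or the string 'lower-branch-start' (the cycle point where
    the post-seizure jump lands, so early pulses hit the interictal state).
    """

    amplitude: float
    mean_interval: float
    duration: float
    sigma: float = 0.0
    seed: Optional[int] = None
    initial_state: Union[str, np.ndarray] = "lower-branch-start"

    def __post_init__(self):
        if self.amplitude < 0:
            raise ConfigurationError("amplitude must be >= 0")
        if self.mean_interval <= 0:
            raise ConfigurationError("mean_interval must be > 0")
        if self.sigma < 0:
            raise ConfigurationError("sigma must be >= 0")
        if self.duration <= 0:
            raise ConfigurationError("duration must be > 0")
        if self.sigma > 0 and self.seed is None:
            raise ConfigurationError(
                "a seed is required when sigma > 0 (no silent nondeterminism)"
            )


def generate_intervals(spec: PulseTrainSpec, floor: Optional[float] = None):
    """Draw inter-pulse intervals covering the spec's duration.

    Gaussian draws are clipped at a positive floor (the normal law allows
    negatives for small T_s/sigma); the clip count is logged.
    """
    if spec.sigma == 0.0:
        n = int(np.ceil(spec.duration / spec.mean_interval)) + 1
        return np.full(n, spec.mean_interval)
    if floor is None:
        floor = 1e-3 * spec.mean_interval
    rng = np.random.default_rng(spec.seed)
    out = []
    total, clipped = 0.0, 0
    while total < spec.duration:
        draw = rng.normal(spec.mean_interval, spec.sigma, size=256)
        low = draw < floor
        clipped += int(low.sum())
        draw = np.where(low, floor, draw)
        out.append(draw)
        total += float(draw.sum())
    if clipped:
        log.info("clipped %d negative/short intervals to %.3g", clipped, floor)
    return np.concatenate(out)


@dataclass
class TrainResult:
    """Outcome of one pulse-train simulation."""

    seizure_count: int
    seizure_times: np.ndarray
    pulse_times: np.ndarray
    final_state: np.ndarray
    trajectory: Optional[Trajectory] = None


def _initial_state(lc: LimitCycle, spec: PulseTrainSpec) -> np.ndarray:
    if isinstance(spec.initial_state, str):
        if spec.initial_state != "lower-branch-start":
            raise ConfigurationError(
                f"unknown initial_state {spec.initial_state!r}"
            )
        # the down-jump lands at the cycle's smallest fast coordinate
        return lc.samples[int(np.argmin(lc.samples[:, 0]))].copy()
    return np.asarray(spec.initial_state, dtype=float)


def simulate_train(
    system: PlanarSlowFastSystem,
    lc: LimitCycle,
    spec: PulseTrainSpec,
    tol: float = 1e-9,
    record: bool = False,
    refractory_fraction: float = DEFAULT_REFRACTORY_FRACTION,
) -> TrainResult:
    """Integrate the kicked flow and count seizure transitions.

    Pulses are exact state jumps along the system's pulse direction between
    integration segments.  Seizures are event-located upward crossings of
    fast = 0, de-duplicated by a refractory window of
    ``refractory_fraction * T``.
    """
    intervals = generate_intervals(spec)
    pulse_times = np.cumsum(intervals)
    z = _initial_state(lc, spec)
    refractory = refractory_fraction * lc.period

    def ev(t, s):
        return s[0]

    ev.direction = 1.0

    t_now = 0.0
    seizures = []
    rec_t, rec_z = [0.0], [z.copy()]
    i_pulse = 0
    last = -np.inf
    while t_now < spec.duration:
        t_next = min(
            pulse_times[i_pulse] if i_pulse < len(pulse_times) else spec.duration,
            spec.duration,
        )
        if t_next > t_now:
            try:
                traj = integrate(system, z, t_next - t_now, tol=tol, events=ev)
            except IntegrationError as exc:
                raise IntegrationError(
                    f"integration failed after pulse {i_pulse}: {exc}",
                    t_reached=t_now + (exc.t_reached or 0.0),
                ) from exc
            for tc in traj._scipy.t_events[0]:
                tc_abs = t_now + tc
                if tc_abs - last >= refractory:
                    seizures.append(tc_abs)
                    last = tc_abs
            z = traj.end
            if record:
                rec_t.append(t_next)
                rec_z.append(z.copy())
        t_now = t_next
        if i_pulse < len(pulse_times) and t_now >= pulse_times[i_pulse] - 1e-12:
            before = z[0]
            z = z + spec.amplitude * system.pulse_direction
            # a kick across v = 0 is itself a transition to seizure
            if before < 0.0 <= z[0] and t_now - last >= refractory:
                seizures.append(t_now)
                last = t_now
            i_pulse += 1
            if record:
                rec_t.append(t_now)
                rec_z.append(z.copy())
    trajectory = (
        Trajectory(np.array(rec_t), np.array(rec_z), tol) if record else None
    )
    return TrainResult(
        seizure_count=len(seizures),
        seizure_times=np.array(seizures),
        pulse_times=pulse_times[:i_pulse],
        final_state=z,
        trajectory=trajectory,
    )


def seizure_rate_change(count: int, duration: float, T: float) -> float:
    """Delta: perturbed seizure count over the unperturbed count
    (one seizure per period) for the same duration."""
    if duration < T:
        raise ConfigurationError("duration must cover at least one period")
    return count / (duration / T)


@dataclass
class SweepGrid:
    """Seizure-rate change over an (A, T_s) grid.

    ``delta`` has shape (len(A_values), len(Ts_values)) and holds the mean
    over replicates; invalid cells are NaN and listed in ``failures``.
    """

    A_values: np.ndarray
    Ts_values: np.ndarray
    delta: np.ndarray
    counts: np.ndarray  # (nA, nTs, reps)
    sigma_policy: Union[float, str]
    reps: int
    seed: Optional[int]
    duration_periods: float
    failures: list = field(default_factory=list)


def _cell_sigma(sigma_policy, Ts: float) -> float:
    if sigma_policy in (0, 0.0, None):
        return 0.0
    if sigma_policy == "0.05Ts":
        return 0.05 * Ts
    return float(sigma_policy)


def sweep(
    system: PlanarSlowFastSystem,
    lc: LimitCycle,
    A_grid,
    Ts_grid,
    sigma_policy: Union[float, str] = 0.0,
    reps: int = 1,
    seed: Optional[int] = None,
    duration_periods: float = 20.0,
    tol: float = 1e-9,
    amplitude_cap: Optional[float] = None,
    progress: bool = False,
) -> SweepGrid:
    """Seizure-rate change Delta over an amplitude x interval grid.

    ``sigma_policy`` is 0 (periodic trains) or '0.05Ts' (jitter with
    sigma = 0.05 T_s, replicated ``reps`` times per cell).  Seeds for every
    cell and replicate derive deterministically from ``seed``.
    """
    A_grid = np.asarray(A_grid, dtype=float)
    Ts_grid = np.asarray(Ts_grid, dtype=float)
    if amplitude_cap is not None and np.any(A_grid > amplitude_cap):
        raise ConfigurationError(
            f"amplitudes exceed the model's cap {amplitude_cap}"
        )
    stochastic = not (sigma_policy in (0, 0.0, None))
    if stochastic and seed is None:
        raise ConfigurationError("a seed is required for jittered sweeps")
    n_reps = reps if stochastic else 1
    duration = duration_periods * lc.period
    counts = np.full((len(A_grid), len(Ts_grid), n_reps), -1, dtype=int)
    delta = np.full((len(A_grid), len(Ts_grid)), np.nan)
    failures = []
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    cell_seeds = ss.generate_state(len(A_grid) * len(Ts_grid) * n_reps) % (2 ** 31)
    it = 0
    cells = [(i, j) for i in range(len(A_grid)) for j in range(len(Ts_grid))]
    if progress:
        try:
            from tqdm import tqdm

            cells = tqdm(cells, desc="sweep")
        except ImportError:  # pragma: no cover
            pass
    for i, j in cells:
        A, Ts = float(A_grid[i]), float(Ts_grid[j])
        sig = _cell_sigma(sigma_policy, Ts)
        cell = []
        for r in range(n_reps):
            sd = int(cell_seeds[it]) if stochastic else None
            it += 1
            try:
                res = simulate_train(
                    system, lc,
                    PulseTrainSpec(A, Ts, duration, sigma=sig, seed=sd),
                    tol=tol,
                )
                counts[i, j, r] = res.seizure_count
                cell.append(seizure_rate_change(res.seizure_count, duration,
                                                lc.period))
            except (IntegrationError, ConfigurationError) as exc:
                failures.append({"A": A, "Ts": Ts, "rep": r, "error": str(exc)})
        if cell:
            delta[i, j] = float(np.mean(cell))
    return SweepGrid(
        A_values=A_grid,
        Ts_values=Ts_grid,
        delta=delta,
        counts=counts,
        sigma_policy=sigma_policy,
        reps=n_reps,
        seed=seed,
        duration_periods=duration_periods,
        failures=failures,
    )


def locking_onset(
    system: PlanarSlowFastSystem,
    lc: LimitCycle,
    A_grid,
    Ts_grid,
    duration_periods: float = 20.0,
    tol: float = 1e-9,
    stop_at_first: bool = True,
) -> tuple:
    """Smallest amplitude whose periodic-train row contains a Delta = 0 cell.

    Scans amplitudes in ascending order; with ``stop_at_first`` the scan
    stops as soon as a fully suppressing cell is found (rows above the onset
    are then left unevaluated).  Returns (onset amplitude or None, partial
    SweepGrid).
    """
    A_grid = np.sort(np.asarray(A_grid, dtype=float))
    Ts_grid = np.asarray(Ts_grid, dtype=float)
    duration = duration_periods * lc.period
    delta = np.full((len(A_grid), len(Ts_grid)), np.nan)
    onset = None
    for i, A in enumerate(A_grid):
        for j, Ts in enumerate(Ts_grid):
            res = simulate_train(
                system, lc,
                PulseTrainSpec(float(A), float(Ts), duration), tol=tol,
            )
            delta[i, j] = seizure_rate_change(res.seizure_count, duration,
                                              lc.period)
        if np.any(delta[i] == 0.0):
            onset = float(A)
            if stop_at_first:
                break
    grid = SweepGrid(
        A_values=A_grid, Ts_values=Ts_grid, delta=delta,
        counts=np.full((len(A_grid), len(Ts_grid), 1), -1),
        sigma_policy=0.0, reps=1, seed=None,
        duration_periods=duration_periods,
    )
    return onset, grid
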