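"""Planar slow-fast vector fields and the bundled epilepsy models.

A planar slow-fast system is

    x' = f(x, y),      y' = eps * g(x, y),      0 <= eps << 1,

with a fast variable ``x`` and a slow variable ``y``.  Two conventions are
supported and recorded per instance in ``epsilon_absorbed``:

* explicit epsilon: ``slow_rhs`` is the bare ``g`` and the integrator
  multiplies by ``epsilon`` (used by the test-fixture oscillator);
* absorbed epsilon: the model's own small time constant (``tau_a`` for the
  phenomenor, ``tau_z`` for the reduced epileptor) already sits inside
  ``slow_rhs``, and ``epsilon`` merely records the effective timescale ratio
  for the singular-perturbation operations.

Two epilepsy models are bundled.  The *phenomenor* couples a firing rate v
to a slowly drifting excitability a,

    v' = -tau_x (v^3 + v^2 - a),
    a' = tau_a (tanh(c (h - v)) - a0),     h = hm * a - hn,

so that the excitability grows while v sits below the threshold h and decays
when v exceeds it (the a0 = 0.5 offset deliberately makes the response
asymmetric: about +0.5 below threshold, about -1.5 above; it is part of the
model, not a defect).  The *reduced epileptor* couples the firing rate v to a
permittivity z,

    v' = 1 + I_app - v^3 - 2 v^2 - z,
    z' = tau_z * s * (c (v - v0) + z),

with three canonical parameter rows P+, P0, P- that differ only in the slope
and position of the slow nullcline.  Delta pulses act along +v in both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional

import numpy as np

from .exceptions import ConfigurationError, DomainError

__all__ = [
    "PlanarSlowFastSystem",
    "ParameterSet",
    "PARAMETER_SETS",
    "P_PHENO",
    "P_PLUS",
    "P_ZERO",
    "P_MINUS",
    "make_phenomenor",
    "make_reduced_epileptor",
    "make_fixture_oscillator",
    "get_model",
    "load_system_from_config",
    "MODEL_DEFAULTS",
]


@dataclass(frozen=True)
class ParameterSet:
    """A named mapping of model parameters."""

    name: str
    values: Mapping[str, float]

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def require(self, keys, model: str) -> None:
        missing = [k for k in keys if k not in self.values]
        if missing:
            raise ConfigurationError(
                f"parameter set {self.name!r} is missing "
                f"{', '.join(missing)} required by the {model} model"
            )


# Canonical parameter rows.  tau_z is stored as the exact quotient.
P_PHENO = ParameterSet(
    "P_pheno",
    {"tau_x": 1.0, "tau_a": 0.001, "c": 1000.0, "hn": 0.86, "hm": 1.6, "a0": 0.5},
)
P_PLUS = ParameterSet(
    "P+", {"tau_z": 1.0 / 2857.0, "v0": -2.0, "Iapp": 3.1, "c": -4.0, "s": -1.0}
)
P_ZERO = ParameterSet(
    "P0", {"tau_z": 1.0 / 2857.0, "v0": -1.5, "Iapp": 3.1, "c": -16.0, "s": -1.0}
)
P_MINUS = ParameterSet(
    "P-", {"tau_z": 1.0 / 2857.0, "v0": -0.1, "Iapp": 3.1, "c": 2.4, "s": 1.0}
)

PARAMETER_SETS = {p.name: p for p in (P_PHENO, P_PLUS, P_ZERO, P_MINUS)}


@dataclass
class PlanarSlowFastSystem:
    """A planar vector field split into fast and slow components.

    ``fast_rhs(x, y)`` and ``slow_rhs(x, y)`` are scalar functions.  The full
    flow is ``x' = fast_rhs``, ``y' = epsilon * slow_rhs`` when
    ``epsilon_absorbed`` is False, and ``x' = fast_rhs``, ``y' = slow_rhs``
    when the timescale ratio is already folded into ``slow_rhs``.
    """

    fast_rhs: Callable[[float, float], float]
    slow_rhs: Callable[[float, float], float]
    epsilon: float
    params: Mapping[str, float]
    epsilon_absorbed: bool = True
    fast_var_name: str = "x"
    slow_var_name: str = "y"
    pulse_direction: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.0])
    )
    name: str = ""
    jacobian: Optional[Callable[[float, float], np.ndarray]] = None

    def __post_init__(self):
        if not (0.0 <= self.epsilon < 1.0):
            raise ConfigurationError(
                f"epsilon must lie in [0, 1), got {self.epsilon}"
            )
        self.pulse_direction = np.asarray(self.pulse_direction, dtype=float)
        n = np.linalg.norm(self.pulse_direction)
        if n == 0:
            raise ConfigurationError("pulse_direction must be a nonzero vector")
        self.pulse_direction = self.pulse_direction / n

    # -- evaluation ---------------------------------------------------------
    def slow_rate(self, x: float, y: float) -> float:
        """Full slow velocity y' (epsilon included whichever the convention)."""
        g = self.slow_rhs(x, y)
        return g if self.epsilon_absorbed else self.epsilon * g

    def rhs(self, t, z):
        """Right-hand side in solve_ivp form; t is ignored (autonomous)."""
        x, y = z
        return np.array([self.fast_rhs(x, y), self.slow_rate(x, y)])

    def jac(self, z, h: float = 1e-7) -> np.ndarray:
        """Jacobian of the full flow at z (analytic if available, else central FD)."""
        x, y = z
        if self.jacobian is not None:
            return self.jacobian(x, y)
        J = np.empty((2, 2))
        for j, (dx, dy) in enumerate(((h, 0.0), (0.0, h))):
            fp = self.rhs(0.0, (x + dx, y + dy))
            fm = self.rhs(0.0, (x - dx, y - dy))
            J[:, j] = (fp - fm) / (2 * h)
        return J


# ---------------------------------------------------------------------------
# Bundled models
# ---------------------------------------------------------------------------

def make_phenomenor(params: ParameterSet = P_PHENO) -> PlanarSlowFastSystem:
    """Phenomenological epilepsy model (firing rate v, excitability a)."""
    params.require(("tau_x", "tau_a", "c", "hn", "hm", "a0"), "phenomenor")
    tau_x, tau_a = params["tau_x"], params["tau_a"]
    c, hn, hm, a0 = params["c"], params["hn"], params["hm"], params["a0"]

    def fast(v, a):
        return -tau_x * (v ** 3 + v ** 2 - a)

    def slow(v, a):
        # np.tanh saturates cleanly for |c*(h-v)| large; no overflow guard needed
        return tau_a * (np.tanh(c * (hm * a - hn - v)) - a0)

    def jac(v, a):
        sech2 = 1.0 / np.cosh(np.clip(c * (hm * a - hn - v), -350.0, 350.0)) ** 2
        return np.array(
            [
                [-tau_x * (3 * v ** 2 + 2 * v), tau_x],
                [-tau_a * c * sech2, tau_a * c * hm * sech2],
            ]
        )

    return PlanarSlowFastSystem(
        fast_rhs=fast,
        slow_rhs=slow,
        epsilon=tau_a / tau_x,
        params=dict(params.values),
        epsilon_absorbed=True,
        fast_var_name="v",
        slow_var_name="a",
        pulse_direction=np.array([1.0, 0.0]),
        name="phenomenor",
        jacobian=jac,
    )


def make_reduced_epileptor(params: ParameterSet) -> PlanarSlowFastSystem:
    """Planar reduction of the epileptor (firing rate v, permittivity z)."""
    params.require(("tau_z", "v0", "Iapp", "c", "s"), "reduced epileptor")
    tau_z, v0 = params["tau_z"], params["v0"]
    Iapp, c, s = params["Iapp"], params["c"], params["s"]

    def fast(v, z):
        return 1.0 + Iapp - v ** 3 - 2 * v ** 2 - z

    def slow(v, z):
        return tau_z * s * (c * (v - v0) + z)

    def jac(v, z):
        return np.array(
            [[-3 * v ** 2 - 4 * v, -1.0], [tau_z * s * c, tau_z * s]]
        )

    return PlanarSlowFastSystem(
        fast_rhs=fast,
        slow_rhs=slow,
        epsilon=tau_z,
        params=dict(params.values),
        epsilon_absorbed=True,
        fast_var_name="v",
        slow_var_name="z",
        pulse_direction=np.array([1.0, 0.0]),
        name="epileptor",
        jacobian=jac,
    )


def make_fixture_oscillator(mu: float) -> PlanarSlowFastSystem:
    """Cubic Lienard (van der Pol type) relaxation oscillator for tests.

    x' = x - x^3/3 - y,  y' = eps * x with eps = 1/mu.  The fast nullcline is
    the cubic y = x - x^3/3, the slow nullcline the line x = 0, and the system
    is symmetric under (x, y) -> (-x, -y).
    """
    if not mu > 0:
        raise DomainError(f"stiffness mu must be positive, got {mu}")
    eps = 1.0 / mu

    def fast(x, y):
        return x - x ** 3 / 3.0 - y

    def slow(x, y):
        return x

    def jac(x, y):
        return np.array([[1.0 - x ** 2, -1.0], [eps, 0.0]])

    return PlanarSlowFastSystem(
        fast_rhs=fast,
        slow_rhs=slow,
        epsilon=eps,
        params={"mu": mu},
        epsilon_absorbed=False,
        fast_var_name="x",
        slow_var_name="y",
        pulse_direction=np.array([1.0, 0.0]),
        name="vdp-fixture",
        jacobian=jac,
    )


# ---------------------------------------------------------------------------
# Registry and configuration loading
# ---------------------------------------------------------------------------

#: Per-model defaults used by the CLI: cycle-search guess, Poincare section
#: placement (fast coordinate, crossing direction) and a slow-variable window
#: bracketing both folds for slow-manifold work.
MODEL_DEFAULTS = {
    "phenomenor": {
        "guess": (-0.9, 0.05),
        "section": (-0.8, +1),
        "y_range": (-0.05, 0.2),
        "amplitude_cap": 0.8,
    },
    "epileptor": {
        "guess": (-1.0, 3.0),
        "section": (-0.9, -1),
        "y_range": (2.0, 4.6),
        "amplitude_cap": 1.8,
    },
    "fixture": {
        "guess": (0.5, 0.0),
        "section": (1.0, +1),
        "y_range": (-1.0, 1.0),
        "amplitude_cap": None,
    },
}


def get_model(name: str, params=None) -> PlanarSlowFastSystem:
    """Build a registered model by name.

    ``params`` may be a ParameterSet, the name of a canonical set, a plain
    mapping, or (for the fixture oscillator) the stiffness mu.
    """
    if isinstance(params, str):
        if params not in PARAMETER_SETS:
            raise ConfigurationError(
                f"unknown parameter set {params!r}; "
                f"registered: {', '.join(sorted(PARAMETER_SETS))}"
            )
        params = PARAMETER_SETS[params]
    elif isinstance(params, Mapping):
        params = ParameterSet("custom", dict(params))

    if name == "phenomenor":
        return make_phenomenor(params if params is not None else P_PHENO)
    if name == "epileptor":
        if params is None:
            raise ConfigurationError(
                "the epileptor model needs a parameter set (P+, P0 or P-)"
            )
        return make_reduced_epileptor(params)
    if name == "fixture":
        mu = params["mu"] if params is not None else 100.0
        return make_fixture_oscillator(mu)
    raise ConfigurationError(
        f"unknown model {name!r}; registered models: "
        f"{', '.join(sorted(MODEL_DEFAULTS))}"
    )


def load_system_from_config(path) -> PlanarSlowFastSystem:
    """Load a user model from a YAML file.

    The file declares the two right-hand sides as expressions in the fast and
    slow variable names plus a parameter mapping, e.g.::

        fast_var: x
        slow_var: y
        fast_rhs: "x - x**3/3 - y"
        slow_rhs: "x + b"
        epsilon: 0.01
        epsilon_absorbed: false
        params: {b: 0.1}
    """
    import yaml
    import sympy as sp

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    for key in ("fast_rhs", "slow_rhs"):
        if key not in cfg:
            raise ConfigurationError(f"model config is missing {key!r}")
    xname = cfg.get("fast_var", "x")
    yname = cfg.get("slow_var", "y")
    params = dict(cfg.get("params", {}))
    x, y = sp.symbols(f"{xname} {yname}")
    syms = {xname: x, yname: y}
    psyms = {k: sp.Symbol(k) for k in params}
    local = {**syms, **psyms}
    try:
        fexpr = sp.sympify(cfg["fast_rhs"], locals=local).subs(
            {psyms[k]: v for k, v in params.items()}
        )
        gexpr = sp.sympify(cfg["slow_rhs"], locals=local).subs(
            {psyms[k]: v for k, v in params.items()}
        )
    except sp.SympifyError as exc:
        raise ConfigurationError(f"cannot parse model expressions: {exc}") from exc
    free = (fexpr.free_symbols | gexpr.free_symbols) - {x, y}
    if free:
        raise ConfigurationError(
            "model expressions reference undeclared parameters: "
            + ", ".join(sorted(str(s) for s in free))
        )
    fast = sp.lambdify((x, y), fexpr, "numpy")
    slow = sp.lambdify((x, y), gexpr, "numpy")
    jf = [sp.lambdify((x, y), sp.diff(e, v), "numpy")
          for e in (fexpr, gexpr) for v in (x, y)]
    eps = float(cfg.get("epsilon", 0.0))
    absorbed = bool(cfg.get("epsilon_absorbed", True))

    def jac(xv, yv):
        J = np.array([[jf[0](xv, yv), jf[1](xv, yv)],
                      [jf[2](xv, yv), jf[3](xv, yv)]], dtype=float)
        if not absorbed:
            J[1, :] *= eps
        return J

    return PlanarSlowFastSystem(
        fast_rhs=lambda a, b: float(fast(a, b)),
        slow_rhs=lambda a, b: float(slow(a, b)),
        epsilon=eps,
        params=params,
        epsilon_absorbed=absorbed,
        fast_var_name=xname,
        slow_var_name=yname,
        pulse_direction=np.array(cfg.get("pulse_direction", [1.0, 0.0]), dtype=float),
        name=cfg.get("name", "user-model"),
        jacobian=jac,
    )
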