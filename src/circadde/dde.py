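"""Constant-delay DDE machinery for delayed gene regulatory networks.

A :class:`DelayModel` couples linear mRNA degradation with production
terms that are products of *modulation factors* — bounded rational
functions of a single delayed regulator concentration, one per
cis-regulatory element (E-box, D-box, ROR element).  This module
provides integration (fixed-step RK4 with cubic-Hermite dense history,
a standard method-of-steps discretisation), steady states,
linearization, characteristic-equation Hopf-onset detection, and
period/amplitude scans.

Units: rates in 1/h, delays and times in h.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy import optimize

from ._kernel import rk4_delay_integrate

__all__ = [
    "ModulationFactor", "Forcing", "DelayModel", "History", "Trajectory",
    "Linearization", "HopfResult", "PeriodInfo", "IntegrationError",
    "integrate", "integrate_rhs", "steady_state", "linearize",
    "characteristic_det", "characteristic_roots", "oscillatory_abscissa",
    "find_hopf", "hopf_onset", "detect_period", "delay_scan",
    "with_param", "get_param", "param_names",
    "model_to_dict", "model_from_dict", "save_model", "load_model",
]


class IntegrationError(RuntimeError):
    """Raised when the integrator produces a non-finite state."""


# ---------------------------------------------------------------------------
# model data types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModulationFactor:
    """One cis-regulatory element's multiplicative contribution.

    With u = (kd * x_reg(t - tau) / saturation) ** exponent the factor
    evaluates to

        activator:  basal * (1 + strength * u) / (1 + u)
        inhibitor:  basal / (1 + u)

    so that vanishing regulator concentration returns exactly the basal
    rate.  ``exponent`` is the number of binding sites of this element;
    ``kd`` is an internal knock-down multiplier on the regulator
    concentration (1 = unperturbed, 0 = this input deleted).
    """

    regulator: str
    role: str  # "activator" | "inhibitor"
    delay_h: float
    exponent: int
    basal: float
    saturation: float = 1.0
    strength: float = 1.0  # fold-activation; unused for inhibitors
    kd: float = 1.0

    def __post_init__(self):
        if self.role not in ("activator", "inhibitor"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.delay_h < 0:
            raise ValueError("delay must be >= 0")
        if self.exponent <= 0:
            raise ValueError("exponent (binding-site count) must be positive")
        if self.basal < 0 or self.saturation <= 0 or self.strength < 0:
            raise ValueError("basal/saturation/strength must be positive")
        if not 0 <= self.kd:
            raise ValueError("kd must be >= 0")

    def value(self, x: float) -> float:
        """Evaluate the factor at regulator concentration ``x`` >= 0."""
        x = max(self.kd * x, 0.0)
        u = (x / self.saturation) ** self.exponent
        if self.role == "activator":
            return self.basal * (1.0 + self.strength * u) / (1.0 + u)
        return self.basal / (1.0 + u)

    def derivative(self, x: float) -> float:
        """d value / d x at regulator concentration ``x``."""
        xs = max(self.kd * x, 0.0)
        u = (xs / self.saturation) ** self.exponent
        if xs == 0.0:
            if self.exponent == 1:
                du = self.kd / self.saturation
            else:
                return 0.0
        else:
            du = self.exponent * u / xs * self.kd
        if self.role == "activator":
            dFdu = self.basal * (self.strength - 1.0) / (1.0 + u) ** 2
        else:
            dFdu = -self.basal / (1.0 + u) ** 2
        return dFdu * du


@dataclass(frozen=True)
class Forcing:
    """Smoothed square-wave multiplier s(t) on one gene's production.

    s(t) = 1 + strength inside the "on" window of length ``on_hours``
    starting at ``t0`` (mod ``period``), 1 outside; edges smoothed over
    ``smooth`` hours by logistic ramps (0 gives a hard square wave).
    """

    gene: str
    strength: float
    period: float = 24.0
    on_hours: float = 12.0
    t0: float = 12.0
    smooth: float = 0.1

    def __post_init__(self):
        if self.strength < 0:
            raise ValueError("forcing strength must be >= 0")

    def value(self, t: float) -> float:
        p = (t - self.t0) % self.period
        if self.smooth <= 0:
            g = 1.0 if p < self.on_hours else 0.0
        else:
            g = 0.0
            for k in (-1, 0, 1):
                q = p - k * self.period
                g += (1.0 / (1.0 + np.exp(-q / self.smooth))
                      * 1.0 / (1.0 + np.exp((q - self.on_hours) / self.smooth)))
        return 1.0 + self.strength * g


@dataclass
class DelayModel:
    """A delayed gene network: per-gene degradation and factor products.

    ``productions[g]`` is the ordered list of modulation factors whose
    product (times ``production_scale[g]`` and the forcing multiplier,
    if attached to g) forms the production term of gene g.  A gene with
    an empty factor list has zero production (pure decay).
    """

    variable_names: list[str]
    degradation_rates: dict[str, float]
    productions: dict[str, list[ModulationFactor]]
    production_scale: dict[str, float] = field(default_factory=dict)
    forcing: Forcing | None = None

    def __post_init__(self):
        for g in self.variable_names:
            if g not in self.degradation_rates:
                raise ValueError(f"missing degradation rate for {g}")
            if self.degradation_rates[g] <= 0:
                raise ValueError(f"degradation rate of {g} must be > 0")
            self.productions.setdefault(g, [])
            self.production_scale.setdefault(g, 1.0)
            for f in self.productions[g]:
                if f.regulator not in self.variable_names:
                    raise ValueError(
                        f"factor regulator {f.regulator!r} of {g} is not a "
                        "model variable")
        if self.forcing is not None and self.forcing.gene not in self.variable_names:
            raise ValueError("forcing gene is not a model variable")

    # -- convenience -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.variable_names)

    def index(self, gene: str) -> int:
        return self.variable_names.index(gene)

    @property
    def delays(self) -> list[float]:
        out = sorted({f.delay_h for fs in self.productions.values() for f in fs})
        return out

    @property
    def tau_max(self) -> float:
        d = self.delays
        return max(d) if d else 0.0

    def production(self, gene: str, delayed: dict | None = None,
                   x: np.ndarray | None = None, t: float = 0.0) -> float:
        """Production term of ``gene`` with all delayed regulator values
        taken from ``x`` (state vector, delayed arguments equal to the
        instantaneous ones — the steady-state convention)."""
        if x is None:
            raise ValueError("state vector required")
        fs = self.productions[gene]
        if not fs:
            return 0.0
        p = self.production_scale[gene]
        for f in fs:
            p *= f.value(x[self.index(f.regulator)])
        if self.forcing is not None and self.forcing.gene == gene:
            p *= self.forcing.value(t)
        return p

    def copy(self) -> "DelayModel":
        return DelayModel(
            list(self.variable_names),
            dict(self.degradation_rates),
            {g: list(fs) for g, fs in self.productions.items()},
            dict(self.production_scale),
            self.forcing,
        )

    # -- kernel packing ----------------------------------------------
    def _pack(self):
        n = self.n
        deg = np.array([self.degradation_rates[g] for g in self.variable_names])
        scale = np.array([self.production_scale[g] for g in self.variable_names])
        has = np.array([len(self.productions[g]) > 0
                        for g in self.variable_names])
        rows = []
        for gi, g in enumerate(self.variable_names):
            for f in self.productions[g]:
                rows.append((gi, self.index(f.regulator),
                             1 if f.role == "activator" else -1,
                             f.delay_h, float(f.exponent), f.basal,
                             f.strength, f.saturation, f.kd))
        if rows:
            arr = np.array(rows, dtype=float)
        else:
            arr = np.zeros((0, 9))
        fg = arr[:, 0].astype(np.int64)
        fr = arr[:, 1].astype(np.int64)
        frole = arr[:, 2].astype(np.int64)
        if self.forcing is None:
            force = (-1, 0.0, 24.0, 12.0, 12.0, 0.1)
        else:
            fo = self.forcing
            force = (self.index(fo.gene), fo.strength, fo.period,
                     fo.on_hours, fo.t0, fo.smooth)
        return (deg, scale, fg, fr, frole, arr[:, 3], arr[:, 4], arr[:, 5],
                arr[:, 6], arr[:, 7], arr[:, 8], force, has)


# ---------------------------------------------------------------------------
# history and trajectory
# ---------------------------------------------------------------------------

class History:
    """Initial data on [-tau_max, 0]: constant vector or function of t."""

    def __init__(self, values=None, function=None, tmin=-np.inf):
        if (values is None) == (function is None):
            raise ValueError("give either a constant vector or a function")
        self.values = None if values is None else np.asarray(values, float)
        self.function = function
        self.tmin = -np.inf if values is not None else tmin

    @classmethod
    def constant(cls, values) -> "History":
        return cls(values=values)

    @classmethod
    def from_function(cls, fn, tmin) -> "History":
        return cls(function=fn, tmin=tmin)

    def __call__(self, t: float) -> np.ndarray:
        if self.values is not None:
            return self.values
        return np.asarray(self.function(t), float)


@dataclass
class Trajectory:
    """Dense DDE solution on a uniform grid with Hermite interpolation."""

    times: np.ndarray
    states: np.ndarray
    derivs: np.ndarray
    variable_names: list[str]

    @property
    def step(self) -> float:
        return float(self.times[1] - self.times[0])

    def column(self, gene: str) -> np.ndarray:
        return self.states[:, self.variable_names.index(gene)]

    def __call__(self, t):
        """Evaluate the cubic-Hermite interpolant at time(s) t."""
        t = np.atleast_1d(np.asarray(t, float))
        h = self.step
        s = (t - self.times[0]) / h
        i = np.clip(np.floor(s).astype(int), 0, len(self.times) - 2)
        u = (s - i)[:, None]
        x0, x1 = self.states[i], self.states[i + 1]
        d0, d1 = self.derivs[i], self.derivs[i + 1]
        h00 = (1 + 2 * u) * (1 - u) ** 2
        h10 = u * (1 - u) ** 2
        h01 = u ** 2 * (3 - 2 * u)
        h11 = u ** 2 * (u - 1)
        out = h00 * x0 + h10 * h * d0 + h01 * x1 + h11 * h * d1
        return out[0] if out.shape[0] == 1 and np.ndim(t) == 0 else out

    def to_dataframe(self):
        import pandas as pd
        df = pd.DataFrame(self.states, columns=self.variable_names)
        df.insert(0, "time_h", self.times)
        return df

    def to_csv(self, path):
        self.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def _choose_step(model_delays, step):
    pos = [d for d in model_delays if d > 0]
    if step is not None:
        h = float(step)
    else:
        h = min(0.1, min(pos) / 4.0) if pos else 0.05
    if pos and h > min(pos):
        raise ValueError("step must not exceed the smallest positive delay")
    return h


def integrate(model: DelayModel, history, t_end: float, *,
              step: float | None = None, t_start_history: float | None = None
              ) -> Trajectory:
    """Integrate ``model`` from t=0 to ``t_end`` with the given history.

    ``history`` may be a :class:`History`, a constant state vector, or a
    callable of time.  Raises :class:`IntegrationError` (naming the time
    of failure) if the state becomes non-finite, and ``ValueError`` when
    the history does not cover [-tau_max, 0].
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if not isinstance(history, History):
        if callable(history):
            history = History.from_function(history, tmin=-np.inf)
        else:
            history = History.constant(history)
    tau_max = model.tau_max
    if history.tmin > -tau_max:
        raise ValueError(
            f"history covers [{history.tmin}, 0] but the model needs "
            f"[-{tau_max}, 0]")
    h = _choose_step(model.delays, step)
    n_pre = max(int(np.ceil(tau_max / h)) + 1, 1)
    n_steps = int(np.ceil(t_end / h))
    n = model.n
    X = np.zeros((n_pre + n_steps + 1, n))
    D = np.zeros_like(X)
    t0 = -n_pre * h
    for i in range(n_pre + 1):
        X[i] = history(t0 + i * h)
    Dh = np.zeros((n_pre + 1, n))
    if history.values is None:  # finite-difference the history derivative
        eps = 1e-6
        for i in range(n_pre + 1):
            t = t0 + i * h
            Dh[i] = (history(min(t + eps, 0.0)) - history(t - eps)) / (
                min(t + eps, 0.0) - (t - eps))
    D[:n_pre + 1] = Dh
    (deg, scale, fg, fr, frole, ftau, fexp, fbas, ffold, fsat, fkd,
     force, has) = model._pack()
    bad = rk4_delay_integrate(h, n_pre, n_steps, X, D, Dh, deg, scale,
                              fg, fr, frole, ftau, fexp, fbas, ffold,
                              fsat, fkd, force[0], force[1], force[2],
                              force[3], force[4], force[5], has)
    if bad:
        raise IntegrationError(
            f"non-finite state at t = {t0 + bad * h:.3f} h")
    times = t0 + h * np.arange(len(X))
    keep = times >= -1e-12
    return Trajectory(times[keep], X[keep], D[keep], list(model.variable_names))


def integrate_rhs(rhs, delays, history, t_end, n_var, *, step=0.05):
    """Generic method-of-steps RK4 for ``x'(t) = rhs(t, x, Z)``.

    ``Z`` has shape (len(delays), n_var) holding x(t - tau_j).  Pure
    Python reference path, used to cross-check the compiled kernel and
    to integrate systems (e.g. the linear test DDE) that are not
    products of modulation factors.
    """
    delays = [float(d) for d in delays]
    if not isinstance(history, History):
        history = (History.from_function(history, -np.inf) if callable(history)
                   else History.constant(history))
    h = _choose_step(delays, step)
    tau_max = max(delays) if delays else 0.0
    n_pre = max(int(np.ceil(tau_max / h)) + 1, 1)
    n_steps = int(np.ceil(t_end / h))
    X = np.zeros((n_pre + n_steps + 1, n_var))
    D = np.zeros_like(X)
    t0 = -n_pre * h
    for i in range(n_pre + 1):
        X[i] = history(t0 + i * h)
    Dh = np.zeros((n_pre + 1, n_var))
    if history.values is None:
        eps = 1e-6
        for i in range(n_pre + 1):
            t = t0 + i * h
            Dh[i] = (history(min(t + eps, 0.0)) - history(t - eps)) / (
                min(t + eps, 0.0) - (t - eps))
    D[:n_pre + 1] = Dh

    def lookup(tq, i_last):
        s = (tq - t0) / h
        i = int(np.clip(np.floor(s), 0, i_last - 1))
        u = s - i
        h00 = (1 + 2 * u) * (1 - u) ** 2
        h10 = u * (1 - u) ** 2
        h01 = u * u * (3 - 2 * u)
        h11 = u * u * (u - 1)
        d0 = Dh[i] if i + 1 <= n_pre else D[i]
        d1 = Dh[i + 1] if i + 1 <= n_pre else D[i + 1]
        return h00 * X[i] + h10 * h * d0 + h01 * X[i + 1] + h11 * h * d1

    def f(t, y, i_last):
        if delays:
            Z = np.array([y if d == 0 else lookup(t - d, i_last)
                          for d in delays])
        else:
            Z = np.zeros((0, n_var))
        return np.asarray(rhs(t, y, Z), float)

    for i in range(n_pre, n_pre + n_steps):
        t = t0 + i * h
        y = X[i]
        k1 = f(t, y, i)
        D[i] = k1
        k2 = f(t + h / 2, y + h / 2 * k1, i)
        k3 = f(t + h / 2, y + h / 2 * k2, i)
        k4 = f(t + h, y + h * k3, i)
        X[i + 1] = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(X[i + 1])):
            raise IntegrationError(f"non-finite state at t = {t + h:.3f} h")
    D[-1] = f(t0 + (len(X) - 1) * h, X[-1], len(X) - 1)
    times = t0 + h * np.arange(len(X))
    keep = times >= -1e-12
    names = [f"x{j}" for j in range(n_var)]
    return Trajectory(times[keep], X[keep], D[keep], names)


# ---------------------------------------------------------------------------
# steady states and linearization
# ---------------------------------------------------------------------------

def steady_state(model: DelayModel, guess=None) -> np.ndarray:
    """Fixed point with delayed arguments equal to instantaneous ones."""
    if model.forcing is not None and model.forcing.strength > 0:
        raise ValueError("steady states are defined for autonomous models")
    n = model.n
    if guess is None:
        guess = np.ones(n)
    guess = np.asarray(guess, float)

    def res(x):
        return np.array([
            model.production(g, x=np.maximum(x, 0.0))
            - model.degradation_rates[g] * x[model.index(g)]
            for g in model.variable_names])

    sol = optimize.root(res, guess, method="hybr")
    x = sol.x
    if np.max(np.abs(res(x))) > 1e-8 or np.any(x < -1e-9):
        raise RuntimeError(
            "steady-state search did not converge from the given guess; "
            "try a multi-start over different initial states")
    return np.maximum(x, 0.0)


@dataclass
class Linearization:
    """Linearized dynamics at a fixed point.

    ``A0`` holds the instantaneous part (diagonal -d_i plus undelayed
    partials); ``delay_matrices`` maps each distinct positive delay to
    the matrix of partials with respect to the state delayed by it.
    A0 + sum of the delay matrices equals the Jacobian of the
    undelayed (tau -> 0) vector field.
    """

    x_star: np.ndarray
    A0: np.ndarray
    delay_matrices: list[tuple[float, np.ndarray]]

    @property
    def n(self) -> int:
        return self.A0.shape[0]


def linearize(model: DelayModel, x_star) -> Linearization:
    x_star = np.asarray(x_star, float)
    resid = max(abs(model.production(g, x=x_star)
                    - model.degradation_rates[g] * x_star[model.index(g)])
                for g in model.variable_names)
    scale = max(1.0, float(np.max(np.abs(x_star))))
    if resid > 1e-6 * scale:
        raise ValueError(f"x_star is not a steady state (residual {resid:.2e})")
    n = model.n
    A0 = np.diag([-model.degradation_rates[g] for g in model.variable_names])
    mats: dict[float, np.ndarray] = {}
    for gi, g in enumerate(model.variable_names):
        fs = model.productions[g]
        if not fs:
            continue
        vals = [f.value(x_star[model.index(f.regulator)]) for f in fs]
        for k, f in enumerate(fs):
            ri = model.index(f.regulator)
            dF = f.derivative(x_star[ri])
            others = model.production_scale[g] * float(
                np.prod([w for j, w in enumerate(vals) if j != k]))
            contrib = others * dF
            tau = round(float(f.delay_h), 12)
            if tau == 0.0:
                A0[gi, ri] += contrib
            else:
                mats.setdefault(tau, np.zeros((n, n)))[gi, ri] += contrib
    return Linearization(x_star, A0, sorted(mats.items()))


# ---------------------------------------------------------------------------
# characteristic equation and Hopf onset
# ---------------------------------------------------------------------------

def characteristic_det(lin: Linearization, lam: complex) -> complex:
    M = lam * np.eye(lin.n, dtype=complex) - lin.A0.astype(complex)
    for tau, A in lin.delay_matrices:
        M -= A * np.exp(-lam * tau)
    return complex(np.linalg.det(M))


def characteristic_roots(lin: Linearization, *, re_range=(-0.6, 0.4),
                         omega_max=2.5, n_re=5, n_im=22,
                         tol=1e-11) -> list[complex]:
    """Roots of det(lam I - A0 - sum A_tau e^(-lam tau)) near the axis.

    Newton iteration (secant derivative) from a grid of seeds over the
    strip Re in ``re_range``, 0 < Im <= ``omega_max``.  Returns distinct
    roots sorted by descending real part.
    """
    seeds = [complex(a, b)
             for a in np.linspace(*re_range, n_re)
             for b in np.linspace(0.02, omega_max, n_im)]
    roots: list[complex] = []
    for lam in seeds:
        for _ in range(40):
            if abs(lam) > 25.0:  # Newton escaped the region of interest
                break
            fval = characteristic_det(lin, lam)
            dl = 1e-7 * (1.0 + abs(lam))
            fp = (characteristic_det(lin, lam + dl)
                  - characteristic_det(lin, lam - dl)) / (2 * dl)
            if fp == 0:
                break
            step = fval / fp
            lam = lam - step
            if abs(step) < tol:
                break
        else:
            continue
        if abs(characteristic_det(lin, lam)) > 1e-7:
            continue
        lam = complex(lam.real, abs(lam.imag))
        if lam.imag > omega_max + 0.5 or lam.real < re_range[0] - 0.5:
            continue
        if all(abs(lam - r) > 1e-6 for r in roots):
            roots.append(lam)
    return sorted(roots, key=lambda z: -z.real)


def oscillatory_abscissa(lin: Linearization, omega_min=1e-3, **kw) -> float:
    """Largest real part among characteristic roots with frequency > 0."""
    roots = [r for r in characteristic_roots(lin, **kw)
             if r.imag > omega_min]
    return max((r.real for r in roots), default=-np.inf)


@dataclass
class HopfResult:
    found: bool
    critical_value: float | None = None
    omega: float | None = None
    period_at_onset: float | None = None


def find_hopf(lin_for, search_range, *, n_grid=25, omega_max=2.5) -> HopfResult:
    """Smallest parameter value in ``search_range`` at which a
    characteristic root with positive frequency crosses into the right
    half-plane.  ``lin_for(p)`` must return a Linearization."""
    lo, hi = search_range
    grid = np.linspace(lo, hi, n_grid)
    vals = []
    for p in grid:
        try:
            vals.append(oscillatory_abscissa(lin_for(p), omega_max=omega_max))
        except Exception:
            vals.append(np.nan)
    for a, b, va, vb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if not (np.isfinite(va) and np.isfinite(vb)):
            continue
        if va < 0 <= vb or vb < 0 <= va:
            f = lambda p: oscillatory_abscissa(lin_for(p), omega_max=omega_max)
            pc = optimize.brentq(f, a, b, xtol=1e-6)
            roots = [r for r in characteristic_roots(lin_for(pc),
                                                     omega_max=omega_max)
                     if r.imag > 1e-3]
            root = max(roots, key=lambda z: z.real)
            return HopfResult(True, float(pc), float(root.imag),
                              float(2 * np.pi / root.imag))
    return HopfResult(False)


def hopf_onset(model: DelayModel, parameter: str, search_range,
               guess=None, **kw) -> HopfResult:
    """Hopf-onset scan of a named model parameter (see :func:`with_param`).

    Returns an explicit "not found" result rather than raising when no
    onset lies in the range.
    """
    state = {"guess": np.ones(model.n) if guess is None else np.asarray(guess)}

    def lin_for(p):
        m = with_param(model, parameter, p)
        xs = steady_state(m, state["guess"])
        state["guess"] = xs
        return linearize(m, xs)

    return find_hopf(lin_for, search_range, **kw)


# ---------------------------------------------------------------------------
# parameter addressing
# ---------------------------------------------------------------------------

_FIELD = {"tau": "delay_h", "basal": "basal", "fold": "strength",
          "sat": "saturation", "kd": "kd"}


def with_param(model: DelayModel, name: str, value: float) -> DelayModel:
    """Copy of ``model`` with one named parameter replaced.

    Names: ``deg:<gene>``, ``scale:<gene>``, or per-factor
    ``tau|basal|fold|sat|kd:<gene>:<regulator>``.
    """
    parts = name.split(":")
    m = model.copy()
    if parts[0] == "deg":
        m.degradation_rates[parts[1]] = float(value)
    elif parts[0] == "scale":
        m.production_scale[parts[1]] = float(value)
    elif parts[0] in _FIELD:
        kind, gene, reg = parts
        fs = m.productions[gene]
        hit = [i for i, f in enumerate(fs) if f.regulator == reg]
        if not hit:
            raise KeyError(f"no factor of {gene} regulated by {reg}")
        fs[hit[0]] = replace(fs[hit[0]], **{_FIELD[kind]: float(value)})
    else:
        raise KeyError(f"unknown parameter {name!r}")
    return m


def get_param(model: DelayModel, name: str) -> float:
    parts = name.split(":")
    if parts[0] == "deg":
        return model.degradation_rates[parts[1]]
    if parts[0] == "scale":
        return model.production_scale[parts[1]]
    kind, gene, reg = parts
    for f in model.productions[gene]:
        if f.regulator == reg:
            return getattr(f, _FIELD[kind])
    raise KeyError(name)


def param_names(model: DelayModel, kinds=("deg", "tau", "basal", "fold", "sat")
                ) -> list[str]:
    out = []
    for g in model.variable_names:
        if "deg" in kinds:
            out.append(f"deg:{g}")
        for f in model.productions[g]:
            for kind in ("tau", "basal", "fold", "sat"):
                if kind not in kinds:
                    continue
                if kind == "fold" and f.role != "activator":
                    continue
                if kind == "tau" and f.delay_h == 0:
                    continue
                out.append(f"{kind}:{g}:{f.regulator}")
    return out


# ---------------------------------------------------------------------------
# period detection and scans
# ---------------------------------------------------------------------------

@dataclass
class PeriodInfo:
    oscillating: bool
    period_h: float | None
    rel_amplitude: float
    peak_times: np.ndarray
    maximum: float
    minimum: float
    status: str = "ok"  # "ok" | "undetermined"


def _refined_peaks(t, x):
    """Interior local maxima with parabolic sub-grid refinement."""
    idx = np.flatnonzero((x[1:-1] >= x[:-2]) & (x[1:-1] > x[2:])) + 1
    peaks, heights = [], []
    h = t[1] - t[0]
    for i in idx:
        a, b, c = x[i - 1], x[i], x[i + 1]
        denom = a - 2 * b + c
        off = 0.0 if denom == 0 else 0.5 * (a - c) / denom
        off = np.clip(off, -0.5, 0.5)
        peaks.append(t[i] + off * h)
        heights.append(b - 0.25 * (a - c) * off)
    return np.array(peaks), np.array(heights)


def detect_period(traj: Trajectory, variable: str,
                  transient_fraction: float = 0.7,
                  amp_threshold: float = 1e-3,
                  cv_threshold: float = 0.01) -> PeriodInfo:
    """Period, relative amplitude, and peak times of a trajectory column.

    The leading ``transient_fraction`` of the trajectory is discarded.
    Oscillating requires relative peak-to-trough amplitude above
    ``amp_threshold`` and a peak-spacing coefficient of variation below
    ``cv_threshold``; fewer than 3 post-transient peaks yields an
    "undetermined" result.
    """
    x = traj.column(variable)
    t = traj.times
    keep = t >= t[0] + transient_fraction * (t[-1] - t[0])
    t, x = t[keep], x[keep]
    mx, mn, mean = float(x.max()), float(x.min()), float(x.mean())
    rel = (mx - mn) / (2 * mean) if mean > 0 else mx - mn
    peaks, _ = _refined_peaks(t, x)
    if rel <= amp_threshold:
        return PeriodInfo(False, None, rel, peaks, mx, mn)
    if len(peaks) < 3:
        return PeriodInfo(False, None, rel, peaks, mx, mn, "undetermined")
    gaps = np.diff(peaks)
    cv = gaps.std() / gaps.mean()
    period = float(gaps.mean())
    osc = bool(rel > amp_threshold and cv < cv_threshold)
    return PeriodInfo(osc, period if osc else None, rel, peaks, mx, mn)


def delay_scan(model: DelayModel, parameter: str, grid, *,
               variable: str | None = None, t_end: float = 480.0,
               history=None, step=None):
    """Simulate + detect once per grid value of a named parameter.

    Returns a DataFrame with value, oscillating, period_h, max, min.
    """
    import pandas as pd
    grid = np.asarray(grid, float)
    if np.any(np.diff(grid) < 0):
        raise ValueError("grid must be sorted")
    variable = variable or model.variable_names[0]
    rows = []
    for v in grid:
        m = with_param(model, parameter, v)
        hist = history
        if hist is None:
            try:
                hist = steady_state(m) + 0.1
            except RuntimeError:
                hist = np.ones(m.n)
        traj = integrate(m, hist, t_end, step=step)
        info = detect_period(traj, variable)
        rows.append({"value": v, "oscillating": info.oscillating,
                     "period_h": info.period_h, "max": info.maximum,
                     "min": info.minimum,
                     "rel_amplitude": info.rel_amplitude})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# serialization (units: rates 1/h, delays h)
# ---------------------------------------------------------------------------

def model_to_dict(model: DelayModel) -> dict:
    return {
        "units": {"rates": "1/h", "delays": "h"},
        "variables": list(model.variable_names),
        "degradation_rates": {g: float(r)
                              for g, r in model.degradation_rates.items()},
        "production_scale": {g: float(s)
                             for g, s in model.production_scale.items()},
        "productions": {
            g: [{"regulator": f.regulator, "role": f.role,
                 "delay_h": float(f.delay_h), "exponent": int(f.exponent),
                 "basal": float(f.basal), "saturation": float(f.saturation),
                 "strength": float(f.strength), "kd": float(f.kd)}
                for f in fs]
            for g, fs in model.productions.items()},
        "forcing": None if model.forcing is None else {
            "gene": model.forcing.gene, "strength": model.forcing.strength,
            "period": model.forcing.period, "on_hours": model.forcing.on_hours,
            "t0": model.forcing.t0, "smooth": model.forcing.smooth},
    }


def model_from_dict(d: dict) -> DelayModel:
    forcing = None
    if d.get("forcing"):
        forcing = Forcing(**d["forcing"])
    return DelayModel(
        list(d["variables"]),
        {g: float(r) for g, r in d["degradation_rates"].items()},
        {g: [ModulationFactor(**f) for f in fs]
         for g, fs in d["productions"].items()},
        {g: float(s) for g, s in d.get("production_scale", {}).items()},
        forcing,
    )


def save_model(model: DelayModel, path):
    path = str(path)
    d = model_to_dict(model)
    with open(path, "w") as fh:
        if path.endswith(".json"):
            json.dump(d, fh, indent=1)
        else:
            yaml.safe_dump(d, fh, sort_keys=False)


def load_model(path) -> DelayModel:
    path = str(path)
    with open(path) as fh:
        d = json.load(fh) if path.endswith(".json") else yaml.safe_load(fh)
    return model_from_dict(d)
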