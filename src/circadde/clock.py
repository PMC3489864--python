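"""Builders for the liver core-clock DDE models.

Three models of increasing size: delayed *Per2* self-inhibition (one
variable), the *Bmal1*–*Rev-erbα* nuclear-receptor loop (two
variables), and the six-gene network (*Bmal1*, *Rev-erbα*, *Per2*,
*Cry1*, *Rorg*, *Dbp*) whose production terms are products of
modulation factors, one per cis-regulatory element.  The regulators
are Bmal1 (E-box activator), Per2 (E-box inhibitor), Rev-erbα (RRE
inhibitor, with ROR activation folded in by antiphase synergy) and Dbp
(D-box activator, with E4BP4 folded in likewise); Cry1 and Rorg are
output genes that do not feed back.

Also here: knock-down and light-dark forcing transformations,
modulation-factor traces along a limit cycle, and calibration of the
small models to the observed 24 h rhythm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .dde import (DelayModel, Forcing, ModulationFactor, Trajectory,
                  detect_period, integrate, steady_state)

__all__ = [
    "GENES", "CCE_SITES", "CoreClockParams", "ModulatorTrace",
    "build_per2_model", "calibrate_per2_model",
    "build_nr_loop_model", "calibrate_nr_loop_model",
    "build_core_clock_model", "default_core_params",
    "modulation_trace", "apply_knockdown", "apply_ld_forcing",
    "limit_cycle", "peak_phase_of", "LN2",
]

LN2 = float(np.log(2.0))

GENES = ["Bmal1", "Rev-erba", "Per2", "Cry1", "Rorg", "Dbp"]

#: cis-regulatory layout: per gene, (element, regulator, role, site count)
CCE_SITES: dict[str, list[tuple[str, str, str, int]]] = {
    "Bmal1":    [("RRE",  "Rev-erba", "inhibitor", 2)],
    "Rev-erba": [("Ebox", "Bmal1",    "activator", 3),
                 ("Ebox", "Per2",     "inhibitor", 3)],
    "Per2":     [("Ebox", "Bmal1",    "activator", 2),
                 ("Ebox", "Per2",     "inhibitor", 2),
                 ("Dbox", "Dbp",      "activator", 1)],
    "Cry1":     [("Ebox", "Bmal1",    "activator", 1),
                 ("Ebox", "Per2",     "inhibitor", 1),
                 ("Dbox", "Dbp",      "activator", 1),
                 ("RRE",  "Rev-erba", "inhibitor", 2)],
    "Rorg":     [("Ebox", "Bmal1",    "activator", 2),
                 ("Ebox", "Per2",     "inhibitor", 2),
                 ("Dbox", "Dbp",      "activator", 1),
                 ("RRE",  "Rev-erba", "inhibitor", 1)],
    "Dbp":      [("Ebox", "Bmal1",    "activator", 3),
                 ("Ebox", "Per2",     "inhibitor", 3)],
}

#: literature anchors: mRNA half-lives [h] and regulatory delays [h]
DEFAULT_HALFLIVES = {"Bmal1": 2.0, "Rev-erba": 1.5, "Per2": 2.8,
                     "Cry1": 5.0, "Rorg": 4.0, "Dbp": 1.3}
DEFAULT_DELAYS = {"Bmal1": 4.0, "Per2": 8.4, "Rev-erba": 1.0, "Dbp": 1.0}


@dataclass
class CoreClockParams:
    """Parameters of the six-variable model.

    ``delays`` are per-regulator (the lag between a gene's mRNA and its
    regulatory action); entries for the output genes Cry1/Rorg are
    accepted but unused since they regulate nothing.  ``factors`` maps
    (target gene, regulator) to the rational-form constants of that
    modulation factor.
    """

    degradation_rates: dict[str, float] = field(default_factory=lambda: {
        g: LN2 / hl for g, hl in DEFAULT_HALFLIVES.items()})
    delays: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DELAYS))
    factors: dict[tuple[str, str], dict] = field(default_factory=dict)
    production_scale: dict[str, float] = field(
        default_factory=lambda: {g: 1.0 for g in GENES})

    def factor_constants(self, gene: str, reg: str) -> dict:
        return self.factors.get((gene, reg),
                                {"basal": 1.0, "strength": 5.0,
                                 "saturation": 1.0})


def default_core_params() -> CoreClockParams:
    return CoreClockParams()


# ---------------------------------------------------------------------------
# one-variable Per2 self-inhibition
# ---------------------------------------------------------------------------

def build_per2_model(degradation: float = LN2 / 2.8, basal: float = 90.0,
                     saturation: float = 1.0, delay_h: float = 8.0,
                     exponent: int = 2) -> DelayModel:
    """Delayed self-inhibition of Per2 through its two E-box elements:

        dP/dt = b / (1 + (P(t - tau)/s)^2) - d P
    """
    if exponent != 2:
        warnings.warn("Per2 carries two E-box-like elements; "
                      f"exponent={exponent} deviates from the biology")
    f = ModulationFactor("Per2", "inhibitor", delay_h, exponent,
                         basal, saturation)
    return DelayModel(["Per2"], {"Per2": degradation}, {"Per2": [f]})


def calibrate_per2_model(period_target: float = 24.0,
                         amplitude_target: float = 1.0,
                         delay_h: float = 8.0,
                         halflife_bounds: tuple[float, float] = (1.5, 4.0),
                         basal_bounds: tuple[float, float] = (5.0, 300.0),
                         ) -> tuple[DelayModel, dict]:
    """Calibrate (d, b) so the model at ``delay_h`` oscillates with the
    target period and an order-one relative amplitude.

    The degradation rate is constrained to the published Per2 mRNA
    half-life range; the basal rate is searched in a bounded box (the
    period saturates logarithmically in b, so an upper bound is part of
    the calibration design).  Returns the model and a diagnostics dict.
    """

    def simulate(d, b):
        m = build_per2_model(d, b, 1.0, delay_h)
        tr = integrate(m, steady_state(m) + 0.5, 600.0, step=0.05)
        return detect_period(tr, "Per2"), m

    def resid(p):
        info, _ = simulate(p[0], np.exp(p[1]))
        if not info.oscillating:
            return [10.0, 10.0]
        return [info.period_h - period_target,
                2.0 * (info.rel_amplitude - amplitude_target)]

    lo = [LN2 / halflife_bounds[1], np.log(basal_bounds[0])]
    hi = [LN2 / halflife_bounds[0], np.log(basal_bounds[1])]
    sol = least_squares(resid, [0.25, np.log(80.0)], bounds=(lo, hi),
                        diff_step=0.02)
    d, b = sol.x[0], float(np.exp(sol.x[1]))
    info, model = simulate(d, b)
    return model, {"degradation": d, "basal": b, "period_h": info.period_h,
                   "rel_amplitude": info.rel_amplitude, "cost": 2 * sol.cost}


# ---------------------------------------------------------------------------
# two-variable Bmal1 / Rev-erba loop
# ---------------------------------------------------------------------------

def build_nr_loop_model(basal_bmal1: float = 1.0, basal_reverba: float = 1.0,
                        fold: float = 10.0, sat_rre: float = 1.0,
                        sat_ebox: float = 1.0,
                        deg_bmal1: float = LN2 / 2.0,
                        deg_reverba: float = LN2 / 1.5,
                        tau_bmal1: float | None = 4.0,
                        tau_reverba: float | None = 2.0) -> DelayModel:
    """Nuclear-receptor loop: Rev-erbα activated by delayed Bmal1 via
    three E-boxes; Bmal1 inhibited by delayed Rev-erbα via two RREs."""
    if tau_bmal1 is None or tau_reverba is None:
        raise ValueError("both explicit delays are required")
    fB = ModulationFactor("Rev-erba", "inhibitor", tau_reverba, 2,
                          basal_bmal1, sat_rre)
    fR = ModulationFactor("Bmal1", "activator", tau_bmal1, 3,
                          basal_reverba, sat_ebox, strength=fold)
    return DelayModel(["Bmal1", "Rev-erba"],
                      {"Bmal1": deg_bmal1, "Rev-erba": deg_reverba},
                      {"Bmal1": [fB], "Rev-erba": [fR]})


def calibrate_nr_loop_model(period_target: float = 24.0,
                            separation_target: float = 17.0,
                            seed: int = 0, n_starts: int = 6
                            ) -> tuple[DelayModel, dict]:
    """Fit the free constants of the two-gene loop so it oscillates at
    the target period with the observed Rev-erbα→Bmal1 peak separation
    (Bmal1 at about CT 1, Rev-erbα at about CT 8: 17 h from a Rev-erbα
    peak to the next Bmal1 peak).  Degradations may float within ±50%
    of their half-life anchors."""
    rng = np.random.default_rng(seed)

    def build(p):
        lb, lf, lsR, lsE, dB, dR = p
        return build_nr_loop_model(np.exp(lb), 1.0, np.exp(lf),
                                   np.exp(lsR), np.exp(lsE), dB, dR)

    def resid(p):
        m = build(p)
        try:
            tr = integrate(m, steady_state(m) + 0.3, 600.0, step=0.05)
        except Exception:
            return [20.0, 20.0]
        iB = detect_period(tr, "Bmal1")
        if not iB.oscillating:
            return [15.0, 15.0]
        sep = _peak_separation(tr, "Rev-erba", "Bmal1")
        return [iB.period_h - period_target,
                _circ(sep - separation_target, iB.period_h)]

    best = None
    for _ in range(n_starts):
        x0 = [rng.uniform(0, 3), rng.uniform(1, 3.5),
              rng.uniform(-1, 1), rng.uniform(-1, 1),
              rng.uniform(0.23, 0.52), rng.uniform(0.31, 0.92)]
        sol = least_squares(resid, x0, diff_step=0.03,
                            bounds=([-2, 0, -3, -3, LN2 / 3.0, LN2 / 2.25],
                                    [5, 5, 3, 3, LN2 / 1.0, LN2 / 0.75]))
        if best is None or sol.cost < best.cost:
            best = sol
    m = build(best.x)
    tr = integrate(m, steady_state(m) + 0.3, 600.0, step=0.05)
    info = detect_period(tr, "Bmal1")
    return m, {"period_h": info.period_h,
               "separation_h": _peak_separation(tr, "Rev-erba", "Bmal1"),
               "cost": 2 * best.cost}


def _circ(x, period=24.0):
    """Signed circular difference mapped to (-period/2, period/2]."""
    return float((x + period / 2) % period - period / 2)


def peak_separation(traj, gene_from, gene_to) -> float:
    """Time [h] from a peak of ``gene_from`` to the next peak of
    ``gene_to`` on the post-transient part of a trajectory."""
    return _peak_separation(traj, gene_from, gene_to)


def _peak_separation(traj, gene_from, gene_to):
    """Time from a peak of ``gene_from`` to the next peak of ``gene_to``
    on the post-transient part of a trajectory."""
    a = detect_period(traj, gene_from).peak_times
    b = detect_period(traj, gene_to).peak_times
    if len(a) == 0 or len(b) == 0:
        return np.nan
    t0 = a[len(a) // 2]
    later = b[b > t0]
    return float(later[0] - t0) if len(later) else np.nan


# ---------------------------------------------------------------------------
# six-variable core clock
# ---------------------------------------------------------------------------

def build_core_clock_model(params: CoreClockParams) -> DelayModel:
    """Assemble the six-gene network from a parameter set.

    Raises a validation error listing any mismatch between the
    requested factors and the cis-regulatory site table."""
    problems = [g for g in GENES if g not in params.degradation_rates]
    if problems:
        raise ValueError(f"missing degradation rates: {problems}")
    extra = [k for k in params.factors if
             k[0] not in CCE_SITES
             or k[1] not in [r for _, r, _, _ in CCE_SITES[k[0]]]]
    if extra:
        raise ValueError(
            f"factors not in the cis-regulatory site table: {extra}")
    productions = {}
    for g in GENES:
        fs = []
        for _cce, reg, role, n_sites in CCE_SITES[g]:
            if reg not in params.delays:
                raise ValueError(f"missing delay for regulator {reg}")
            c = params.factor_constants(g, reg)
            fs.append(ModulationFactor(
                reg, role, params.delays[reg], n_sites,
                c.get("basal", 1.0), c.get("saturation", 1.0),
                c.get("strength", 1.0), c.get("kd", 1.0)))
        productions[g] = fs
    return DelayModel(list(GENES), dict(params.degradation_rates),
                      productions, dict(params.production_scale))


# ---------------------------------------------------------------------------
# limit cycles, phases, modulator traces
# ---------------------------------------------------------------------------

def limit_cycle(model: DelayModel, *, t_end: float = 600.0,
                step: float = 0.05, history=None) -> Trajectory:
    """Integrate long enough to converge to the attractor.

    The default constant history of ones sits far from the unstable
    fixed point, so the limit cycle is reached well inside the
    transient window."""
    if history is None:
        history = np.ones(model.n)
    return integrate(model, history, t_end, step=step)


def peak_phase_of(traj: Trajectory, gene: str, period: float | None = None
                  ) -> float:
    """Peak time of ``gene`` on the final cycle, in circadian hours
    (model time modulo the period, rescaled to a 24 h cycle)."""
    info = detect_period(traj, gene, cv_threshold=np.inf)
    if period is None:
        period = info.period_h
    if not len(info.peak_times):
        return np.nan
    return float((info.peak_times[-1] % period) * 24.0 / period)


@dataclass
class ModulatorTrace:
    """Modulation-factor time courses of one gene over one cycle."""

    gene: str
    times: np.ndarray
    factor_traces: dict[str, np.ndarray]  # keyed by regulator name
    production: np.ndarray
    period_h: float
    #: per-trace (peak phase [circadian h], relative amplitude)
    phases: dict[str, tuple[float, float]]

    def trace_phase(self, key: str) -> float:
        return self.phases[key][0]

    def trace_amplitude(self, key: str) -> float:
        return self.phases[key][1]


def _trace_stats(t, y, period):
    i = int(np.argmax(y))
    n = len(y)
    a, b, c = y[(i - 1) % n], y[i], y[(i + 1) % n]
    den = a - 2 * b + c
    off = 0.0 if den == 0 else float(np.clip(0.5 * (a - c) / den, -0.5, 0.5))
    tp = t[i] + off * (t[1] - t[0])
    phase = (tp % period) * 24.0 / period
    mean = float(np.mean(y))
    rel = (y.max() - y.min()) / (2 * mean) if mean > 0 else 0.0
    return float(phase), float(rel)


def modulation_trace(model: DelayModel, traj: Trajectory, gene: str,
                     n_points: int = 2400) -> ModulatorTrace:
    """Evaluate every modulation factor of ``gene`` along the delayed
    trajectory over the final full cycle.

    The pointwise product of the factor traces (times the production
    scale and forcing) reproduces the gene's production term."""
    if gene not in model.variable_names:
        raise KeyError(f"{gene!r} is not a model variable")
    info = detect_period(traj, gene, cv_threshold=np.inf)
    if info.period_h is None or len(info.peak_times) < 2:
        raise ValueError("trajectory is not periodic after the transient")
    period = info.period_h
    t1 = traj.times[-1]
    t = np.linspace(t1 - period, t1, n_points, endpoint=False)
    traces = {}
    prod = np.full(n_points, model.production_scale[gene])
    for f in model.productions[gene]:
        ri = model.index(f.regulator)
        xd = traj(t - f.delay_h)[:, ri]
        vals = np.array([f.value(x) for x in xd])
        traces[f.regulator] = vals
        prod = prod * vals
    if model.forcing is not None and model.forcing.gene == gene:
        prod = prod * np.array([model.forcing.value(tt) for tt in t])
    phases = {r: _trace_stats(t, y, period) for r, y in traces.items()}
    phases["production"] = _trace_stats(t, prod, period)
    phases["mrna"] = _trace_stats(t, traj(t)[:, model.index(gene)], period)
    return ModulatorTrace(gene, t, traces, prod, period, phases)


# ---------------------------------------------------------------------------
# perturbations
# ---------------------------------------------------------------------------

def modulator_antiphase_lag(model: DelayModel, traj: Trajectory, gene: str,
                            regulator: str, n_points: int = 4800) -> float:
    """Lag [h] from the regulator mRNA trough to the peak of its
    inhibitory modulation factor on ``gene``.

    An inhibitory factor is a decreasing function of the delayed
    regulator, so its peak sits exactly one explicit delay after the
    regulator's trough — the measured lag recovers tau.
    """
    mt = modulation_trace(model, traj, gene, n_points=n_points)
    info = detect_period(traj, regulator, cv_threshold=np.inf)
    period = info.period_h
    t1 = traj.times[-1]
    t = np.linspace(t1 - period, t1, n_points, endpoint=False)
    x = traj(t)[:, model.index(regulator)]
    trough_t = t[int(np.argmin(x))]
    peak_t = mt.times[int(np.argmax(mt.factor_traces[regulator]))]
    return float((peak_t - trough_t) % period)


def apply_knockdown(model: DelayModel, regulator: str, fraction: float,
                    targets: list[str] | None = None) -> DelayModel:
    """Scale the named regulator's concentration inside modulation
    factors by ``fraction`` (RNAi mimic; 0 deletes the input).

    ``targets`` restricts the scaling to factors of the listed genes —
    knocking out a single cis-regulatory input (e.g. only the RRE of
    Cry1) rather than the regulator everywhere."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if regulator not in model.variable_names:
        raise KeyError(f"{regulator!r} is not a model variable")
    m = model.copy()
    for g in m.variable_names:
        if targets is not None and g not in targets:
            continue
        m.productions[g] = [
            f if f.regulator != regulator
            else ModulationFactor(f.regulator, f.role, f.delay_h, f.exponent,
                                  f.basal, f.saturation, f.strength,
                                  fraction * f.kd)
            for f in m.productions[g]]
    return m


def apply_ld_forcing(model: DelayModel, gene: str, strength: float,
                     photoperiod: tuple[float, float] = (12.0, 12.0),
                     t0: float = 12.0, smooth: float = 0.1,
                     square: bool = False) -> DelayModel:
    """Attach a light-dark step-function multiplier to one gene.

    The production of ``gene`` is multiplied by 1 + strength during the
    "on" window (default the 12 h dark phase, when systemic cues drive
    hepatic *Per2*) and by 1 otherwise; edges are smoothed over
    ``smooth`` h unless ``square`` is set."""
    if strength < 0:
        raise ValueError("forcing strength must be >= 0")
    if gene not in model.variable_names:
        raise KeyError(f"{gene!r} is not a model variable")
    on, off = photoperiod
    m = model.copy()
    m.forcing = Forcing(gene, strength, period=on + off, on_hours=on,
                        t0=t0, smooth=0.0 if square else smooth)
    return m
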