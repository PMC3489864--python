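"""Fitting the six-gene clock to phase/amplitude targets, and the
perturbation experiments run on the fitted model.

The fit follows the statsmodels pattern: :class:`CoreClockModel` is
built from a :class:`FitTargets` data object, and :meth:`fit` returns
a :class:`CoreClockResults` carrying the estimated parameters,
per-gene residuals, cost breakdown and optimizer metadata.

Strategy.  Cry1 and Rorg regulate nothing, so the recurrent core
(Bmal1, Rev-erbα, Per2, Dbp) is fitted first by multi-start bounded
least squares on DDE simulations; the two output genes are then fitted
on the core limit cycle by an exact periodic linear-filter response
(their production is a known periodic drive and their degradation is
linear), which costs microseconds per evaluation.  The full
six-variable model is re-simulated once at the end to verify the
reported cost.  Phase errors are circular distances taken after a
single global rotation (the autonomous model has no intrinsic CT
zero); amplitude errors are log ratios; non-oscillating parameter
points receive a large finite penalty that decays with the observed
amplitude, keeping the optimizer pointed toward oscillatory regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .clock import (CCE_SITES, GENES, LN2, CoreClockParams,
                    apply_knockdown, apply_ld_forcing,
                    build_core_clock_model, limit_cycle, _circ)
from .cosinor import align_to_ct, circular_diff
from .dde import (DelayModel, ModulationFactor, detect_period, integrate,
                  param_names, get_param, with_param)

__all__ = ["FitTargets", "CoreClockModel", "CoreClockResults",
           "fit_parameters", "control_analysis",
           "transcription_scaling_experiment", "knockdown_curve",
           "ld_adaptation_experiment", "measure_phases", "peak_order",
           "orders_equivalent"]

CORE_GENES = ["Bmal1", "Rev-erba", "Per2", "Dbp"]
OUTPUT_GENES = ["Cry1", "Rorg"]

#: measured liver DD targets: peak phases [CT h] and relative amplitudes
LIVER_PHASES_CT = {"Bmal1": 1.0, "Rev-erba": 8.0, "Dbp": 11.0,
                   "Per2": 17.0, "Rorg": 21.0, "Cry1": 22.0}
LIVER_REL_AMPLITUDES = {"Bmal1": 0.9, "Rev-erba": 1.6, "Per2": 1.0,
                        "Cry1": 0.7, "Rorg": 0.4, "Dbp": 1.8}


@dataclass
class FitTargets:
    """Per-gene peak phases [CT h], relative amplitudes, and the
    free-running period, with cost weights."""

    phases_ct: dict[str, float] = field(
        default_factory=lambda: dict(LIVER_PHASES_CT))
    rel_amplitudes: dict[str, float] = field(
        default_factory=lambda: dict(LIVER_REL_AMPLITUDES))
    period_h: float = 24.0
    w_period: float = 8.0
    w_phase: float = 1.0
    w_amplitude: float = 3.0

    def __post_init__(self):
        self.phases_ct = {g: p % 24.0 for g, p in self.phases_ct.items()}
        if any(a <= 0 for a in self.rel_amplitudes.values()):
            raise ValueError("target amplitudes must be > 0")


# ---------------------------------------------------------------------------
# phase / amplitude readout of a simulation
# ---------------------------------------------------------------------------

def measure_phases(traj, genes=None) -> tuple[float | None, dict, dict]:
    """(period, per-gene phase [circadian h], per-gene rel amplitude)
    on the post-transient part of a trajectory.

    Phases are peak times modulo the period, rescaled to a 24 h cycle,
    so they live in the same circular space as CT targets."""
    genes = genes or traj.variable_names
    ref = detect_period(traj, genes[0])
    if not ref.oscillating:
        return None, {}, {g: detect_period(traj, g).rel_amplitude
                          for g in genes}
    # the cycle converges from the transient side, so the late gaps
    # are the least biased period estimate
    gaps = np.diff(ref.peak_times)
    period = float(gaps[-3:].mean()) if len(gaps) >= 3 else ref.period_h
    phases, amps = {}, {}
    for g in genes:
        info = detect_period(traj, g, cv_threshold=np.inf)
        amps[g] = info.rel_amplitude
        phases[g] = (float(np.mean(info.peak_times % period))
                     if len(info.peak_times) else np.nan)
        # average circularly: peak times mod period cluster tightly, but
        # guard the wrap-around case via the first peak instead
        if len(info.peak_times):
            pk = info.peak_times % period
            if pk.max() - pk.min() > period / 2:
                pk = (pk + period / 2) % period
                phases[g] = (np.mean(pk) - period / 2) % period
            else:
                phases[g] = float(np.mean(pk))
            phases[g] = phases[g] * 24.0 / period
    return period, phases, amps


def peak_order(phases: dict[str, float], anchor: str = "Bmal1") -> list[str]:
    """Gene names sorted by circadian peak time starting at ``anchor``."""
    a = phases[anchor]
    return sorted(phases, key=lambda g: (phases[g] - a) % 24.0)


def orders_equivalent(ref: dict[str, float], other: dict[str, float],
                      tie_tol: float = 0.5) -> bool:
    """Whether the circular peak order is preserved.

    Pairs closer than ``tie_tol`` hours in the reference count as tied
    (Rorg and Cry1 peak within half an hour of each other, so their
    formal order is not meaningful)."""
    genes = sorted(set(ref) & set(other))
    for i, g in enumerate(genes):
        for h in genes[i + 1:]:
            d_ref = circular_diff(ref[g], ref[h])
            if abs(d_ref) <= tie_tol:
                continue
            if d_ref * circular_diff(other[g], other[h]) < 0:
                return False
    return True


# ---------------------------------------------------------------------------
# the model object
# ---------------------------------------------------------------------------

class CoreClockModel:
    """Six-gene clock model to be fitted to rhythm targets.

    Delays and degradation rates are anchored to literature values via
    the ``template`` parameter set; the regulatory-action delays of
    Rev-erbα and Dbp and all modulation-factor constants are free
    within bounds.
    """

    #: stage-A free parameters: per-core-gene production scale (log),
    #: activator fold changes (log), per-factor saturations (log),
    #: the two unanchored regulatory delays (linear, hours), and the
    #: core degradation rates (log, bounded to ±50% of the anchors).
    _FOLDS = [("Rev-erba", "Bmal1"), ("Per2", "Bmal1"),
              ("Per2", "Dbp"), ("Dbp", "Bmal1")]
    #: BMAL1's E-box affinity scale is shared across its targets (the
    #: same heterodimer binding the same element class; per-target
    #: strength differences live in the folds) — this keeps every gene,
    #: Per2 included, firmly coupled to the activating hub.  The other
    #: factors get per-factor saturations.
    _SAT_KEYS = ["Bmal1", "Bmal1:Rev-erba", "Rev-erba:Per2",
                 "Per2:Per2", "Dbp:Per2", "Per2:Dbp"]
    _I_SAT, _I_TAU, _I_DEG = 8, 14, 16

    @staticmethod
    def _sat_key(gene, reg):
        return "Bmal1" if reg == "Bmal1" else f"{gene}:{reg}"

    def __init__(self, targets: FitTargets | None = None,
                 template: CoreClockParams | None = None):
        self.targets = targets or FitTargets()
        self.template = template or CoreClockParams()

    # -- stage A: recurrent core ------------------------------------
    def _core_model(self, theta) -> DelayModel:
        tpl = self.template
        scale = {g: float(np.exp(theta[i]))
                 for i, g in enumerate(CORE_GENES)}
        folds = {k: float(np.exp(theta[4 + i]))
                 for i, k in enumerate(self._FOLDS)}
        sats = {k: float(np.exp(theta[self._I_SAT + i]))
                for i, k in enumerate(self._SAT_KEYS)}
        delays = dict(tpl.delays)
        delays["Rev-erba"] = float(theta[self._I_TAU])
        delays["Dbp"] = float(theta[self._I_TAU + 1])
        productions = {}
        for g in CORE_GENES:
            fs = []
            for _cce, reg, role, n_sites in CCE_SITES[g]:
                fs.append(ModulationFactor(
                    reg, role, delays[reg], n_sites, 1.0,
                    sats[self._sat_key(g, reg)],
                    folds.get((g, reg), 1.0)))
            productions[g] = fs
        deg = {g: float(np.exp(theta[self._I_DEG + i]))
               for i, g in enumerate(CORE_GENES)}
        return DelayModel(list(CORE_GENES), deg, productions, scale)

    def _stage_a_bounds(self):
        d0 = [self.template.degradation_rates[g] for g in CORE_GENES]
        lo = ([np.log(0.05)] * 4 + [np.log(1.5)] * 4 + [-3.0] * 6
              + [0.5, 0.5] + [np.log(0.5 * d) for d in d0])
        hi = ([np.log(500.)] * 4 + [np.log(60.)] * 4 + [3.0] * 6
              + [3.0, 3.0] + [np.log(1.5 * d) for d in d0])
        return np.array(lo), np.array(hi)

    def _simulate_core(self, theta, t_end=320.0, step=0.1):
        model = self._core_model(theta)
        return model, integrate(model, np.ones(4), t_end, step=step)

    @staticmethod
    def _factor_amplitudes(model, traj, period):
        """Relative amplitude of every modulation-factor trace of the
        model's genes over the final cycle (fast vectorized path)."""
        t1 = traj.times[-1]
        t = np.linspace(t1 - period, t1, 360, endpoint=False)
        out = {}
        for g in model.variable_names:
            for f in model.productions[g]:
                ri = model.index(f.regulator)
                x = np.maximum(traj(t - f.delay_h)[:, ri], 0.0)
                u = (f.kd * x / f.saturation) ** f.exponent
                if f.role == "activator":
                    vals = (1.0 + f.strength * u) / (1.0 + u)
                else:
                    vals = 1.0 / (1.0 + u)
                m = vals.mean()
                out[(g, f.regulator)] = (vals.max() - vals.min()) / (2 * m)
        return out

    N_RES_A = 15

    def _stage_a_residuals(self, theta, structure: bool = True,
                           t_end: float = 320.0, step: float = 0.1):
        tg = self.targets
        try:
            model, traj = self._simulate_core(theta, t_end=t_end, step=step)
        except Exception:
            return np.full(self.N_RES_A, 40.0)
        period, phases, amps = measure_phases(traj)
        if period is None:
            worst = min(amps.values()) if amps else 0.0
            return np.full(self.N_RES_A,
                           10.0 + 20.0 / (1.0 + 20.0 * worst))
        res = [tg.w_period * (period - tg.period_h)]
        al = align_to_ct({g: phases[g] for g in CORE_GENES},
                         {g: tg.phases_ct[g] for g in CORE_GENES})
        for g in CORE_GENES:
            res.append(tg.w_phase * al.residuals[g])
        for g in CORE_GENES:
            res.append(tg.w_amplitude
                       * np.log(max(amps[g], 1e-6) / tg.rel_amplitudes[g]))
        if not structure:
            res += [0.0] * (self.N_RES_A - len(res))
            return np.asarray(res)
        # structural residuals of the documented fitted model: every
        # experimentally verified cis-element must contribute a
        # non-vanishing modulation (no silently deleted regulation),
        # and Dbp's two E-box modulators have comparable amplitudes
        fa = self._factor_amplitudes(model, traj, period)
        floor = sum(max(0.0, 0.15 - a) for a in fa.values())
        res.append(15.0 * floor)
        aB, aP = fa[("Dbp", "Bmal1")], fa[("Dbp", "Per2")]
        res.append(0.7 * np.log(max(aB, 1e-6) / max(aP, 1e-6)))
        # D-box effects on clock genes are weak (fine-tuning, not a
        # primary phase determinant), while E-box activation by BMAL1
        # is the hub of the network: Per2 must stay firmly coupled to
        # the core through its E-boxes, not through the D-box
        res.append(10.0 * max(0.0, fa[("Per2", "Dbp")] - 0.3))
        res.append(15.0 * max(0.0, 0.45 - fa[("Per2", "Bmal1")]))
        res += [0.0] * (self.N_RES_A - len(res))
        return np.asarray(res)

    # -- stage B: output genes on the core limit cycle ---------------
    @staticmethod
    def _core_cycle(traj, period, n=720):
        t1 = traj.times[-1]
        t = np.linspace(t1 - period, t1, n, endpoint=False)
        return t, traj

    def _output_response(self, gene, psi, t, traj, period, deg):
        """Periodic steady-state response of a non-feedback gene.

        ``psi`` = (log folds for activators..., log sats for all
        factors...).  Returns phase [circadian h], rel amplitude, and
        the factor traces (for modulator-structure inspection)."""
        sites = CCE_SITES[gene]
        n_act = sum(1 for _c, _r, role, _n in sites if role == "activator")
        folds = np.exp(psi[:n_act])
        sats = np.exp(psi[n_act:n_act + len(sites)])
        p = np.ones_like(t)
        traces = {}
        ia = 0
        for (cce, reg, role, n_sites), s in zip(sites, sats):
            ri = traj.variable_names.index(reg)
            xd = traj(t - self.template.delays[reg])[:, ri]
            u = (np.maximum(xd, 0.0) / s) ** n_sites
            if role == "activator":
                f = (1.0 + folds[ia] * u) / (1.0 + u)
                ia += 1
            else:
                f = 1.0 / (1.0 + u)
            traces[(cce, reg)] = f
            p = p * f
        w = 2 * np.pi / period
        k = np.arange(len(t) // 2 + 1)
        ph = np.fft.rfft(p)
        y = np.fft.irfft(ph / (deg + 1j * k * w), n=len(t))
        i = int(np.argmax(y))
        a, b, c = y[i - 1], y[i], y[(i + 1) % len(y)]
        den = a - 2 * b + c
        off = 0.0 if den == 0 else float(np.clip(0.5 * (a - c) / den,
                                                 -0.5, 0.5))
        tp = t[i] + off * (t[1] - t[0])
        phase = (tp % period) * 24.0 / period
        mean = float(np.mean(y))
        rel = (y.max() - y.min()) / (2 * mean) if mean > 0 else 0.0
        return float(phase), float(rel), traces

    @staticmethod
    def _trace_amp(f):
        m = float(np.mean(f))
        return (f.max() - f.min()) / (2 * m) if m > 0 else 0.0

    def _stage_b_residuals(self, gene, psi, t, traj, period, rotation,
                           hierarchy_prior):
        tg = self.targets
        deg = psi[-1]
        phase, rel, traces = self._output_response(gene, psi[:-1], t, traj,
                                                   period, deg)
        res = [tg.w_phase * circular_diff(phase + rotation,
                                          tg.phases_ct[gene]),
               tg.w_amplitude * np.log(max(rel, 1e-6)
                                       / tg.rel_amplitudes[gene])]
        if hierarchy_prior:
            # documented fitted-model structure: RRE and combined E-box
            # modulators dominate Cry1; the D-box modulator is minor
            aR = max((self._trace_amp(f) for (c, _r), f in traces.items()
                      if c == "RRE"), default=0.0)
            e_prod = np.prod([f for (c, _r), f in traces.items()
                              if c == "Ebox"], axis=0)
            aE = self._trace_amp(e_prod)
            aD = max((self._trace_amp(f) for (c, _r), f in traces.items()
                      if c == "Dbox"), default=0.0)
            res.append(2.0 * max(0.0, aD - 0.2 * aR))
            res.append(2.0 * max(0.0, aD - 0.2 * aE))
            res.append(1.0 * max(0.0, aE / 3.0 - aR))
        return np.asarray(res)

    def _fit_output(self, gene, t, traj, period, rotation, rng,
                    n_starts=20):
        sites = CCE_SITES[gene]
        n_act = sum(1 for _c, _r, role, _n in sites if role == "activator")
        d0 = self.template.degradation_rates[gene]
        lo = np.r_[[np.log(1.5)] * n_act, [-3.0] * len(sites), [0.5 * d0]]
        hi = np.r_[[np.log(60.)] * n_act, [3.0] * len(sites), [1.5 * d0]]
        prior = gene == "Cry1"
        # two deterministic starts (moderate folds / unit saturations,
        # and a weak-D variant) ahead of the random ones keep this
        # stage stable across seeds
        det = [np.clip(np.r_[[np.log(6.0)] * n_act, [0.0] * len(sites),
                             [d0]], lo, hi)]
        x1 = det[0].copy()
        x1[n_act:n_act + len(sites)] = 1.5
        det.append(np.clip(x1, lo, hi))
        starts = det + [rng.uniform(lo, hi)
                        for _ in range(max(n_starts - 2, 0))]
        best = None
        for x0 in starts:
            sol = least_squares(
                lambda p: self._stage_b_residuals(gene, p, t, traj, period,
                                                  rotation, prior),
                x0, bounds=(lo, hi), diff_step=0.02)
            if best is None or sol.cost < best.cost:
                best = sol
        return best

    def _core_robust(self, theta) -> bool:
        """Reject fits parked at the oscillation boundary.

        The physiological clock keeps oscillating under moderate
        transcription-rate fluctuation and under knock-out of any
        single regulator input (the RNAi/knock-out simulations all
        retain rhythms); near-optimal minima violating these
        qualitative facts are discarded in favour of robust ones."""
        try:
            m0 = self._core_model(theta)
            traj = integrate(m0, np.ones(4), 360.0, step=0.1)
            p0, _, _ = measure_phases(traj)
            if p0 is None:
                return False
            m = m0.copy()
            m.production_scale = {g: 0.85 * s
                                  for g, s in m.production_scale.items()}
            traj = integrate(m, np.ones(4), 360.0, step=0.1)
            p1, _, _ = measure_phases(traj)
            if p1 is None or abs(p1 - p0) / p0 > 0.03:
                return False
            traj = integrate(apply_knockdown(m0, "Dbp", 0.0), np.ones(4),
                             360.0, step=0.1)
            p2, _, _ = measure_phases(traj)
            return p2 is not None
        except Exception:
            return False

    def _per2_delay_dominates(self, theta, p0) -> bool:
        """Per2's regulatory delay is the period's dominant delay.

        The period of the documented network is controlled foremost by
        the Per2 explicit delay, with the Bmal1 and Rev-erbα delays
        fine-tuning it; candidates whose period is steered by another
        delay sit in a different dynamical regime."""
        m0 = self._core_model(theta)

        def dP(reg):
            worst = 0.0
            for f in (0.9, 1.1):
                m = m0.copy()
                for g in m.variable_names:
                    m.productions[g] = [
                        fc if fc.regulator != reg else
                        ModulationFactor(fc.regulator, fc.role,
                                         fc.delay_h * f, fc.exponent,
                                         fc.basal, fc.saturation,
                                         fc.strength, fc.kd)
                        for fc in m.productions[g]]
                try:
                    traj = integrate(m, np.ones(m.n), 420.0, step=0.1)
                    p, _, _ = measure_phases(traj)
                except Exception:
                    p = None
                if p is not None:
                    worst = max(worst, abs(p - p0))
            return worst

        s_per2 = dP("Per2")
        return all(s_per2 >= dP(r) for r in ("Bmal1", "Rev-erba", "Dbp"))

    # -- public API ---------------------------------------------------
    def fit(self, n_starts: int = 50, seed: int = 0,
            output_starts: int = 30, n_polish: int = 8
            ) -> "CoreClockResults":
        rng = np.random.default_rng(seed)
        lo, hi = self._stage_a_bounds()
        x0_default = np.r_[np.log([3.0, 3.0, 3.0, 3.0]),
                           np.log([10.0, 10.0, 5.0, 10.0]),
                           [0.0] * 6, [1.0, 1.0],
                           np.log([self.template.degradation_rates[g]
                                   for g in CORE_GENES])]
        # curated warm start retained from an earlier fitting campaign;
        # deterministic starts keep the multi-start outcome stable
        # across seeds
        x0_curated = np.array([
            2.645455, -2.964929, 0.274646, 2.475696,
            4.051967, 0.582195, 4.089179, 2.626987,
            2.998606, -0.155448, 1.989874, -1.856367, 0.914806,
            -0.464719, 1.578592, 0.813256,
            -1.100926, -0.726747, -1.281717, -0.656216])
        starts = [np.clip(x0_curated, lo, hi), x0_default]             + [rng.uniform(lo, hi) for _ in range(max(n_starts - 2, 0))]
        # cheap screening pass on the data-only cost, full polish of
        # the leading starts, then a structural continuation: each
        # plain minimum is re-polished with the documented-structure
        # residuals switched on, finding the constrained optimum
        # adjacent to the data optimum
        def plain(th):
            return self._stage_a_residuals(th, structure=False)

        screened = []
        for x0 in starts:
            sol = least_squares(plain, x0, bounds=(lo, hi),
                                diff_step=0.03, max_nfev=50)
            screened.append(sol)
        screened.sort(key=lambda s: s.cost)
        polished, start_costs = [], []
        for sol in screened[:n_polish]:
            mid = least_squares(plain, sol.x, bounds=(lo, hi),
                                diff_step=0.03)
            full = least_squares(self._stage_a_residuals, mid.x,
                                 bounds=(lo, hi), diff_step=0.03)
            polished.append(full)
            start_costs.append(float(full.cost))
        # among the structural minima prefer the lowest-cost one whose
        # oscillation survives a 15% transcription-rate reduction and
        # deletion of the D-box input — the physiological clock is
        # resilient to transcription-rate fluctuations and the
        # knock-out simulations all retain rhythms, so minima parked
        # at the oscillation boundary are rejected as unphysiological
        # score every polished candidate on a fine, long simulation:
        # data cost at final resolution plus a robustness penalty —
        # marginal (slowly converging) minima look better on the coarse
        # fitting grid than they are
        tg = self.targets
        scored = []
        for cand in polished:
            try:
                _, traj = self._simulate_core(cand.x, t_end=600.0,
                                              step=0.05)
            except Exception:
                continue
            p, ph, am = measure_phases(traj)
            if p is None:
                continue
            al = align_to_ct({g: ph[g] for g in CORE_GENES},
                             {g: tg.phases_ct[g] for g in CORE_GENES})
            cost = 0.5 * ((tg.w_period * (p - tg.period_h)) ** 2
                          + sum((tg.w_phase * r) ** 2
                                for r in al.residuals.values())
                          + sum((tg.w_amplitude
                                 * np.log(max(am[g], 1e-6)
                                          / tg.rel_amplitudes[g])) ** 2
                                for g in CORE_GENES))
            score = cost + (0.0 if self._core_robust(cand.x) else 8.0)
            scored.append((score, cand.x, traj, p))
        if not scored:
            raise RuntimeError(
                "no oscillating fit found; widen the starts or bounds")
        scored.sort(key=lambda s: s[0])
        _, theta, core_traj, period = scored[0]
        _, phases, _amps = measure_phases(core_traj)
        al = align_to_ct({g: phases[g] for g in CORE_GENES},
                         {g: self.targets.phases_ct[g] for g in CORE_GENES})
        t, _ = self._core_cycle(core_traj, period)
        # the output genes participate in the final CT alignment, so
        # alternate fitting them with re-anchoring the rotation until
        # the frame is self-consistent
        rotation = al.rotation_h
        out_params = {}
        for _round in range(3):
            for gene in OUTPUT_GENES:
                out_params[gene] = self._fit_output(
                    gene, t, core_traj, period, rotation, rng,
                    n_starts=output_starts)
            all_phases = dict(phases)
            for gene in OUTPUT_GENES:
                psi = out_params[gene].x
                ph_g, _, _ = self._output_response(gene, psi[:-1], t,
                                                   core_traj, period,
                                                   psi[-1])
                all_phases[gene] = ph_g
            al6 = align_to_ct(all_phases, self.targets.phases_ct)
            if abs(al6.rotation_h - rotation) < 0.05:
                rotation = al6.rotation_h
                break
            rotation = al6.rotation_h
        params = self._assemble_params(theta, out_params)
        return CoreClockResults(self, params, seed=seed, n_starts=n_starts,
                                start_costs=start_costs,
                                stage_a_theta=np.array(theta))

    def _assemble_params(self, theta, out_sols) -> CoreClockParams:
        tpl = self.template
        folds = {k: float(np.exp(theta[4 + i]))
                 for i, k in enumerate(self._FOLDS)}
        sats = {k: float(np.exp(theta[self._I_SAT + i]))
                for i, k in enumerate(self._SAT_KEYS)}
        delays = dict(tpl.delays)
        delays["Rev-erba"] = float(theta[self._I_TAU])
        delays["Dbp"] = float(theta[self._I_TAU + 1])
        deg = dict(tpl.degradation_rates)
        for i, g in enumerate(CORE_GENES):
            deg[g] = float(np.exp(theta[self._I_DEG + i]))
        scale = {g: 1.0 for g in GENES}
        for i, g in enumerate(CORE_GENES):
            scale[g] = float(np.exp(theta[i]))
        factors = {}
        for g in CORE_GENES:
            for _cce, reg, role, _n in CCE_SITES[g]:
                factors[(g, reg)] = {"basal": 1.0,
                                     "saturation": sats[self._sat_key(g,
                                                                      reg)],
                                     "strength": folds.get((g, reg), 1.0)}
        for g in OUTPUT_GENES:
            psi = out_sols[g].x
            sites = CCE_SITES[g]
            n_act = sum(1 for _c, _r, role, _n in sites
                        if role == "activator")
            fvals = np.exp(psi[:n_act])
            svals = np.exp(psi[n_act:n_act + len(sites)])
            deg[g] = float(psi[-1])
            ia = 0
            for (cce, reg, role, _n), s in zip(sites, svals):
                d = {"basal": 1.0, "saturation": float(s), "strength": 1.0}
                if role == "activator":
                    d["strength"] = float(fvals[ia])
                    ia += 1
                factors[(g, reg)] = d
        return CoreClockParams(deg, delays, factors, scale)


@dataclass
class CoreClockResults:
    """Fitted six-gene model with diagnostics.

    The reported cost is recomputed from a fresh simulation of the
    assembled full model, so it is reproducible from ``params`` alone.
    """

    model_spec: CoreClockModel
    params: CoreClockParams
    seed: int
    n_starts: int
    start_costs: list[float]
    stage_a_theta: np.ndarray

    def __post_init__(self):
        self.model = build_core_clock_model(self.params)
        self._evaluate()

    def _evaluate(self):
        tg = self.model_spec.targets
        traj = limit_cycle(self.model, t_end=480.0, step=0.05)
        self.trajectory = traj
        period, phases, amps = measure_phases(traj)
        self.period_h = period
        self.converged = period is not None
        if not self.converged:
            self.cost = np.inf
            return
        al = align_to_ct(phases, tg.phases_ct)
        self.rotation_h = al.rotation_h
        self.phases_ct = al.aligned
        self.phase_residuals = al.residuals
        self.rel_amplitudes = amps
        self.amp_residuals = {
            g: float(np.log(amps[g] / tg.rel_amplitudes[g])) for g in GENES}
        self.cost_breakdown = {
            "period": float((tg.w_period * (period - tg.period_h)) ** 2),
            "phase": float(sum((tg.w_phase * r) ** 2
                               for r in self.phase_residuals.values())),
            "amplitude": float(sum((tg.w_amplitude * r) ** 2
                                   for r in self.amp_residuals.values())),
        }
        self.cost = float(sum(self.cost_breakdown.values()))
        self.peak_order = peak_order(self.phases_ct)

    def recompute_cost(self) -> float:
        """Re-simulate the fitted parameters and recompute the cost."""
        saved = self.cost
        self._evaluate()
        assert abs(self.cost - saved) <= 1e-8 * max(abs(saved), 1.0)
        return self.cost

    def summary(self) -> str:
        tg = self.model_spec.targets
        if not self.converged:
            return ("Core clock fit\nno sustained oscillation at the "
                    "fitted parameters (cost inf)")
        lines = ["Core clock fit",
                 "=" * 58,
                 f"free-running period   {self.period_h:8.3f} h "
                 f"(target {tg.period_h} h)",
                 f"CT rotation           {self.rotation_h:8.3f} h",
                 f"total cost            {self.cost:8.4f}"
                 f"   (period {self.cost_breakdown['period']:.4f}, phase "
                 f"{self.cost_breakdown['phase']:.4f}, amplitude "
                 f"{self.cost_breakdown['amplitude']:.4f})",
                 f"starts                {self.n_starts}  (seed {self.seed})",
                 "-" * 58,
                 f"{'gene':10s} {'phase CT':>9s} {'target':>7s} "
                 f"{'resid':>6s} {'rel amp':>8s} {'target':>7s}"]
        for g in GENES:
            lines.append(
                f"{g:10s} {self.phases_ct[g]:9.2f} {tg.phases_ct[g]:7.1f} "
                f"{self.phase_residuals[g]:6.2f} "
                f"{self.rel_amplitudes[g]:8.3f} "
                f"{tg.rel_amplitudes[g]:7.2f}")
        lines.append("peak order: " + " -> ".join(self.peak_order))
        return "\n".join(lines)


def fit_parameters(targets: FitTargets | None = None,
                   template: CoreClockParams | None = None,
                   n_starts: int = 50, seed: int = 0) -> CoreClockResults:
    """Multi-start fit of the six-variable model (functional wrapper)."""
    return CoreClockModel(targets, template).fit(n_starts=n_starts,
                                                 seed=seed)


# ---------------------------------------------------------------------------
# perturbation / control analyses
# ---------------------------------------------------------------------------

def _aligned_shift(ref_phases, pert_phases, align_genes):
    """Rotation-corrected per-gene phase changes (pert - ref, h),
    aligning on ``align_genes`` only."""
    al = align_to_ct({g: pert_phases[g] for g in align_genes},
                     {g: ref_phases[g] for g in align_genes})
    return {g: circular_diff(pert_phases[g] + al.rotation_h, ref_phases[g])
            for g in pert_phases}


def control_analysis(model: DelayModel, perturbation_fraction: float = 0.1,
                     parameters: list[str] | None = None,
                     phase_threshold_pct: float = 1.0,
                     amp_threshold_pct: float = 3.0,
                     t_end: float = 480.0, step: float = 0.1
                     ) -> pd.DataFrame:
    """Relative change of period, phases, and amplitudes under ±fraction
    perturbation of each parameter.

    Phases are re-aligned (single circular rotation over all genes)
    before differencing and reported both in hours and as % of the
    reference period; exceedances are flagged at 1% (period, phases)
    and 3% (amplitudes).  A perturbed model that stops oscillating is
    recorded as such rather than raising.
    """
    ref_traj = limit_cycle(model, t_end=t_end, step=step)
    period0, phases0, amps0 = measure_phases(ref_traj)
    if period0 is None:
        raise ValueError("reference model is not oscillating")
    parameters = parameters or param_names(model)
    genes = model.variable_names
    rows = []
    for p in parameters:
        for sgn in (+1, -1):
            v0 = get_param(model, p)
            m = with_param(model, p, v0 * (1 + sgn * perturbation_fraction))
            row = {"parameter": p, "direction": sgn, "oscillating": True}
            try:
                traj = limit_cycle(m, t_end=t_end, step=step)
                period, phases, amps = measure_phases(traj)
            except Exception:
                period = None
            if period is None:
                row["oscillating"] = False
                rows.append(row)
                continue
            dp = 100.0 * (period - period0) / period0
            row["period_pct"] = dp
            row["period_flag"] = abs(dp) > phase_threshold_pct
            shifts = _aligned_shift(phases0, phases, genes)
            for g in genes:
                hpct = 100.0 * shifts[g] / 24.0
                row[f"phase_{g}_h"] = shifts[g]
                row[f"phase_{g}_pct"] = hpct
                row[f"phase_{g}_flag"] = abs(hpct) > phase_threshold_pct
                apct = 100.0 * (amps[g] - amps0[g]) / amps0[g]
                row[f"amp_{g}_pct"] = apct
                row[f"amp_{g}_flag"] = abs(apct) > amp_threshold_pct
            rows.append(row)
    return pd.DataFrame(rows)


def transcription_scaling_experiment(model: DelayModel, scale: float,
                                     t_end: float = 600.0,
                                     step: float = 0.05) -> dict:
    """Scale every production term and report period/phase effects.

    Returns period change (% of the reference, positive = shorter),
    rotation-corrected phase changes, and whether the circular peak
    order is conserved."""
    if scale <= 0:
        raise ValueError("scale must be > 0")
    ref = limit_cycle(model, t_end=t_end, step=step)
    period0, phases0, _ = measure_phases(ref)
    m = model.copy()
    m.production_scale = {g: s * scale for g, s in m.production_scale.items()}
    traj = limit_cycle(m, t_end=t_end, step=step)
    period, phases, _ = measure_phases(traj)
    if period is None:
        return {"oscillating": False}
    shifts = _aligned_shift(phases0, phases, model.variable_names)
    return {
        "oscillating": True,
        "period_ref_h": period0,
        "period_scaled_h": period,
        "period_shortening_pct": 100.0 * (period0 - period) / period0,
        "phase_changes_h": shifts,
        "order_preserved": orders_equivalent(phases0, phases),
    }


def knockdown_curve(model: DelayModel, regulator: str, fractions,
                    readout_gene: str, targets: list[str] | None = None,
                    t_end: float = 480.0, step: float = 0.05
                    ) -> pd.DataFrame:
    """Phase and amplitude of a readout gene across knock-down levels.

    The perturbed model's phase frame is re-anchored on the genes other
    than the readout before the shift is computed; ``shift_h`` is the
    signed circular change (advance positive).  Rows where oscillation
    is lost are flagged.
    """
    ref = limit_cycle(model, t_end=t_end, step=step)
    _, phases0, amps0 = measure_phases(ref)
    align_genes = [g for g in model.variable_names if g != readout_gene]
    rows = []
    for fr in fractions:
        m = apply_knockdown(model, regulator, fr, targets=targets)
        row = {"fraction": fr, "oscillating": True}
        try:
            traj = limit_cycle(m, t_end=t_end, step=step)
            period, phases, amps = measure_phases(traj)
        except Exception:
            period = None
        if period is None:
            row["oscillating"] = False
        else:
            shifts = _aligned_shift(phases0, phases, align_genes)
            row["shift_h"] = -shifts[readout_gene]  # advance positive
            row["rel_amplitude"] = amps[readout_gene]
            row["amplitude_ratio"] = amps[readout_gene] / amps0[readout_gene]
        rows.append(row)
    return pd.DataFrame(rows)


def ld_adaptation_experiment(model: DelayModel, strength: float,
                             tau_b_override: float | None = None,
                             reference_phases: dict | None = None,
                             forced_gene: str = "Per2",
                             t_end: float = 960.0, step: float = 0.05
                             ) -> dict:
    """Light-dark forcing of Per2 versus the free-running baseline.

    Simulates the model with a 12 h:12 h step multiplier on the forced
    gene's production (optionally with an increased Bmal1 regulatory
    delay), checks 24 h entrainment, and reports per-gene phase shifts
    (advance positive) and amplitude ratios against the DD limit cycle.
    DD phases are put on the CT axis via alignment to the reference
    phases (the fit targets by default); entrained phases are read in
    zeitgeber time directly.
    """
    refs = reference_phases or LIVER_PHASES_CT
    dd = limit_cycle(model, t_end=480.0, step=step)
    _, phases_dd, amps_dd = measure_phases(dd)
    al = align_to_ct(phases_dd, refs)
    dd_ct = {g: (phases_dd[g] + al.rotation_h) % 24.0
             for g in model.variable_names}
    m = apply_ld_forcing(model, forced_gene, strength)
    if tau_b_override is not None:
        for g in m.variable_names:
            m.productions[g] = [
                f if f.regulator != "Bmal1"
                else ModulationFactor(f.regulator, f.role, tau_b_override,
                                      f.exponent, f.basal, f.saturation,
                                      f.strength, f.kd)
                for f in m.productions[g]]
    traj = integrate(m, dd.states[-1], t_end, step=step)
    out = {"entrained": True, "per_gene": {}}
    period, phases_ld, amps_ld = measure_phases(traj)
    if strength > 0:
        info = detect_period(traj, forced_gene, transient_fraction=0.75)
        if not info.oscillating or abs(info.period_h - 24.0) > 0.01:
            out["entrained"] = False
        out["period_h"] = info.period_h
        ld_zt = phases_ld  # entrained: model time is zeitgeber time
    else:
        # free-running baseline: same attractor, compare in circadian
        # phase after aligning the whole phase set
        al0 = align_to_ct(phases_ld, phases_dd)
        ld_zt = {g: (dd_ct[g] - al0.residuals[g]) % 24.0
                 for g in model.variable_names}
    for g in model.variable_names:
        out["per_gene"][g] = {
            "phase_shift_h": circular_diff(dd_ct[g], ld_zt[g]),
            "amplitude_ratio": amps_ld[g] / amps_dd[g],
        }
    return out
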