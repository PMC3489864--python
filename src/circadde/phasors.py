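"""Trigonometric theory of combinatorial transcriptional regulation.

Periodic modulation factors are approximated by first-harmonic
phasors, 1 + a*cos(omega*(t - phi)).  A product of such modulators has
a fundamental component equal to the vector sum of the individual
phasors, so the peak of combined regulation lies between the peaks of
the components, pulled toward the larger amplitude.  Antiphase
activator/inhibitor pairs add constructively (synergy), and linear
degradation delays the expression peak behind the production peak by
atan(omega/d)/omega — between 0 (fast turnover) and a quarter period
(6 h for a 24 h rhythm, very stable mRNA).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Phasor", "PhasorSet", "combined_modulator_phase",
    "antiphase_synergy_reduction", "halflife_phase_shift",
    "phase_range_prediction", "MODULATOR_PHASES",
]

#: default peak phases [CT h] of the four transcriptional modulators
MODULATOR_PHASES = {"RRE": 22.0, "Dbox": 12.0,
                    "Ebox_Bmal1": 5.0, "Ebox_Per2": 15.0}


@dataclass(frozen=True)
class Phasor:
    """Relative amplitude and peak phase [CT h, mod 24] of a modulator."""

    amplitude: float
    phase_ct: float
    period: float = 24.0

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")

    @property
    def complex(self) -> complex:
        return self.amplitude * np.exp(2j * np.pi * self.phase_ct
                                       / self.period)

    def curve(self, t):
        w = 2 * np.pi / self.period
        return 1.0 + self.amplitude * np.cos(w * (np.asarray(t)
                                                  - self.phase_ct))


PhasorSet = list  # list of Phasor (or (amplitude, phase) pairs)


def _as_phasor(p) -> Phasor:
    return p if isinstance(p, Phasor) else Phasor(*p)


def combined_modulator_phase(components, n_grid: int = 4800
                             ) -> tuple[float | None, float]:
    """Peak phase and relative amplitude of a product of modulators.

    Each modulator is the trigonometric approximation
    1 + a_i cos(omega (t - phi_i)) of a modulation-factor trace; their
    product's fundamental is the phasor sum of the components, so
    larger amplitudes dominate the combined phase.  The peak is read
    off a dense evaluation of the exact product (the higher harmonics
    generated by the product shift it slightly off the phasor-sum
    angle).  Returns (phase_ct, relative amplitude); the phase is None
    when every amplitude vanishes.
    """
    ps = [_as_phasor(p) for p in components]
    if not ps:
        raise ValueError("at least one component required")
    period = ps[0].period
    if all(p.amplitude < 1e-12 for p in ps):
        return None, 0.0
    t = np.linspace(0.0, period, n_grid, endpoint=False)
    prod = np.ones_like(t)
    for p in ps:
        prod = prod * p.curve(t)
    i = int(np.argmax(prod))
    a, b, c = prod[i - 1], prod[i], prod[(i + 1) % n_grid]
    den = a - 2 * b + c
    off = 0.0 if den == 0 else float(np.clip(0.5 * (a - c) / den, -0.5, 0.5))
    phase = (t[i] + off * (t[1] - t[0])) % period
    mean = float(prod.mean())
    amp = (prod.max() - prod.min()) / (2 * mean) if mean > 0 else 0.0
    return float(phase), float(amp)


def antiphase_synergy_reduction(activator, inhibitor,
                                tolerance_h: float = 3.0) -> Phasor:
    """Replace an antiphase activator/inhibitor pair by one regulator.

    ``activator`` and ``inhibitor`` are (amplitude, regulator peak
    phase) of the two *regulators*.  The inhibitory modulation factor
    peaks half a period after its regulator, so for an exactly
    antiphase pair both modulations peak together and their amplitudes
    add: the equivalent regulator keeps the activator's phase with an
    enlarged amplitude.  A warning is issued when the pair is far from
    antiphase and the approximation degrades.
    """
    act, inh = _as_phasor(activator), _as_phasor(inhibitor)
    period = act.period
    delta = (inh.phase_ct - act.phase_ct) % period
    if abs(delta - period / 2) > tolerance_h:
        warnings.warn("activator/inhibitor pair is not antiphase; the "
                      "single-regulator reduction is a poor approximation")
    z = act.complex + Phasor(inh.amplitude,
                             (inh.phase_ct + period / 2) % period).complex
    amp = abs(z)
    phase = (np.angle(z) * period / (2 * np.pi)) % period if amp > 0 else \
        act.phase_ct
    return Phasor(float(amp), float(phase))


def halflife_phase_shift(degradation_rate: float, period: float = 24.0
                         ) -> float:
    """Peak delay [h] of a linearly degraded species behind a sinusoidal
    production term: lag = atan(omega/d)/omega, omega = 2 pi / period.

    Fast turnover tracks production (lag -> 0); very stable mRNA lags a
    quarter period (6 h on a 24 h rhythm)."""
    if degradation_rate <= 0:
        raise ValueError("degradation rate must be > 0")
    w = 2 * np.pi / period
    return float(np.arctan(w / degradation_rate) / w)


def phase_range_prediction(cce_set, modulator_phases=None,
                           amp_grid=None, halflife_lag=(0.0, 6.0)
                           ) -> tuple[float, float]:
    """Attainable peak-phase interval [CT h] for a gene regulated by the
    given cis-element set (subset of {"E", "D", "R"}).

    Sweeps the relative amplitudes of the participating modulators
    through the phasor combination (for E-boxes the BMAL1 activator
    component must be at least as large as the PER2 inhibitor
    component — without net activation there is no expression peak to
    speak of), then widens the production-phase interval by the
    half-life lag range.  Returns (lo, hi) with hi possibly wrapping
    past CT 24.
    """
    cce_set = set(cce_set)
    if not cce_set or not cce_set <= {"E", "D", "R"}:
        raise ValueError("cce_set must be a non-empty subset of {E, D, R}")
    phases = dict(MODULATOR_PHASES)
    if modulator_phases:
        phases.update(modulator_phases)
    if amp_grid is None:
        amp_grid = np.linspace(0.15, 1.0, 6)
    singles = sorted(c for c in cce_set if c != "E")
    angles = []
    grids = []
    if "E" in cce_set:
        grids.append([(aB, aP) for aB in amp_grid for aP in amp_grid
                      if aP <= aB])
    for _ in singles:
        grids.append([(a,) for a in amp_grid])
    from itertools import product as iproduct
    for combo in iproduct(*grids):
        comps = []
        i = 0
        if "E" in cce_set:
            aB, aP = combo[0]
            comps.append(Phasor(aB, phases["Ebox_Bmal1"]))
            comps.append(Phasor(aP, phases["Ebox_Per2"]))
            i = 1
        for s, c in zip(singles, combo[i:]):
            key = "Dbox" if s == "D" else "RRE"
            comps.append(Phasor(c[0], phases[key]))
        ph, amp = combined_modulator_phase(comps)
        if ph is not None and amp > 1e-9:
            angles.append(2 * np.pi * ph / 24.0)
    angles = np.asarray(angles)
    # smallest arc containing every attainable production phase
    order = np.sort(angles % (2 * np.pi))
    gaps = np.diff(np.concatenate([order, [order[0] + 2 * np.pi]]))
    k = int(np.argmax(gaps))
    lo = order[(k + 1) % len(order)] * 24 / (2 * np.pi)
    hi = order[k] * 24 / (2 * np.pi)
    if hi < lo:
        hi += 24.0
    return (float((lo + halflife_lag[0]) % 24.0),
            float((hi + halflife_lag[1]) % 24.0))
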