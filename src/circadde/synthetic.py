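"""Synthetic RT-qPCR time-course generator.

Emulates the statistical structure of the liver measurement design:
2 h sampling over 24 h, at least 4 biological replicates per point,
lognormal multiplicative replicate noise (expression is positive and
qPCR errors act on the fold scale), per-primer efficiencies near 2,
and three constant reference genes.  Ground truth is either an
explicit harmonic profile per gene or a simulated model trajectory,
so every pipeline stage can be tested against known parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .qpcr import DEFAULT_REFERENCE_GENES, QpcrTable

__all__ = ["HarmonicTruth", "GeneratorSpec", "generate_profiles",
           "generate_qpcr_dataset", "generate_ld_dd_pair"]


@dataclass(frozen=True)
class HarmonicTruth:
    """True continuous profile: mean + sum of cosine harmonics."""

    mean: float
    amplitudes: tuple = ()        # aligned with periods
    phases: tuple = ()            # acrophase [h] per harmonic
    periods: tuple = (24.0, 12.0, 8.0)

    def __call__(self, t):
        t = np.asarray(t, float)
        out = np.full(t.shape, self.mean)
        for a, p, per in zip(self.amplitudes, self.phases, self.periods):
            out = out + a * np.cos(2 * np.pi * (t - p) / per)
        return out


@dataclass
class GeneratorSpec:
    """Study design of one synthetic dataset.

    Defaults mirror the measurement protocol: samples every 2 h over
    24 h, 4 biological replicates, 10% lognormal coefficient of
    variation, primer efficiencies near 1.9-2.0.
    """

    truths: dict[str, HarmonicTruth]
    times: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 26.0, 2.0))
    replicates: int = 4
    noise_cv: float = 0.10
    efficiencies: dict[str, float] = field(default_factory=dict)
    reference_genes: tuple = DEFAULT_REFERENCE_GENES
    reference_level: float = 1.0
    cp_offset: float = 18.0       # arbitrary per-run Cp anchor
    seed: int = 0

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        for g, tr in self.truths.items():
            if np.any(tr(np.linspace(0, 24, 481)) <= 0):
                raise ValueError(f"truth of {g} is not strictly positive "
                                 "(amplitudes must stay below the mean)")
        for g in list(self.truths) + list(self.reference_genes):
            self.efficiencies.setdefault(g, 1.95)


def generate_profiles(spec: GeneratorSpec) -> dict:
    """Deterministic truth functions per gene (references constant)."""
    out = dict(spec.truths)
    for g in spec.reference_genes:
        out[g] = HarmonicTruth(spec.reference_level)
    return out


def _lognormal_factors(rng, cv, size):
    sigma = float(np.sqrt(np.log1p(cv ** 2)))
    return rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma, size=size)


def generate_qpcr_dataset(spec: GeneratorSpec,
                          seed: int | None = None) -> QpcrTable:
    """Sample the truths on the design grid and encode as Cp values.

    Quantities get multiplicative lognormal noise (unit mean), then
    Cp = cp_offset - log(q)/log(E) so that E**(-Cp) is proportional to
    the noisy quantity.  Fully reproducible from the seed.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    profiles = generate_profiles(spec)
    rows = []
    for g in sorted(profiles):
        truth = profiles[g]
        E = spec.efficiencies[g]
        for t in spec.times:
            q0 = float(truth(t))
            noise = _lognormal_factors(rng, spec.noise_cv, spec.replicates)
            for r in range(spec.replicates):
                q = q0 * noise[r]
                cp = spec.cp_offset - np.log(q) / np.log(E)
                rows.append((g, float(t), r, float(cp)))
    df = pd.DataFrame(rows, columns=["gene", "time_h", "replicate", "cp"])
    return QpcrTable(df, dict(spec.efficiencies), spec.reference_genes)


def generate_ld_dd_pair(spec: GeneratorSpec, ld_deltas: dict,
                        seed: int | None = None
                        ) -> tuple[QpcrTable, QpcrTable]:
    """DD dataset from the generator's truths plus an LD dataset whose
    truths have injected per-gene phase advances and amplitude ratios.

    ``ld_deltas`` maps gene -> {"phase_advance_h": float,
    "amplitude_ratio": float}; omitted genes are unchanged.
    """
    base_seed = spec.seed if seed is None else seed
    dd = generate_qpcr_dataset(spec, seed=base_seed)
    truths_ld = {}
    for g, tr in spec.truths.items():
        d = ld_deltas.get(g, {})
        adv = float(d.get("phase_advance_h", 0.0))
        ratio = float(d.get("amplitude_ratio", 1.0))
        if not np.isfinite(adv) or not np.isfinite(ratio):
            raise ValueError(f"non-finite LD delta for {g}")
        truths_ld[g] = HarmonicTruth(
            tr.mean, tuple(a * ratio for a in tr.amplitudes),
            tuple((p - adv) % per for p, per in zip(tr.phases, tr.periods)),
            tr.periods)
    spec_ld = GeneratorSpec(truths_ld, spec.times.copy(), spec.replicates,
                            spec.noise_cv, dict(spec.efficiencies),
                            spec.reference_genes, spec.reference_level,
                            spec.cp_offset, base_seed + 1)
    return dd, generate_qpcr_dataset(spec_ld)
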