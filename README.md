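# circadde

Delay-differential-equation models of the mouse liver circadian
clock: simulation and bifurcation analysis of delayed gene networks,
harmonic (cosinor) rhythm regression, RT-qPCR normalization, synthetic
time-course generation, and multi-start fitting of a six-gene core
clock to measured phases and amplitudes.

## The problem

Peripheral clocks such as the liver's are driven by transcriptional
feedback loops acting through three classes of cis-regulatory
clock-controlled elements: E-boxes (BMAL1:CLOCK activation, PER/CRY
repression), D-boxes (DBP activation, E4BP4 repression), and ROR
elements (ROR activation, REV-ERB repression).  The intermediate
protein steps — translation, modification, complex formation, nuclear
import — are slow and poorly characterized.  This package models them
as explicit time delays: each mRNA x_i follows

    dx_i/dt = s_i · Π_k F_k( x_{r(k)}(t − τ_k) ) − d_i x_i

with linear degradation and a production term that is a product of
*modulation factors*, one per cis-element, of the thermodynamic form
F = b(1 + f·u)/(1 + u) (activators) or F = b/(1 + u) (inhibitors),
u = (x/s)^n with n the binding-site count.  Delayed negative feedback
with over-critical delay τ generates oscillations through a Hopf
bifurcation, with a period two to four times the delay — so circadian
rhythms require delays of several hours, and the interplay of the
modulation factors sets each gene's peak phase.

The package is organised around two statsmodels-style model objects:

* `HarmonicRegression(series).fit() -> RhythmFit` — least-squares
  cosinor regression (24/12/8 h harmonics) of expression time courses,
  with circular phase handling, CT alignment, and DD-vs-LD comparison.
* `CoreClockModel(targets).fit() -> CoreClockResults` — multi-start
  bounded least-squares fit of the six-gene network (Bmal1, Rev-erbα,
  Per2, Cry1, Rorg, Dbp) to per-gene peak phases and relative
  amplitudes, returning the fitted model, residuals, cost breakdown
  and a `summary()` table.

Around them: `circadde.dde` (integration by fixed-step RK4 with
cubic-Hermite delayed-state interpolation, steady states, analytic
linearization, characteristic-equation Hopf-onset detection, parameter
scans), `circadde.clock` (the one-, two- and six-gene models,
knock-down and light-dark-forcing transforms, modulation-factor
traces), `circadde.phasors` (combinatorial phase theory: products of
periodic modulators, antiphase activator/inhibitor synergy, half-life
phase lags, attainable phase ranges per cis-element combination),
`circadde.qpcr` (Cp → quantity with primer efficiencies, reference-
gene geometric-mean normalization), `circadde.synthetic` (seeded
generator emulating the 2 h / 4-replicate qPCR design with lognormal
noise), and `circadde.fitting` (control analysis and the perturbation
experiments).  A `circadde` command-line tool exposes the experiment
pipeline (`simulate`, `scan`, `fit`, `knockdown`, `ld`, `control`,
`scale-transcription`, `synthesize`, `rhythm-fit`), each run writing
CSV outputs plus a JSON manifest.

## Worked example

Calibrate the one-gene delayed Per2 self-repressor and find its
oscillation onset:

```python
from circadde import calibrate_per2_model, hopf_onset, delay_scan

model, info = calibrate_per2_model()   # d from the Per2 half-life range,
print(info)                            # b fitted: 24 h rhythm at tau = 8 h
onset = hopf_onset(model, "tau:Per2:Per2", (2.0, 10.0))
print(onset.critical_value, onset.period_at_onset / onset.critical_value)
```

prints (calibration diagnostics abridged)

```
{'degradation': 0.2189, 'basal': 300.0, 'period_h': 23.892, ...}
5.598 2.993
```

i.e. the calibrated model crosses its Hopf bifurcation at a delay of
about 5.6 h — sustained rhythms need an over-critical delay — and the
period at onset is about three times the delay, squarely inside the
2–4× window that delayed negative feedback allows.

Fit the six-gene network to the measured liver phase map and probe it:

```python
from circadde import CoreClockModel, knockdown_curve

res = CoreClockModel().fit(n_starts=50, seed=0)
print(res.summary())
tab = knockdown_curve(res.model, "Rev-erba", [0.0], "Cry1",
                      targets=["Cry1"])   # delete Cry1's RRE input
print(tab[["fraction", "shift_h"]])
```

The summary table lists each gene's CT-aligned peak phase against its
target — with the shipped configuration it prints a free-running
period of 23.888 h and phases Bmal1 CT 1.4, Rev-erbα CT 9.3, Dbp
CT 10.9, Per2 CT 15.9, Rorg CT 21.0, Cry1 CT 22.5 (every residual
within 1.4 h of the measured CT 1 / 8 / 11 / 17 / 21 / 22 map, peak
order preserved) — plus the cost breakdown.  The knock-down table
reports that deleting the RRE input advances Cry1 by about +5.8 h, a
prediction the fit never saw, arising from the large amplitude of the
RRE modulator that dictates Cry1's late phase.

A fitted model ships as a preset (`circadde.cli.load_preset_model()`),
so the perturbation experiments can be run from the shell without
refitting, e.g. `circadde knockdown --preset cry1-rre` or
`circadde scale-transcription --scale 0.9`.

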