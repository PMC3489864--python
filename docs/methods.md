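# Methods

## Model

The package models the cell-autonomous liver circadian clock as a
small gene regulatory network in which transcriptional regulation acts
with explicit time delays.  Each mRNA species x_i obeys

    dx_i/dt = s_i * prod_k F_k( x_{r(k)}(t - tau_k) ) - d_i x_i

with linear degradation (rate d_i, 1/h) and a production term that is
a product of *modulation factors*, one per cis-regulatory
clock-controlled element (CCE): E-boxes, D-boxes, and ROR elements
(RREs).  Each factor is a bounded rational function of one delayed
regulator concentration, the thermodynamic form for independent
binding sites:

    activator:  F(x) = b (1 + f u) / (1 + u),   u = (x / s)^n
    inhibitor:  F(x) = b / (1 + u)

where n is the number of binding sites of that element, b the basal
rate contribution (recovered exactly when the regulator concentration
vanishes), f > 1 the fold activation, and s the saturation constant.
Because the elements act independently, the factors multiply.  The
explicit delay tau of each regulator lumps translation,
post-translational modification, complex formation and nuclear import
into a single lag of several hours, which removes all protein species
from the state.

Three instances are provided:

* **One gene.**  Delayed self-inhibition of *Per2* through its two
  E-box-like elements (n = 2).  Over-critical delays destabilize the
  fixed point through a Hopf bifurcation; the emerging period is two
  to four times the explicit delay.
* **Two genes.**  The nuclear-receptor loop: *Rev-erbα* activated by
  delayed *Bmal1* via three E-boxes, *Bmal1* inhibited by delayed
  *Rev-erbα* via two RREs.
* **Six genes.**  *Bmal1*, *Rev-erbα*, *Per2*, *Cry1*, *Rorg*, *Dbp*.
  The regulators are Bmal1 (E-box activator), Per2 (E-box inhibitor),
  Rev-erbα (RRE inhibitor) and Dbp (D-box activator); ROR activation
  of RREs and E4BP4 repression of D-boxes are folded into the
  Rev-erbα and Dbp terms by the antiphase-synergy reduction (an
  antiphase activator/inhibitor pair is equivalent, to first harmonic
  order, to a single regulator with enlarged amplitude).  Cry1 and
  Rorg are output genes: they are regulated but regulate nothing.

Site counts used per gene (element, regulator, sites): Bmal1 — RRE×2;
Rev-erbα — E×3 (both Bmal1 activation and Per2 inhibition); Per2 —
E×2 and D×1; Dbp — E×3; Cry1 — E×1, D×1, RRE×2; Rorg — E×2, D×1,
RRE×1.  The two intronic RREs of Cry1 and the 2E/3E/2R counts of
Per2/Rev-erbα/Bmal1 follow the experimental mapping of these
regulatory regions; Dbp's three E-boxes and the remaining counts
follow the canonical assignments for these loci.

## Numerics

Constant-delay DDEs are integrated by a fixed-step classical
Runge–Kutta scheme with the method of steps: states and derivatives
are stored on a uniform grid and delayed values are interpolated with
cubic Hermite polynomials, keeping the dense-output error at the
order of the step.  The step never exceeds a quarter of the smallest
positive delay (default 0.05–0.1 h).  The history segment keeps its
own derivative values so that interpolation near t = 0 does not leak
the solution's right-derivative across the initial discontinuity;
later discontinuity propagation points fall on grid nodes and the
solution is C¹ there, so no special handling is needed.  A pure
Python reference integrator (same scheme, arbitrary right-hand
sides) cross-checks the compiled kernel.

Steady states solve production(x, …, x) = d·x by a hybrid Newton
method.  Linearizations are analytic (the rational factors have
closed-form derivatives), grouped by distinct delay.  Hopf onsets are
located on the characteristic function det(λI − A0 − Σ A_τ e^(−λτ)):
complex-secant Newton iterations from a seed grid over the strip
Re λ ∈ [−0.6, 0.4], 0 < Im λ ≤ 2.5 1/h give the rightmost oscillatory
root, and the onset parameter is bracketed and bisected on its real
part.  The linear test equation x' = −k x(t−τ) (onset k·τ = π/2,
period 4τ) serves as the closed-form oracle.

Oscillation detection discards the leading 70% of a trajectory,
refines interior maxima parabolically, and declares a limit cycle
when the relative peak-to-trough amplitude exceeds 1e−3 and the peak
spacings have a coefficient of variation below 1%.  The amplitude
threshold separates numerical ringing from true limit cycles near a
Hopf point; the spacing criterion rejects quasiperiodic (torus)
dynamics of weakly coupled sub-oscillators.

## Calibration of the small models

The one-gene model fixes the degradation rate within the published
Per2 mRNA half-life range (1.5–4 h) and fits (d, b) jointly so the
8 h-delay model oscillates with a 24 h period and an order-one
relative amplitude (target 1.0: peak near twice the mean, trough near
zero, typical of mean-normalized clock-gene profiles).  The period at
fixed delay saturates logarithmically in b, so the basal rate is
searched inside a bounded box (5–300); the fit lands near d = 0.22/h
(half-life ≈ 3.2 h) and reproduces a 23.9 h period.  The Hopf onset
near 5.5–5.6 h and the onset period/delay ratio ≈ 3 are then
predictions of the calibrated model, not fitted quantities.

The two-gene loop fixes the delays at their measured anchors (Bmal1
4 h, Rev-erbα 2 h), bounds the degradations within ±50% of the 2 h /
1.5 h half-life anchors, and fits the remaining constants to a 24 h
period with the observed 17 h Rev-erbα→Bmal1 peak separation.

## Fitting the six-variable model

Targets are the measured liver free-running rhythms: peak phases
CT 1 (Bmal1), 8 (Rev-erbα), 11 (Dbp), 17 (Per2), 21 (Rorg), 22
(Cry1), relative amplitudes with Dbp largest and Rorg smallest
(0.9, 1.6, 1.8, 1.0, 0.4, 0.7 respectively), and a 24 h period.  The
cost is w_T²(P−24)² + w_φ² Σ (circular phase error)² + w_A² Σ (log
amplitude ratio)², with phases compared after a single global
rotation — the autonomous model has no intrinsic CT zero, so the
rotation minimizing the mean absolute circular error anchors all
genes jointly instead of pinning one; the mean-absolute alignment
objective can be flat over an interval of rotations, and ties are
broken toward the rotation that protects the worst-fitting gene.
Default weights w_T = 8, w_φ = 1, w_A = 3 (per hour and per
log-unit) weight the period strongly without overruling the phases.

The regulatory delays of Per2 (8.4 h) and Bmal1 (4 h) are fixed at
their printed anchors; the Rev-erbα and Dbp action delays are free in
[0.5, 3] h; core degradation rates float within ±50% of the half-life
anchors (Bmal1 2 h, Rev-erbα 1.5 h, Per2 2.8 h, Dbp 1.3 h; outputs
Cry1 5 h, Rorg 4 h — the long Cry1/Rorg half-lives produce their
late, broad peaks).

Because Cry1 and Rorg do not feed back, fitting proceeds in two
stages.  Stage A fits the recurrent four-gene core (20 parameters) by
multi-start bounded least squares on DDE simulations (320 h at 0.1 h
steps, 70% transient discard, period read from the last peak gaps
where the cycle is most converged); all starts get a cheap screening
pass (≤50 function evaluations), the leading eight are polished to
convergence, and every polished candidate is then re-scored on a
long fine-grid simulation (600 h at 0.05 h), because slowly
converging, marginal limit cycles look better on the coarse fitting
grid than they are.  BMAL1's E-box affinity scale is shared across
its target genes (the same heterodimer binding the same element
class; per-target strength differences live in the fold constants),
which keeps every E-box gene — Per2 included — firmly coupled to the
activating hub; the other factors carry per-factor saturations.  The
start list opens with two deterministic points (a generic mid-box
start and a curated warm start retained from an earlier fitting
campaign), which keeps the multi-start outcome stable across random
seeds.  Stage B fits each output gene on the core limit cycle by the
exact periodic response of a linear filter: the production trace p(t)
is known, and the periodic solution of y' = p − d y is
p̂_k/(d + ikω) harmonic by harmonic, so each cost evaluation is a
pair of FFTs; the output fits and the global CT rotation are
alternated until the six-gene alignment frame is self-consistent.

Two kinds of documented structural information resolve the
non-identifiability of a pure phase/amplitude fit:

* every experimentally verified cis-element must contribute a
  non-vanishing modulation (factor-trace relative amplitude ≥ 0.15,
  as a hinge penalty) — otherwise the optimizer can silently delete a
  verified regulation, e.g. decouple Per2 from BMAL1 entirely, after
  which the Per2 loop is only weakly locked to the rest of the
  network and single-input knock-outs destroy rhythmicity; Dbp's two
  E-box modulators are additionally kept at comparable amplitude, the
  D-box modulators are kept weak (amplitude ≤ 0.3 on Per2 and minor
  relative to Cry1's RRE and E-box modulators), reflecting the
  documented structure of the fitted network;
* candidate minima are scored with a penalty when the core stops
  oscillating (or shifts its period by more than 3%) under a 15%
  transcription-rate reduction, or stops oscillating when the D-box
  input is deleted — the physiological clock is resilient to
  transcription-rate fluctuations and the knock-out simulations all
  retain rhythms, so minima parked at the oscillation boundary are
  rejected as unphysiological.

Non-oscillating parameter points receive a large finite penalty that
decays with the observed amplitude, keeping the optimizer pointed
toward oscillatory regions without discontinuities.

The perturbation experiments on the fitted model — deletion of Cry1's
RRE input, Dbp knock-out, the 10% transcription-rate reduction, and
the light-dark forcing of Per2 — are run strictly out of sample: none
of their outcomes enters the fit.

## Perturbation readouts

Knock-downs multiply a regulator's concentration inside modulation
factors by a fraction in [0, 1] (0 deletes the input), leaving the
regulator's own dynamics untouched; restricting the scaling to one
target gene models deletion of a single cis-element.  Phase shifts
are read after re-anchoring the perturbed model's free phase on the
unperturbed phases of the non-readout genes.  Peak-order preservation
is judged with a 0.5 h tie tolerance, since Rorg and Cry1 peak within
half an hour of each other and their formal order is not meaningful.

Light-dark entrainment multiplies Per2's production by 1 + F during
the 12 h dark phase (systemic cues drive hepatic Per2 through
nocturnal activity and feeding), with edges smoothed over 0.1 h by
logistic ramps for integrator stability (a hard square wave is
available behind a flag).  Entrained phases are read in zeitgeber
time; free-running phases are put on the CT axis by alignment to the
fit targets.

## Rhythm analysis

Expression time courses are fitted by ordinary least squares on a
mean plus sine/cosine pairs at 24, 12 and 8 h (the 8 h harmonic is
included by default and configurable), replicates entering as
independent observations.  The fit is exact on any series generated
from the basis.  Peak time is the argmax of the fitted curve over one
cycle; below a relative-amplitude floor of 0.05 the phase is reported
as undefined rather than as a noisy number.  All phase arithmetic is
circular.  The CT-alignment objective (mean absolute circular error
over a rotation) is piecewise linear, so the exact optimum is found
by enumerating the per-gene offsets and their antipodes.

qPCR crossing points convert to relative quantities as E^(−Cp) with
per-primer efficiency E ∈ (1, 2]; each sample's targets are divided
by the geometric mean of the three constant reference genes (Hmbs,
Eif2A, Ppib).  Normalization is scale invariant per sample, and
quantities are comparable only within a gene.

## Synthetic data

The generator emulates the measurement design: truth profiles (sums
of 24/12/8 h harmonics, or a simulated trajectory), sampled every 2 h
over 24 h with 4 biological replicates, multiplied by unit-mean
lognormal noise with 10% coefficient of variation, encoded as Cp
values through the per-gene efficiency (defaults 1.95), plus three
constant reference genes under the same noise.  Technical replicates
are treated as pre-averaged upstream.  At zero noise the full
pipeline (Cp → quantities → reference normalization → harmonic
regression) is the identity on phases and amplitudes; under default
noise the median absolute 24 h-phase recovery error is below 0.5 h
across 200 seeds.  What passing these tests shows is that the
analysis chain is unbiased and correctly propagates the designed
noise structure; it does not validate features absent from the
generator — plate effects, Cp censoring, non-stationary noise, or
inter-animal phase dispersion beyond the lognormal replicate model.

## Problem sizes and defaults

Simulations use 320–480 h horizons (13–20 cycles) at 0.05–0.1 h
steps; fits use 50 starts (8 polished) for the core and 12–20 starts
per output gene; the control analysis perturbs each parameter by
±10% (±1–2% for local control coefficients); Monte-Carlo recovery
suites use 200 seeds.  These sizes give phase readouts reproducible
to well under 0.1 h while keeping a full fit in the minutes range on
one CPU core.

## Known limitations

Delays are constant and the model has no explicit protein species, so
mechanisms acting on protein stability or nuclear transport appear
only as changes of tau.  The fit resolves phases and amplitudes but
not absolute concentrations (basal rates and saturations trade off).
The combinatorial phase theory uses first-harmonic modulator
approximations and degrades for strongly non-sinusoidal modulators.
The attainable-phase intervals for CCE combinations depend on the
assumed modulator amplitude sweeps and half-life range and should be
read as qualitative windows, not sharp boundaries.
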