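# Methods

## The gating model

`cavclamp.channel_sim` represents a whole-cell population of Cav1.3
channels with independent first-order gates and a linear (ohmic) driving
force, the same functional form the analysis equations assume:

```
I_chan(t) = g_max · m(t) · h_VDI(t) · h_CDI(t) · (1 − b) · (V − V_rev)
```

with inward current negative, `V` the membrane potential (command voltage
plus the liquid-junction offset), and `b` the steady-state dihydropyridine
block `c/(c + IC50)` (Hill slope 1).

**Activation.** `m` relaxes toward the Boltzmann steady state
`m_∞(V) = 1/(1 + exp[−(V − V0.5,act)/k_act])` with a bell-shaped time
constant `τ_m(V) = τ_max / cosh((V − V_τ)/k_τ)`. Deactivation is carried by
two populations sharing `m_∞`: a fast pathway with `τ_m(V)` and a slow
pathway (`tail_slow_frac`, `tau_tail_slow`) whose time constant is the same
bell scaled to equal `tau_tail_slow` at −40 mV. This reproduces the
bi-exponential tail currents and their amplitude split. The bell peak sits
near the activation threshold (−30 mV), so activation at spike voltages
(0…+20 mV) is fast (≈0.1 ms) for every variant while the published
deactivation time constants at −60/−40 mV are matched exactly; a symmetric
bell centered at depolarized voltages would force slowly-deactivating
variants to also activate slowly and suppress their action-potential
currents, which contradicts the observed spike-evoked current amplitudes.

**Voltage-dependent inactivation (VDI).** Availability is
`h_VDI = f_fast·h_f + f_slow·h_s + f_persistent` — two gates plus a
non-inactivating pathway, because the 50 ms–5 s time course cannot be
matched by one exponential. Both gates share the steady state
`h_∞(V) = 1/(1 + exp[(V − V0.5,inact)/k_inact])`; their time constants
follow a shared bell `τ_i(V) = τ_i0 / cosh((V − v_tau_vdi)/tau_v_dep)`.
A monotone-exponential τ(V) cannot simultaneously keep multi-second
inactivation at V_max and let 5-s conditioning steps equilibrate at the
mid-voltages of the SSI curve (measured slope factors ≈5 mV); the bell —
slow near threshold, faster both toward deep depolarization and toward
recovery voltages — can, and its width is a calibrated parameter.

**Ca²⁺-dependent inactivation (CDI).** `h_CDI` is the weighted sum of two
sub-gates, each inactivating at a rate *linearly proportional to the
instantaneous inward Ca²⁺ current* (coupling in 1/pC) and recovering
first-order with its own time constant. Two sub-gates are needed because a
single flux-driven gate cannot reproduce the stretched, fast-then-slow Ca²⁺
inactivation profile together with its late plateau: the measured
`r_Ca/r_Ba` ratio falls from 1 to ≈0.7 within 50 ms but only to ≈0.47 over
the next 200 ms. Because the drive is the inward flux, CDI inherits the
channel's own U-shaped voltage dependence (maximal near V_max, weak near
the reversal potential) with no buffered Ca²⁺-domain model. With Ba²⁺ as
charge carrier, or coupling 0, `h_CDI ≡ 1` and the Ca²⁺/Ba²⁺ runs are
bit-identical for equal seeds.

**Artifacts.** Linear leak (`g_leak·V`, default 0.5 nS), Gaussian current
noise (default σ = 2 pA, seeded per sweep), ON/OFF-gating-charge
injections at step onsets (decaying exponential, integral `q_on_total`
scaled by ΔV relative to the −89 mV → V_rev step, τ_q = 0.2 ms), linear
run-down (%/min, applied at the pharmacology cadence), and the −9.3 mV
liquid-junction offset between command and membrane voltage. Capacitive
charging transients and series-resistance errors are not modeled.

**Integration.** Sampling is dt = 0.02 ms (50 kHz). On piecewise-constant
segments each linear gate advances by the exact one-step relaxation, so the
trajectory is independent of dt; inside ramps the same update is applied at
fixed dt. The CDI sub-gates are nonlinear (the flux drive contains h_CDI
itself) and advance by a semi-implicit fixed-dt update compiled with numba.
Gates reset to their holding-potential steady state between sweeps (the
5–30 s inter-sweep intervals are taken as full recovery); gap-free APW
trains are integrated continuously so inactivation accumulates across the
train.

## Analysis conventions

* Voltages are reported in the junction-corrected frame; protocols are
  built in the command frame and corrected by `preprocessing`.
* Peak currents are the extremum of a 3-sample-median-smoothed trace within
  the pulse window, excluding the first 1.5 ms after step onset (gating /
  charging transient). V_max ties break toward the more hyperpolarized
  voltage.
* Offline leak subtraction estimates the conductance from the final 60 % of
  the −89→−99 mV step and removes the line through the holding baseline;
  P/4 subtraction uses four quarter-amplitude mirrored sub-sweeps with
  pre-pulse baselines.
* The 100–1000 pA inclusion window is a per-cell rule applied to the
  maximal inward current (boundaries kept).
* G–V normalization divides the chord conductance `I/(V − V_rev)` by the
  fitted `G_max` of the I–V equation (robust near the reversal potential);
  voltages within 5 mV of V_rev are excluded in the pipeline (the
  standalone transform defaults to 2 mV).
* Fit initialization: V0.5 at the half-maximum voltage, k = 8 mV, bounds
  k ∈ (0.5, 30) mV, plateau ∈ [0, 0.9]. Tail fits use a 20-ms window,
  normalize by the extremum within the first 0.5 ms, relabel components so
  τ_fast < τ_slow, and fall back (flagged) to a single exponential when the
  time constants separate by less than 1.5×. The tail half-width is the
  full width at half-extremum of the *fitted* curve with the left crossing
  at t = 0; the tail area is the fitted-curve integral over the window.
* r-values are measured at offsets from the (blanked) peak, clipping the
  5000-ms offset to the final sample of the 5-s pulse.
* The steady-state inactivation protocol is analyzed with Ba²⁺ as charge
  carrier. The published plateau values track the Ba²⁺ (VDI-only) 5-s
  kinetics, not the much deeper Ca²⁺ ones; running SSI in Ca²⁺ would force
  the measured availability near V_max to equal the Ca²⁺ r₅₀₀₀ and make the
  published plateaus unreachable. Ba²⁺ SSI isolates the voltage-dependent
  availability that the plateau parameter describes.
* Dose–response: 30 sweeps at 0.1 Hz per concentration (3 drug-free
  baseline sweeps), run-down corrected against a drug-free control cell
  recorded at the same cadence, steady state read from the last 3 sweeps,
  concentrations {1, 3, 10, 30, 100, 300, 1000} nM. The 95 % CI is computed
  on log IC₅₀ and exponentiated.
* APW analysis: the repolarization window spans the +20→−70 mV downstroke
  and the afterhyperpolarization ramp; only inward current contributes to
  the Ca²⁺ charge; the pre-train reference is the maximal inward current of
  a 200-ms ramp from −89 to +80 mV (the ramp's parameters are a package
  choice; only its existence is prescribed). Train analyses run with leak
  disabled (online-subtracted) and, for tails, without gating-charge
  injections, whose OFF transient would otherwise contaminate the first
  0.5 ms of the fit window.
* Classification defaults: GOF if the activation midpoint shifts ≤ −5 mV,
  or the non-inactivating fraction grows by ≥ 10 points, or the
  subthreshold window current ratio reaches ≥ 2; LOF if activation shifts
  ≥ +3 mV with no enhancement rule firing; otherwise indeterminate. The
  cutoffs distill qualitative diagnostic language and are configurable.
  Group statistics use standard two-sample tests with Bonferroni
  adjustment across voltage families.

## Calibration of the packaged variant sets

`scripts/calibrate_variants.py` tunes each variant's parameters until the
*measured* pipeline outputs — not the raw parameters — match the published
per-construct statistics: fitted activation V0.5/k/V_rev, fitted SSI
V0.5/k/plateau, and the Ca²⁺ and Ba²⁺ r-values of a 5-s step to V_max.
Activation and SSI midpoints converge by fixed-point adjustment of the
underlying parameters; the VDI split/τs (plus the τ(V) bell width) and the
CDI couplings are least-squares fits through full sweep simulations. The
microscopic IC₅₀ is likewise adjusted so the *apparent* IC₅₀ matches the
published value: block reduces Ca²⁺ flux and hence CDI, which biases the
apparent IC₅₀ upward by ~10–15 % relative to the microscopic constant.
Conductances are scaled to a ≈420 pA peak (12 pF, ≈35 pA/pF), inside the
inclusion window.

Achieved agreement (noiseless, full pipeline): activation and inactivation
midpoints within 0.15 mV, slope factors within 0.1 mV, plateaus within
0.7 points, Ca²⁺ r-values within 1.6 points, early Ba²⁺ r-values within
1.5 points. One published pair is *not* jointly reachable: the SSI plateau
(e.g. 22.5 % for the long wild-type) and the Ba²⁺ r₅₀₀₀ (30.26 %) both
measure availability after a 5-s depolarization at nearly the same voltage
yet differ by ~8 points between the underlying cell cohorts. Calibration
weights the SSI curve (which feeds the classifier) and the Ca²⁺ time
course above the late Ba²⁺ points, which consequently run up to ~8 points
low at 1–5 s. The S652W_L set has no published Ba²⁺ kinetics; its VDI is
fitted to the Ca²⁺ r-values with CDI carried over from WT_L. Short-variant
IC₅₀s reuse the long-variant values (only the long constructs were
characterized pharmacologically), and tail parameters for the short
variants reuse the corresponding long-variant kinetics.

## What the generator does and does not emulate

The simulator reproduces the *means* of the published gating statistics
under idealized recording conditions: one synthetic cell per condition,
optional Gaussian noise, exact linear leak, no capacitive transients, no
series-resistance error, no cell-to-cell parameter scatter, and ohmic
(not GHK) permeation. Passing tests therefore demonstrate that the
analysis chain recovers known ground truth and the direction and size of
the mutation effects — they do not certify performance on real recordings
with correlated noise, imperfect compensation, endogenous currents, or
biological variance. Figure-only quantities that rest on real current
densities (absolute APW peak amplitudes, the −40 mV window-current ratio)
are checked as directions of effect, not values; notably, with
Table-calibrated Boltzmann curves the mutant/WT window ratio at −40 mV is
≈1 (activation gain and availability loss cancel) while at −50/−45 mV the
mutant window is >2× WT, consistent with the observation that subthreshold
window current was measurable only in the mutant.

## Problem sizes

Default study conditions: 30-sweep I–V families (−80…+65 mV, Δ5 mV),
15-sweep SSI families (−109…+31 mV, Δ10 mV), single 5-s inactivation
sweeps per carrier, 300-sweep 10-Hz APW trains, 30 sweeps per drug
concentration, all at 50 kHz. The full suite simulates a few hundred
sweeps and runs in well under a minute on one CPU; parameter-recovery
properties use 100–400 synthetic replicates at the points level rather
than full re-simulation.

## Known limitations

* Single deterministic "cell" per condition: group statistics on simulated
  data require explicitly planted scatter.
* CDI is phenomenological (flux-driven sub-gates), not a calmodulin-lobe
  mechanism; its recovery kinetics at sustained depolarization are only
  constrained by the 5-s time course.
* The DHP block is steady-state; no state-dependent (modulated-receptor)
  kinetics, so use-dependence of block is outside scope.
* Gating charge is linear in ΔV and injected only at step boundaries, a
  minimal model sufficient for the Q_ON/I_tail analyses.
* The late Ba²⁺ r-values deviate from the published ones by design (see
  Calibration above).
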