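# cavclamp

Whole-cell voltage-clamp simulation and gating analysis for Cav1.3
(*CACNA1D*) L-type Ca²⁺-channel variants.

De novo *CACNA1D* missense variants cause neurodevelopmental disorders when
— and only when — they *enhance* Cav1.3 channel function: hyperpolarized
activation, larger subthreshold window currents, slowed inactivation or
deactivation. Classifying a variant as gain- or loss-of-function (GOF/LOF)
therefore requires the full biophysical workup that channel labs run on
tsA-201/HEK-293 whole-cell recordings. `cavclamp` implements that workup as
a tested pipeline, together with a kinetic gating simulator so every stage
can be exercised without any recordings:

* **protocols** — the standard command-voltage families: 50-ms I–V steps
  (Δ5 mV), 5-s steady-state-inactivation (SSI) conditioning, tail-current
  repolarizations, 100-ms pharmacology steps at 0.1 Hz, and 10-Hz
  action-potential-waveform (APW) trains.
* **channel_sim** — a Hodgkin–Huxley-style Cav1.3 model: Boltzmann
  activation with fast/slow deactivation pathways, bi-exponential
  voltage-dependent inactivation (VDI) with a persistent fraction,
  Ca²⁺-dependent inactivation (CDI) driven by instantaneous inward flux,
  ON-gating-charge injections, leak, dihydropyridine block, run-down and
  recording noise. Packaged parameter sets: `WT_L`, `WT_S`, `S652L_L`,
  `S652L_S`, `S652W_L`, calibrated so the analysis pipeline reproduces the
  published gating statistics of each construct.
* **preprocessing** — liquid-junction correction (−9.3 mV), offline and P/4
  leak subtraction, density normalization, and the prospective 100–1000 pA
  amplitude inclusion rule.
* **gating_analysis** — every fitted statistic of the workup:

  I–V: `I(V) = G_max (V − V_rev) / (1 + exp[−(V − V_0.5)/k])`
  G–V: `G/G_max = 1 / (1 + exp[−(V − V_0.5)/k])`
  SSI: `S(V) = (1 − plateau) / (1 + exp[(V − V_0.5,inact)/k_inact]) + plateau`

  plus window currents (SSI × current density), the inactivation time
  course r₅₀…r₅₀₀₀, CDI strength `f = (r_Ba − r_Ca)/100` and
  `CDI = 1 − r_Ca/r_Ba`, persistent currents, bi-exponential tail fits, and
  the I_tail/Q_ON open-probability proxy.
* **pharmacology** — run-down-corrected isradipine concentration–response
  with constrained Hill fits (slope 1, 0–100 fixed) and extra-sum-of-squares
  F comparison of IC₅₀s.
* **ap_train_analysis** — APW-train peaks, train decay, cumulative Ca²⁺
  charge and fluorescence normalization.
* **classify_report** — the rule-based GOF/LOF verdict and report rendering.

## Worked example

```python
from cavclamp import load_variant
from cavclamp.channel_sim import SimConfig
from cavclamp.classify_report import classify_variant
from cavclamp.pipeline import variant_gating_fits

cfg = SimConfig(noise_sd=0.0, seed=1)
wt = variant_gating_fits(load_variant("WT_L"), cfg)
mut = variant_gating_fits(load_variant("S652L_L"), cfg)
print(f"WT_L   V0.5,act {wt.activation.v_half_act:+6.2f} mV, "
      f"V0.5,inact {wt.inactivation.v_half_inact:+6.2f} mV")
print(f"S652L_L V0.5,act {mut.activation.v_half_act:+6.2f} mV, "
      f"V0.5,inact {mut.inactivation.v_half_inact:+6.2f} mV")
v = classify_variant(wt, mut)
print(f"verdict: {v.verdict} (activation shift {v.delta_v_act:+.1f} mV)")
```

prints

```
WT_L   V0.5,act  -0.19 mV, V0.5,inact -25.70 mV
S652L_L V0.5,act -16.35 mV, V0.5,inact -43.30 mV
verdict: GOF (activation shift -16.2 mV)
```

i.e. the S652L mutation shifts both the half-maximal activation and
inactivation voltages ~16–18 mV hyperpolarized — channels open at
subthreshold potentials where wild-type channels are silent — which the
classifier calls a gain of function. The same pipeline on `S652W_L` yields
a +4.5 mV depolarized shift and an LOF verdict.

## Analysis scripts

The study itself is a sequence of numbered drivers under `analysis/`, each
a thin narrative over the library that writes its tables to `results/`:

```
python analysis/01_simulate_recordings.py   # example raw sweep archives
python analysis/02_gating_fits.py           # activation/SSI/window tables
python analysis/03_inactivation_cdi.py      # r-values, CDI, f(V) U-shape
python analysis/04_tail_and_train.py        # tail kinetics, APW trains
python analysis/05_pharmacology.py          # isradipine IC50s + F test
python analysis/06_classify.py              # GOF/LOF verdicts + report
```

`scripts/calibrate_variants.py` regenerates the packaged variant parameter
files from the published gating statistics (it is how they were produced).

## Layout

```
src/cavclamp/        library (all computation lives here)
src/cavclamp/data/   calibrated variant parameter files (JSON)
analysis/            numbered study drivers
scripts/             calibration + acceptance entry points
tests/               pytest suite (unit, property, end-to-end)
docs/methods.md      model description, assumptions, limitations
```
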