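# phasicz

Phasic impedance modulation of cardiac tissue: quasi-active linearization of
ionic models, extracellular mapping, and windowed demodulation of
two-electrode recordings.

## The problem

The impedance of the cardiac cell membrane is not a constant: it changes
through the phases of every action potential as voltage-gated channels open
and close. Around any state point the membrane behaves as a *quasi-active*
linear system whose admittance at angular test frequency ω is

    1/Z(ω) = ∂I/∂V − iωC + Σᵢ (1 − iωτᵢ(V))⁻¹ · (dfᵢ^eq/dV) · (∂I/∂fᵢ)

where `I(V, f₁…fₙ; P)` is the total membrane current, `C` the membrane
capacitance, and each Hodgkin-Huxley gate `fᵢ` relaxes to `fᵢ^eq(V)` with
time constant `τᵢ(V)`. The static term is the instantaneous channel
conductance, the capacitive term the membrane reactance, and the dynamic sum
is the contribution of gating: gates fast against the test signal act as
extra conductance, slow gates lag the voltage and behave as a
*phenomenological inductance*.

Evaluated along a rabbit ventricular action potential (the 26-variable
Mahajan-Shiferaw myocyte model), this produces a characteristic pattern of
five deflections — a, b, a′, b′, c: a sharp impedance collapse at the
upstroke driven by sodium-channel activation (b), and a sustained impedance
rise through the plateau driven by the conductance collapse of the inward
rectifier I_K1 (c). Seen through an extracellular electrode, whose current
is mostly shunted by the interstitium, the same pattern survives as a
strongly compressed *dip and dome* of a few ohms on a few-hundred-ohm
baseline. This package predicts that signal, synthesizes realistic raw
recordings of it, and recovers it by windowed Lomb-Scargle demodulation —
the full chain from ionic model to measured impedance trace.

For whom: cardiac electrophysiologists and modellers who want to predict or
interpret phasic impedance signals, and anyone building impedance-based
tissue-state readouts.

## Worked example

```python
from phasicz import Mahajan, simulate_ap
from phasicz.impedance import TestSignalSpec, impedance_trace, extract_deflections
from phasicz.tissue import TissueParams, extracellular_from_membrane, delta_Z_ext

model = Mahajan()
traj = simulate_ap(model, dt=0.01)          # 20 paced beats at CL 400 ms
zt = impedance_trace(model, traj, TestSignalSpec(50.0), stride=10)
f = extract_deflections(zt, traj)
print(f"APD90      {traj.apd90[-1]:.1f} ms")
print(f"Z_rest     {f.Z_rest/1e6:.2f} MOhm")
print(f"dip ratio  {f.dip_ratio:.3f}")
print(f"dZ/Z       {100*f.deltaZ_rel:.1f} %")

tr = extracellular_from_membrane(zt, TissueParams())
dZ, rel = delta_Z_ext(tr, traj)
print(f"extracellular dome  {dZ:.2f} Ohm ({100*rel:.2f} %)")
```

prints (about half a minute on one CPU):

```
APD90      201.6 ms
Z_rest     8.65 MOhm
dip ratio  0.033
dZ/Z       20.1 %
extracellular dome  2.53 Ohm (0.86 %)
```

Reading: at a 50 Hz test frequency the resting single-cell impedance is
8.65 MΩ (for C = 3.1·10⁻⁴ µF); at the upstroke it collapses to 3% of rest
for under a millisecond; through the plateau it rises 20% above rest. The
calibrated tissue divider compresses that modulation to a 2.5 Ω dome on a
~300 Ω extracellular baseline — below 1% relative, which is why detecting it
needs a dedicated demodulation pipeline.

The same stages are scriptable from the shell:

```sh
phasicz impedance --model mahajan --freq 50 --out trace.csv
phasicz sweep --freqs 20,50,100,200,400,800 --remove-capacitance
phasicz synth --ftest 1000 --i0 0.02 --dome 3 --seed 42 --out rec.npz
phasicz demod rec.npz --window-ms 10 --out result.csv
phasicz run docs/config_template.yaml
```

`phasicz run` chains simulate → linearize → extracellularize → window →
synthesize → demodulate and writes a manifest with content hashes, so a
config plus a seed reproduces a run byte-for-byte.

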