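# Methods

## Quasi-active impedance of an ionic model

A generic cardiac membrane model is the charge balance
`C dV/dt = −I(V, f₁…fₙ; P) + Iext` with Hodgkin-Huxley gates
`dfᵢ/dt = −(fᵢ − fᵢ^eq(V))/τᵢ(V)` and auxiliary state `P` (ion
concentrations, buffers, Markov-chain occupancies). Linearizing around a
state point and driving with a sinusoidal test current gives the admittance

    Y(ω) = ∂I/∂V − iωC + Σᵢ (1 − iωτᵢ)⁻¹ (dfᵢ^eq/dV)(∂I/∂fᵢ),   Z = 1/Y.

Assumptions baked into this formula, and into the package:

* **Small signals.** Only the first-order response is modelled; harmonic
  distortion of large test currents is out of scope.
* **Frozen auxiliary state.** `P` contributes through `∂I/∂V` only. For the
  rabbit ventricular model this means the six L-type Markov occupancies and
  all concentrations are static on the test-signal time scale; the ten
  Hodgkin-Huxley gates alone form the dynamic sum.
* **Gates near their equilibrium manifold.** The gate equations are
  linearized about `fᵢ = fᵢ^eq(V)`. Along an action potential the gates are
  not exactly at equilibrium and a literal state Jacobian carries an extra
  `(fᵢ^eq − fᵢ)·d(1/τᵢ)/dV` term; the test suite measures this quasi-static
  approximation error at below 1% of |Z| across the beat.
* **Phasor convention.** The formula is evaluated exactly as written
  (capacitive term `−iωC`, gate factor `(1−iωτ)⁻¹`), which is the complex
  conjugate of the `e^{+iωt}` transfer function of the linearized ODEs.
  Magnitudes — every quantitative statistic here — are convention-free;
  reported phases follow this convention (capacitive limit → +90°).

All partial derivatives are obtained by forward-mode automatic
differentiation with vector-valued dual numbers pushed through the model's
own rate-law code. One seeded evaluation yields ∂I/∂V and all ∂I/∂fᵢ
simultaneously; `dfᵢ^eq/dV` comes from a dual pass through the gate
kinetics. There is no symbolic expansion and no finite differencing in the
production path; finite differences appear only as independent oracles in
the tests.

Units are fixed package-wide: mV, ms, µA, µF — so conductances arise in mS
(reported in S or nS) and impedances in kΩ (reported in Ω). Angular
frequency is rad/ms internally, `ω = 2π f/1000` for `f` in Hz.

## Ionic models

**Hodgkin-Huxley** (squid axon, modern convention, rest ≈ −65 mV, C = 1 µF
for 1 cm²) serves as the analytically tractable benchmark: its 4-state
(V, m, h, n) subsystem can be linearized densely and compared against the
closed-form impedance.

**Rabbit ventricular myocyte** (26 state variables: V; m, h, j, xr, xs1,
xs2, xtos, ytos, xtof, ytof; cytosolic/submembrane/SR/junctional-SR/dyadic
calcium, the whole-cell SR release flux and intracellular sodium; two
troponin buffer occupancies; six L-type Markov occupancies with the open
state as their complement). The membrane-current formulations — fast sodium,
inward rectifier, rapid and slow delayed rectifiers, the two transient
outward components, Na/K pump, Na/Ca exchanger, and the 7-state Markov
L-type channel with GHK flux — are transcribed from the model's original
publication. Default capacitance is C = 3.1·10⁻⁴ µF (a standard ventricular
cell); absolute impedances scale as 1/C, so the primary comparable outputs
are relative features (dip ratio, ΔZ/Z).

**Calcium-subsystem calibration.** The whole-cell SR-release gain and the
dyadic-coupling strengths are implemented structurally (graded release with
a piecewise SR-load gain breaking at 50 and 90 µM, an L-type-triggered drive
`po·|i_Ca|`, a voltage sigmoid that shuts release off at diastolic
potentials, release-flux relaxation with τ = 30 ms; a dyadic pool relaxing
to the submembrane space with τ = 0.5 ms) with three gain constants
(`g_rel = 2`, `gdyad = 500`, `rel_dyad = 10`) calibrated once against the
published whole-cell phenotype: APD90 ≈ 200 ms at a 400 ms cycle, calcium
transient ≈ 0.12 → 1.3 µM, roughly half the SR content released per beat,
peak L-type current ≈ −6 µA/µF, stable 1:1 pacing with < 0.3 ms
beat-to-beat APD drift, resting potential −87.8 mV. These constants were
fixed from AP/calcium behavior before any impedance statistic was computed
and are not tuned further. Consequence to keep in mind: quantities that are
steeply sensitive to the resting slope conductance (notably ΔZ/Z at low
test frequencies, which this package computes as 20% at 50 Hz) inherit an
uncertainty of a few percentage points from the transcription.

**Integration.** Explicit Euler for V and P, exact exponential (Rush-Larsen)
updates for the gates at the pre-step voltage, dt = 0.01 ms by default. The
gate update is unconditionally stable and exact for frozen voltage. Pacing
default: cycle length 400 ms, 20 beats, 1 ms pulse at twice the measured
diastolic threshold (Mahajan: 2 × 27.4 µA/µF; HH: 2 × 7 µA). The analysis
window is the final beat plus 100 ms of preceding diastole. Blow-ups raise
an error naming the offending state variable; a beat whose maximal dV/dt
stays below 1 mV/ms raises a stimulus-failure error.

## Deflection features

On the |Z|(t) trace of one beat: resting impedance is the median over the
window 50–10 ms before the stimulus; **b** is the global minimum within
±5 ms of the upstroke (read from the raw trace); **a** and **a′** are the
local maxima immediately before and after b; **c** is the maximum between
30% and 95% of APD90 after the upstroke; **b′** is the local minimum between
a′ and c. ΔZ = |Z|_c − Z_rest and ΔZ/Z = ΔZ/Z_rest ignore the phase-0 dip by
construction; dip ratio = |Z|_b/Z_rest. Slow-wave extrema are located on a
1 ms moving-average of the magnitude so that the fast oscillation of |Z|
inside the phase-0 transient is not mistaken for plateau waves; ties resolve
to the earliest sample; a missing extremum is reported as absent, never
fabricated.

## Extracellular mapping

The interstitium shunts most of the injected current, so a contact electrode
sees a strongly compressed copy of the membrane impedance. The package maps
the membrane trace through a lumped access/shunt divider

    |Zext(t)| = R_access + R_shunt·x/(R_shunt + x),   x = |Z_m(t)|/N_cells,

a deliberate stand-in for a full bidomain treatment of the electrode-tissue
geometry, isolated behind one function so a PDE-based mapping can replace
it. The divider acts on the impedance *magnitude*: during phase 0 the
quasi-active membrane impedance has a negative real part, and a literal
complex parallel combination becomes near-singular when the membrane branch
crosses the shunt resistance, producing an unphysical resonance spike; the
magnitude form is monotone and bounded between R_access and
R_access + R_shunt, which is the behavior the stand-in must preserve.
Defaults (R_access = 100 Ω, R_shunt = 210 Ω, N_cells = 3433, i.e. a 2.5 kΩ
membrane branch at rest) are calibrated so the resting extracellular
impedance is ≈ 294 Ω, the dome is ≈ 2.5 Ω (inside the experimentally
observed 2–4 Ω band) and the relative modulation is < 1%. Window averaging
(non-overlapping, starting at the first sample, arithmetic mean of the
magnitude with a circular mean of phase, stamped at window centres, trailing
partial window dropped) at 10 ms reproduces the measured topology: the a/a′
waves vanish and b/b′ merge into a single dip — the dip and dome.

## Synthetic recordings

The generator emulates the measurement chain: 30 kHz sampling,
`y(t) = MAP(t) + I0·|Z(t)|·sin(φ + arg Z) + noise (+ motion)`, with the
per-sample test phase φ stored alongside, every component retained as ground
truth, and optional 16-bit quantization. Defaults: 1 kHz test frequency,
I0 = 0.02 mA, a 3 Ω raised-cosine dome (experimental band 2–4 Ω) and a
60 Ω × 1 ms rectangular dip (the dip depth the calibrated tissue pipeline
actually produces) on a 300 Ω baseline; MAP amplitude 15 mV with a 3 ms
logistic upstroke — contact-electrode MAP upstrokes are slower than
transmembrane upstrokes, and the electrogram's in-band content at 1 kHz must
be small for the measured controls to be clean, as they are experimentally;
noise_sd = 0.12 mV, chosen so the recovered-impedance noise floor is
≈ 0.5 Ω, the level reported for the real system. Impedance phase modulation
is supported but defaults to magnitude-only. The motion artifact (off by
default) is a smooth bump peaking ≈ 220 ms after the upstroke with a
diastolic tail.

What the generator does *not* emulate: electrode polarization and
double-layer electrochemistry, amplifier nonlinearity, beat-to-beat
morphology variability, and real motion. Passing the recovery tests
therefore demonstrates the correctness and calibration-level noise behavior
of the processing chain, not robustness to every artifact of a live
preparation.

## Demodulation

The recording is cut into non-overlapping 10 ms windows (each must hold at
least 5 test cycles, so 500–1000 Hz test frequencies are the intended
range). Within a window, amplitude and phase at the test frequency are the
least-squares fit of `a·sin φ + b·cos φ` plus a local polynomial trend —
the Lomb-Scargle estimate at the known transmitted phase, so no frequency
search is needed. The trend order defaults to 3: a DC-only fit leaks the
electrogram's within-window variation into the amplitude at the ~12 Ω level
per upstroke (the analytic leak of a ramp ΔV over k cycles is ΔV/(πk)),
which would bury the genuine dip and produce spurious dips in unmodulated
controls; a local cubic absorbs the electrogram trend and brings cross-talk
below the noise floor, restoring the experimentally observed clean
controls. Windows are processed independently; timestamps are window
centres; both the magnitude and the in-phase component are reported.
Degenerate phase coverage raises a conditioning error.

The MAP channel is recovered by a frequency-domain Wiener filter
`H = S_ref/(S_ref + max(S_y − S_ref, 0))` with Welch-averaged spectra
(segment length 4096 by default) from a no-test-signal control recording,
interpolated onto the FFT grid. Impedance series are optionally smoothed
with a third-order Savitzky-Golay filter (default window 9 points;
polynomial endpoint handling).

## Pipeline, seeds, problem sizes

`phasicz run` chains all stages and writes a manifest with package version,
config, per-stage timings, and SHA-256 hashes of every output; identical
config + seed gives identical hashes. A single top-level seed fans out to
per-stage substreams through a seed sequence; the physiological stages are
deterministic, so the seed only drives the synthetic-recording noise.

Default problem sizes, chosen to keep any stage within tens of seconds on
one CPU: 20 paced beats at dt = 0.01 ms for steady state; impedance
evaluated every 0.1 ms (stride 10) along one beat (5001 points); recordings
of 0.5–1 s at 30 kHz; Monte-Carlo checks over 100 seeds.

## Known limitations

* The calcium-cycling gains are calibrated to the published whole-cell
  phenotype rather than transcribed, so calcium-sensitive details (and,
  indirectly, the resting conductance that sets ΔZ/Z at low frequencies)
  carry a few-percent uncertainty.
* The extracellular mapping is a lumped divider, not a bidomain solution;
  it preserves scaling, compression and windowed topology but has no
  electrode geometry in it.
* Linear response only; no harmonic analysis, no spatial propagation, no
  multi-electrode or multi-frequency motion-artifact rejection.
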