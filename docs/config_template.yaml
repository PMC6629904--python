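# phasicz run configuration (YAML). Every key is optional; the values below
# are the defaults. Run with:  phasicz run config.yaml

model: mahajan          # registered ionic model: mahajan | hh
dt: 0.01                # integration step, ms

protocol:               # pacing; null -> per-model default
  cycle_length: 400.0   # ms
  n_beats: 20           # pre-beats to reach steady state
  amplitude: 0.01705    # uA (Mahajan default: 55 uA/uF x 3.1e-4 uF)
  duration: 1.0         # ms

test_frequency: 50.0    # Hz, linearization stage
impedance_stride: 10    # evaluate impedance every N-th trajectory sample

tissue:                 # extracellular access/shunt divider
  R_access: 100.0       # Ohm
  R_shunt: 210.0        # Ohm
  N_cells: 3433.0       # effective membrane units in parallel
  baseline_Z: null      # optional calibration target, Ohm

window_ms: 10.0         # extracellular down-sampling window

recording_f_test: 1000.0  # Hz, synthetic-recording test frequency
recording_I0: 0.02        # mA, test current amplitude (0.01-0.03)
recording_noise_sd: 0.12  # mV, amplifier noise (-> ~0.5 Ohm noise floor)

window_plan:            # demodulation windows
  window_ms: 10.0       # must hold >= min_cycles of the test signal
  min_cycles: 5
  trend_order: 3        # local polynomial absorbed per window (0 = DC only)

out_dir: phasicz_run    # output directory (traces, recording, manifest)
seed: 0                 # single seed; fans out to per-stage substreams
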