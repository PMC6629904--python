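"""Synthetic two-electrode recordings with ground truth.

Emulates the experimental measurement chain: a monophasic-action-potential
(MAP) shaped electrogram, plus a sinusoidal test current I0·sin(ωt) whose
voltage response is amplitude-modulated by the instantaneous extracellular
impedance, plus white amplifier noise and an optional motion artifact.  The
generator stores every component separately, so demodulation can be tested
against exact ground truth with no external data.

Defaults follow the experimental setup: 30 kHz sampling, 1000 Hz test
frequency, I0 in the 0.01-0.03 mA range, an impedance dome of ~3 Ω on a
~300 Ω baseline with a ~1 ms dip at the upstroke.  The noise level defaults
to the value that puts the recovered-impedance noise floor near 0.5 Ω.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import AliasingError

__all__ = ["MAPTemplate", "MotionArtifact", "DomeDipProfile",
           "RecordingParams", "SyntheticRecording",
           "generate_recording", "crosstalk_control",
           "write_recording", "read_recording"]


@dataclass
class MAPTemplate:
    """Parametric monophasic-action-potential waveform.

    A logistic upstroke (1-2 ms), a gently sloping plateau, and an
    exponential phase-3 return to baseline.  Independent of the ionic
    models, so demodulation can be exercised in isolation; a simulated AP
    resampled onto the recording grid can be substituted via ``waveform``.
    """

    amplitude: float = 15.0      # mV
    upstroke_ms: float = 3.0     # 10-90% rise time of the logistic upstroke
    apd_ms: float = 180.0        # plateau + phase-3 span
    plateau_sag: float = 0.25    # fractional amplitude lost across plateau
    tau3_ms: float = 18.0        # phase-3 exponential time constant

    def waveform(self, t_ms: np.ndarray, t_up: float) -> np.ndarray:
        """Evaluate one beat's waveform for sample times t_ms (upstroke at
        t_up)."""
        x = t_ms - t_up
        up = 1.0 / (1.0 + np.exp(np.clip(-x / (self.upstroke_ms / 4.0),
                                         -500.0, 500.0)))
        sag = 1.0 - self.plateau_sag * np.clip(x, 0.0, self.apd_ms) / self.apd_ms
        rep = np.where(x > self.apd_ms,
                       np.exp(-(np.maximum(x - self.apd_ms, 0.0)) / self.tau3_ms),
                       1.0)
        return self.amplitude * up * sag * rep


@dataclass
class MotionArtifact:
    """Smooth bump peaking after the AP with a diastolic tail."""

    amplitude: float = 2.0       # mV
    peak_delay_ms: float = 220.0  # after the upstroke
    width_ms: float = 120.0      # gaussian width

    def waveform(self, t_ms: np.ndarray, t_up: float) -> np.ndarray:
        x = t_ms - t_up - self.peak_delay_ms
        return self.amplitude * np.exp(-0.5 * (x / self.width_ms) ** 2)


@dataclass
class DomeDipProfile:
    """Parametric ground-truth extracellular impedance |Z|(t).

    A rectangular dip of ``dip_ms`` at the upstroke (sodium transient) and a
    smooth raised-cosine dome across the plateau (inward-rectifier
    suppression), on a constant baseline.
    """

    baseline: float = 300.0      # Ohm
    dome: float = 3.0            # Ohm, dome amplitude (experimental 2-4)
    dip_depth: float = 60.0      # Ohm; matches the tissue-divider dip scale
    dip_ms: float = 1.0          # ms
    dome_start_ms: float = 20.0  # after upstroke
    dome_end_ms: float = 180.0   # after upstroke (~APD)

    def magnitude(self, t_ms: np.ndarray, upstrokes) -> np.ndarray:
        z = np.full_like(t_ms, self.baseline, dtype=float)
        for t_up in upstrokes:
            x = t_ms - t_up
            in_dome = (x >= self.dome_start_ms) & (x <= self.dome_end_ms)
            span = self.dome_end_ms - self.dome_start_ms
            z[in_dome] += self.dome * 0.5 * (
                1.0 - np.cos(2.0 * np.pi * (x[in_dome] - self.dome_start_ms) / span))
            z[(x >= 0.0) & (x < self.dip_ms)] -= self.dip_depth
        return z


@dataclass
class RecordingParams:
    """Configuration of one synthetic recording."""

    fs: float = 30000.0          # Hz
    f_test: float = 1000.0       # Hz
    I0: float = 0.02             # mA (0.01-0.03 experimentally)
    duration: float = 1.0        # s
    cycle_length_ms: float = 400.0
    first_upstroke_ms: float = 100.0
    Z_profile: DomeDipProfile | np.ndarray = field(default_factory=DomeDipProfile)
    map_template: MAPTemplate | None = field(default_factory=MAPTemplate)
    noise_sd: float = 0.12       # mV
    motion: MotionArtifact | None = None
    quantize_bits: int | None = None
    quantize_range_mV: float = 50.0
    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 2.0 * self.f_test:
            raise AliasingError(
                f"fs = {self.fs} Hz must exceed twice the test frequency "
                f"({self.f_test} Hz)")
        if self.I0 <= 0:
            raise ValueError("I0 must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @property
    def upstroke_times_ms(self) -> np.ndarray:
        total_ms = self.duration * 1000.0
        return np.arange(self.first_upstroke_ms, total_ms, self.cycle_length_ms)


@dataclass
class SyntheticRecording:
    """A raw recording y(t) with per-sample ground truth."""

    times: np.ndarray            # s
    y: np.ndarray                # mV
    phi: np.ndarray              # rad, instantaneous test phase (unwrapped)
    truth_Z: np.ndarray          # complex Ohm
    truth_map: np.ndarray        # mV, clean electrogram (incl. motion = 0)
    test_component: np.ndarray   # mV, the modulated sinusoid alone
    noise: np.ndarray            # mV
    motion_component: np.ndarray  # mV
    params: RecordingParams

    def __len__(self) -> int:
        return len(self.times)

    @property
    def fs(self) -> float:
        return self.params.fs


def generate_recording(params: RecordingParams) -> SyntheticRecording:
    """Build a synthetic recording; deterministic for a given seed."""
    params.validate()
    n = int(round(params.duration * params.fs))
    t_s = np.arange(n) / params.fs
    t_ms = t_s * 1000.0
    phi = 2.0 * np.pi * params.f_test * t_s

    ups = params.upstroke_times_ms
    if isinstance(params.Z_profile, np.ndarray):
        if len(params.Z_profile) != n:
            raise ValueError("explicit Z_profile must match the sample count")
        truth_Z = params.Z_profile.astype(complex)
    else:
        truth_Z = params.Z_profile.magnitude(t_ms, ups).astype(complex)

    truth_map = np.zeros(n)
    if params.map_template is not None:
        for t_up in ups:
            truth_map += params.map_template.waveform(t_ms, t_up)

    motion = np.zeros(n)
    if params.motion is not None:
        for t_up in ups:
            motion += params.motion.waveform(t_ms, t_up)

    # I0 [mA] * |Z| [Ohm] = mV; impedance phase shifts the test component
    test = params.I0 * np.abs(truth_Z) * np.sin(phi + np.angle(truth_Z))

    rng = np.random.default_rng(params.seed)
    noise = rng.normal(0.0, params.noise_sd, n) if params.noise_sd > 0 else np.zeros(n)

    y = truth_map + test + noise + motion
    if params.quantize_bits is not None:
        lsb = 2.0 * params.quantize_range_mV / 2 ** params.quantize_bits
        y = np.round(y / lsb) * lsb

    return SyntheticRecording(times=t_s, y=y, phi=phi, truth_Z=truth_Z,
                              truth_map=truth_map, test_component=test,
                              noise=noise, motion_component=motion,
                              params=params)


def crosstalk_control(rec: SyntheticRecording) -> SyntheticRecording:
    """Replace the modulated test component by an unmodulated sinusoid.

    The inserted sinusoid keeps the test frequency and phase and takes the
    time-median amplitude of the original test component; electrogram,
    noise and motion are preserved sample-for-sample.  Demodulating the
    control must show no upstroke-locked dips — any dip that survives is
    cross-talk, not impedance.
    """
    z0 = float(np.median(np.abs(rec.truth_Z)))
    ph0 = float(np.median(np.angle(rec.truth_Z)))
    test = rec.params.I0 * z0 * np.sin(rec.phi + ph0)
    y = rec.y - rec.test_component + test
    return SyntheticRecording(
        times=rec.times.copy(), y=y, phi=rec.phi.copy(),
        truth_Z=np.full(len(rec), z0 * np.exp(1j * ph0), dtype=complex),
        truth_map=rec.truth_map.copy(), test_component=test,
        noise=rec.noise.copy(), motion_component=rec.motion_component.copy(),
        params=rec.params)


# ---------------------------------------------------------------------- I/O

def write_recording(rec: SyntheticRecording, path: str) -> None:
    """Binary container (or CSV when the path ends in .csv) holding all
    channels plus fs/f_test/I0/seed metadata."""
    if str(path).endswith(".csv"):
        import pandas as pd
        df = pd.DataFrame({
            "t_s": rec.times, "y_mV": rec.y, "phi_rad": rec.phi,
            "truth_Z_abs": np.abs(rec.truth_Z),
            "truth_Z_phase": np.angle(rec.truth_Z),
            "truth_map_mV": rec.truth_map,
        })
        with open(path, "w") as fh:
            fh.write(f"# phasicz-recording fs={rec.params.fs} "
                     f"f_test={rec.params.f_test} I0={rec.params.I0} "
                     f"seed={rec.params.seed}\n")
            df.to_csv(fh, index=False, float_format="%.17g")
    else:
        np.savez_compressed(
            path, times=rec.times, y=rec.y, phi=rec.phi,
            truth_Z=rec.truth_Z, truth_map=rec.truth_map,
            test_component=rec.test_component, noise=rec.noise,
            motion_component=rec.motion_component,
            fs=rec.params.fs, f_test=rec.params.f_test, I0=rec.params.I0,
            seed=rec.params.seed, duration=rec.params.duration,
            cycle_length_ms=rec.params.cycle_length_ms,
            first_upstroke_ms=rec.params.first_upstroke_ms,
            noise_sd=rec.params.noise_sd)


def read_recording(path: str) -> SyntheticRecording:
    with np.load(path) as z:
        params = RecordingParams(
            fs=float(z["fs"]), f_test=float(z["f_test"]), I0=float(z["I0"]),
            duration=float(z["duration"]),
            cycle_length_ms=float(z["cycle_length_ms"]),
            first_upstroke_ms=float(z["first_upstroke_ms"]),
            Z_profile=np.abs(z["truth_Z"]),
            noise_sd=float(z["noise_sd"]), seed=int(z["seed"]))
        return SyntheticRecording(
            times=z["times"], y=z["y"], phi=z["phi"], truth_Z=z["truth_Z"],
            truth_map=z["truth_map"], test_component=z["test_component"],
            noise=z["noise"], motion_component=z["motion_component"],
            params=params)
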