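"""End-to-end orchestration.

One config-driven run chains every stage of the analysis:

    pace the ionic model -> linearize along the beat -> map to the
    extracellular impedance -> window-average -> synthesize a raw
    two-electrode recording carrying the windowed impedance as ground
    truth -> demodulate it back.

and reports the summary features of each stage (dip ratio, intracellular
ΔZ/Z, extracellular Δℤ/ℤ, recovered dome amplitude) together with a
manifest of all written files, their hashes and the seeds used, so a run is
reproducible bit-for-bit from its config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .demod import WindowPlan, demodulate
from .impedance import TestSignalSpec, impedance_trace, extract_deflections
from .models import get_model
from .recording import (DomeDipProfile, MAPTemplate, RecordingParams,
                        SyntheticRecording, generate_recording,
                        write_recording)
from .simulate import StimulusProtocol, default_protocol, simulate_ap, \
    write_trajectory
from .tissue import (TissueParams, delta_Z_ext, downsample_windows,
                     extracellular_from_membrane)

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("phasicz")


@dataclass
class RunConfig:
    """Full configuration of a pipeline run."""

    model: str = "mahajan"
    dt: float = 0.01                       # ms
    protocol: StimulusProtocol | None = None
    test_frequency: float = 50.0           # Hz, for the linearization stage
    impedance_stride: int = 10
    tissue: TissueParams = field(default_factory=TissueParams)
    window_ms: float = 10.0
    recording_f_test: float = 1000.0       # Hz, for the synthetic recording
    recording_I0: float = 0.02             # mA
    recording_noise_sd: float = 0.12       # mV
    window_plan: WindowPlan = field(default_factory=WindowPlan)
    out_dir: str = "phasicz_run"
    seed: int = 0

    def validate(self) -> None:
        get_model(self.model)
        if self.protocol is not None:
            self.protocol.validate()
        self.tissue.validate()
        self.window_plan.validate(self.recording_f_test)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        TestSignalSpec(self.test_frequency)

    # -- config file round trip --------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("protocol") is not None:
            d["protocol"] = StimulusProtocol(**d["protocol"])
        if "tissue" in d:
            d["tissue"] = TissueParams(**d["tissue"])
        if "window_plan" in d:
            d["window_plan"] = WindowPlan(**d["window_plan"])
        return cls(**d)

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name):
    log.info("stage: %s", name)
    return time.perf_counter()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage; returns (and writes) the run manifest."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": cfg.seed,
                      "config": cfg.to_dict(), "stages": {}, "files": {},
                      "features": {}}
    ss = np.random.SeedSequence(cfg.seed)
    rec_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31))

    model = get_model(cfg.model)
    proto = cfg.protocol or default_protocol(model)

    try:
        t0 = _stage("simulate")
        traj = simulate_ap(model, proto, dt=cfg.dt)
        write_trajectory(traj, str(out / "trajectory.npz"), model)
        manifest["stages"]["simulate"] = time.perf_counter() - t0

        t0 = _stage("linearize")
        test = TestSignalSpec(cfg.test_frequency, amplitude=cfg.recording_I0)
        zt = impedance_trace(model, traj, test, stride=cfg.impedance_stride)
        feats = extract_deflections(zt, traj)
        _write_trace_csv(out / "impedance_trace.csv", zt.times, zt.Z,
                         {"frequency_Hz": zt.frequency, "model": zt.model_name,
                          "capacitance_removed": zt.capacitance_removed})
        manifest["stages"]["linearize"] = time.perf_counter() - t0

        t0 = _stage("extracellular")
        tr = extracellular_from_membrane(zt, cfg.tissue)
        trw = downsample_windows(tr, cfg.window_ms)
        dZe, dZe_rel = delta_Z_ext(trw, traj)
        _write_trace_csv(out / "extracellular_trace.csv", trw.times, trw.Zext,
                         {"frequency_Hz": trw.frequency,
                          "window_ms": trw.window_ms})
        manifest["stages"]["extracellular"] = time.perf_counter() - t0

        t0 = _stage("synthesize")
        rec = _recording_from_windows(cfg, trw, traj, rec_seed)
        write_recording(rec, str(out / "recording.npz"))
        manifest["stages"]["synthesize"] = time.perf_counter() - t0

        t0 = _stage("demodulate")
        res = demodulate(rec, cfg.window_plan)
        base = float(np.median(res.Z_est))
        dome_rec = float(res.Z_est.max() - base)
        np.savetxt(out / "demod.csv",
                   np.column_stack([res.window_times, res.Z_est,
                                    res.phase_est, res.residual_rms]),
                   delimiter=",", header="window_ms,Z_est,phase_est,residual_rms",
                   fmt="%.17g")
        manifest["stages"]["demodulate"] = time.perf_counter() - t0
    except Exception as exc:
        raise type(exc)(f"[stage failure] {exc}") from exc

    manifest["features"] = {
        "dip_ratio": feats.dip_ratio,
        "deltaZ_over_Z": feats.deltaZ_rel,
        "deltaZext_over_Zext": dZe_rel,
        "recovered_dome_Ohm": dome_rec,
    }
    for p in sorted(out.iterdir()):
        if p.name != "manifest.json":
            manifest["files"][p.name] = _sha256(p)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _recording_from_windows(cfg: RunConfig, trw, traj, seed: int
                            ) -> SyntheticRecording:
    """Build the synthetic recording whose ground-truth impedance is the
    windowed extracellular trace of this run (repeated every beat)."""
    cl = traj.protocol.cycle_length if traj.protocol else 400.0
    duration = 2.0 * cl / 1000.0
    fs = 30000.0
    n = int(round(duration * fs))
    t_ms = np.arange(n) / fs * 1000.0
    # map run time onto the trace's beat (stim at cfg first upstroke)
    first_up = 100.0
    src_t = (trw.times - traj.stim_time) % cl
    order = np.argsort(src_t)
    z = np.interp((t_ms - first_up + (traj.upstroke_time - traj.stim_time))
                  % cl, src_t[order], trw.magnitude[order])
    params = RecordingParams(
        fs=fs, f_test=cfg.recording_f_test, I0=cfg.recording_I0,
        duration=duration, cycle_length_ms=cl, first_upstroke_ms=first_up,
        Z_profile=z, map_template=MAPTemplate(apd_ms=max(traj.apd90_final, 50.0)),
        noise_sd=cfg.recording_noise_sd, seed=seed)
    return generate_recording(params)


def _write_trace_csv(path, times, Z, meta: dict) -> None:
    Z = np.asarray(Z)
    data = np.column_stack([times, np.abs(Z), np.angle(Z), Z.real, Z.imag])
    with open(path, "w") as fh:
        fh.write("# phasicz-trace " + json.dumps(meta) + "\n")
        fh.write("t_ms,abs_Ohm,phase_rad,real_Ohm,imag_Ohm\n")
        np.savetxt(fh, data, delimiter=",", fmt="%.17g")
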