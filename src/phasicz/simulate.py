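"""Action-potential integration.

The integrator follows the hybrid explicit scheme standard for stiff cardiac
models: transmembrane potential and auxiliary variables advance by explicit
Euler while every Hodgkin-Huxley gate advances by its exact exponential
relaxation at the pre-step voltage (the Rush-Larsen update)

    f  <-  f_eq(V) + (f - f_eq(V)) * exp(-dt / tau(V)),

which is unconditionally stable in the gates and exact for frozen V.
The default time step is 0.01 ms.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import IntegrationBlowupError, StimulusFailureError
from .models.base import IonicModel, MembraneState

__all__ = ["StimulusProtocol", "APTrajectory", "step_state", "simulate_ap",
           "default_protocol", "write_trajectory", "read_trajectory"]

#: max |dV/dt| (mV/ms) used to detect upstrokes; below this, no AP was elicited
UPSTROKE_DVDT_MIN = 1.0


@dataclass
class StimulusProtocol:
    """Periodic current-pulse pacing."""

    cycle_length: float = 400.0   # ms
    n_beats: int = 20
    amplitude: float = 0.0186     # uA (cell-level; ~2x diastolic threshold)
    duration: float = 1.0         # ms

    def validate(self) -> None:
        if self.duration >= self.cycle_length:
            raise ValueError("stimulus duration must be < cycle length")
        if self.cycle_length <= 0 or self.duration <= 0 or self.n_beats < 1:
            raise ValueError("cycle_length, duration and n_beats must be positive")


def default_protocol(model: IonicModel) -> StimulusProtocol:
    """Per-model pacing defaults (amplitude about twice diastolic threshold
    for a 1 ms pulse)."""
    if model.name == "mahajan":
        return StimulusProtocol(cycle_length=400.0, n_beats=20,
                                amplitude=55.0 * model.C, duration=1.0)
    if model.name == "hh":
        return StimulusProtocol(cycle_length=50.0, n_beats=5,
                                amplitude=14.0 * model.C, duration=1.0)
    return StimulusProtocol()


@dataclass
class APTrajectory:
    """A recorded stretch of a paced run: the final beat plus the diastolic
    window that precedes its stimulus, at full integration resolution."""

    times: np.ndarray            # ms, absolute simulation time
    V: np.ndarray                # mV
    gates: np.ndarray            # (n, n_gates)
    P: np.ndarray                # (n, n_aux)
    dVdt: np.ndarray             # mV/ms
    model_name: str
    dt: float
    stim_time: float             # time of the final stimulus onset
    upstroke_times: np.ndarray   # per paced beat, absolute ms
    apd90: np.ndarray            # per paced beat, ms
    protocol: StimulusProtocol | None = None

    def __len__(self) -> int:
        return len(self.times)

    def state(self, i: int) -> MembraneState:
        return MembraneState(self.V[i], self.gates[i], self.P[i], self.times[i])

    @property
    def upstroke_time(self) -> float:
        """Upstroke time of the recorded (final) beat."""
        return float(self.upstroke_times[-1])

    @property
    def apd90_final(self) -> float:
        return float(self.apd90[-1])

    def validate(self) -> None:
        n = len(self.times)
        if not (len(self.V) == len(self.gates) == len(self.P) == len(self.dVdt) == n):
            raise ValueError("trajectory arrays have mismatched lengths")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")


def step_state(model: IonicModel, s: MembraneState, I_ext: float,
               dt: float) -> MembraneState:
    """Advance one state by one hybrid Euler / Rush-Larsen step."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    f_eq, tau = model.gate_kinetics(s.V)
    dV, dP = model.rhs(s.V, list(s.gates), list(s.P), I_ext)
    V_new = s.V + dt * dV
    P_new = np.asarray(s.P, dtype=float) + dt * np.asarray(dP, dtype=float)
    g_new = np.empty(model.n_gates)
    for i in range(model.n_gates):
        g_new[i] = f_eq[i] + (s.gates[i] - f_eq[i]) * math.exp(-dt / tau[i])
    out = MembraneState(V_new, g_new, P_new, s.t + dt)
    _check_finite(model, out)
    return out


def _check_finite(model: IonicModel, s: MembraneState) -> None:
    if not math.isfinite(s.V):
        raise IntegrationBlowupError(f"V is non-finite at t={s.t:.3f} ms")
    for name, v in zip(model.gate_names, s.gates):
        if not math.isfinite(v):
            raise IntegrationBlowupError(f"gate {name!r} is non-finite at t={s.t:.3f} ms")
    for name, v in zip(model.aux_names, s.P):
        if not math.isfinite(v):
            raise IntegrationBlowupError(
                f"auxiliary variable {name!r} is non-finite at t={s.t:.3f} ms")


def simulate_ap(model: IonicModel, protocol: StimulusProtocol | None = None,
                dt: float = 0.01, pre_ms: float | None = None) -> APTrajectory:
    """Pace the model and return the final beat (with its preceding
    diastolic window) at full resolution.

    The model is paced for ``protocol.n_beats`` beats from its resting state;
    per-beat upstroke times and APD90 are recorded throughout, and the state
    trajectory is kept for the window from ``pre_ms`` before the final
    stimulus to the end of the final beat.
    """
    if protocol is None:
        protocol = default_protocol(model)
    protocol.validate()
    if pre_ms is None:
        pre_ms = min(100.0, 0.45 * protocol.cycle_length)
    if pre_ms >= protocol.cycle_length:
        raise ValueError("pre_ms must be shorter than one cycle")

    cl, dur, amp = protocol.cycle_length, protocol.duration, protocol.amplitude
    n_per_beat = int(round(cl / dt))
    n_dur = int(round(dur / dt))
    n_beats = protocol.n_beats

    s0 = model.resting_state()
    V = float(s0.V)
    gates = [float(g) for g in s0.gates]
    P = [float(p) for p in s0.P]
    n_g, n_p = len(gates), len(P)

    rec_start = max(0, (n_beats - 1) * n_per_beat - int(round(pre_ms / dt)))
    n_rec = n_beats * n_per_beat - rec_start + 1
    rt = np.empty(n_rec)
    rV = np.empty(n_rec)
    rG = np.empty((n_rec, n_g))
    rP = np.empty((n_rec, n_p))
    rD = np.empty(n_rec)

    upstrokes, apd90s = [], []
    beat_V = np.empty(n_per_beat)
    beat_D = np.empty(n_per_beat)

    gk = model.gate_kinetics
    rhs = model.rhs
    mexp = math.exp
    k = 0           # global step index
    irec = 0

    for beat in range(n_beats):
        t_beat = beat * cl
        for i in range(n_per_beat):
            t = t_beat + i * dt
            I_ext = amp if i < n_dur else 0.0
            f_eq, tau = gk(V)
            dV, dP = rhs(V, gates, P, I_ext)
            if k >= rec_start:
                rt[irec] = t
                rV[irec] = V
                rG[irec] = gates
                rP[irec] = P
                rD[irec] = dV
                irec += 1
            beat_V[i] = V
            beat_D[i] = dV
            V += dt * dV
            if not (-500.0 < V < 500.0):
                _check_finite(model, MembraneState(V, np.array(gates),
                                                   np.array(P), t))
                raise IntegrationBlowupError(
                    f"V left the plausible range at t={t:.3f} ms (V={V:.1f})")
            for g in range(n_p):
                P[g] += dt * dP[g]
            for g in range(n_g):
                gates[g] = f_eq[g] + (gates[g] - f_eq[g]) * mexp(-dt / tau[g])
            k += 1

        # per-beat metrics (exclude the stimulus artifact from dV/dt search
        # by masking the stimulus interval is unnecessary: the sodium-driven
        # upstroke dominates when an AP fires)
        i_up = int(np.argmax(beat_D))
        max_dvdt = beat_D[i_up]
        if max_dvdt < UPSTROKE_DVDT_MIN:
            raise StimulusFailureError(
                f"no action potential elicited on beat {beat + 1} "
                f"(max dV/dt = {max_dvdt:.3g} mV/ms)")
        upstrokes.append(t_beat + i_up * dt)
        v_rest = beat_V[0]
        i_peak = int(np.argmax(beat_V))
        v_peak = beat_V[i_peak]
        thr = v_rest + 0.1 * (v_peak - v_rest)
        below = np.nonzero(beat_V[i_peak:] < thr)[0]
        apd90s.append((i_peak + below[0] - i_up) * dt if len(below) else math.nan)

    # final sample (state after the last step)
    f_eq, tau = gk(V)
    dV, _ = rhs(V, gates, P, 0.0)
    rt[irec] = n_beats * cl
    rV[irec] = V
    rG[irec] = gates
    rP[irec] = P
    rD[irec] = dV
    _check_finite(model, MembraneState(V, np.array(gates), np.array(P), rt[irec]))

    traj = APTrajectory(
        times=rt, V=rV, gates=rG, P=rP, dVdt=rD,
        model_name=model.name, dt=dt,
        stim_time=(n_beats - 1) * cl,
        upstroke_times=np.array(upstrokes),
        apd90=np.array(apd90s),
        protocol=protocol,
    )
    traj.validate()
    return traj


# ---------------------------------------------------------------------- I/O

def _meta(traj: APTrajectory, gate_names, aux_names) -> dict:
    return {
        "model": traj.model_name,
        "dt": traj.dt,
        "stim_time": traj.stim_time,
        "upstroke_times": list(map(float, traj.upstroke_times)),
        "apd90": list(map(float, traj.apd90)),
        "protocol": asdict(traj.protocol) if traj.protocol else None,
        "gate_names": list(gate_names),
        "aux_names": list(aux_names),
    }


def write_trajectory(traj: APTrajectory, path: str, model: IonicModel) -> None:
    """Serialize a trajectory; ``.csv`` writes a commented-header text table
    (floats at full precision, so the round trip is bit-exact), anything else
    a compressed binary container."""
    meta = _meta(traj, model.gate_names, model.aux_names)
    if str(path).endswith(".csv"):
        cols = (["t", "V", "dVdt"] + [f"gate_{g}" for g in model.gate_names]
                + [f"P_{p}" for p in model.aux_names])
        data = np.column_stack([traj.times, traj.V, traj.dVdt, traj.gates, traj.P])
        with open(path, "w") as fh:
            fh.write("# phasicz-trajectory " + json.dumps(meta) + "\n")
            fh.write(",".join(cols) + "\n")
            np.savetxt(fh, data, delimiter=",", fmt="%.17g")
    else:
        np.savez_compressed(path, times=traj.times, V=traj.V, gates=traj.gates,
                            P=traj.P, dVdt=traj.dVdt,
                            meta=json.dumps(meta))


def read_trajectory(path: str) -> APTrajectory:
    if str(path).endswith(".csv"):
        with open(path) as fh:
            header = fh.readline()
            meta = json.loads(header.split("phasicz-trajectory", 1)[1])
            fh.readline()  # column names
            data = np.loadtxt(fh, delimiter=",")
        n_g, n_p = len(meta["gate_names"]), len(meta["aux_names"])
        times, V, dVdt = data[:, 0], data[:, 1], data[:, 2]
        gates = data[:, 3:3 + n_g]
        P = data[:, 3 + n_g:3 + n_g + n_p]
    else:
        with np.load(path) as z:
            meta = json.loads(str(z["meta"]))
            times, V, gates, P, dVdt = (z["times"], z["V"], z["gates"],
                                        z["P"], z["dVdt"])
    proto = StimulusProtocol(**meta["protocol"]) if meta["protocol"] else None
    return APTrajectory(times=times, V=V, gates=gates, P=P, dVdt=dVdt,
                        model_name=meta["model"], dt=meta["dt"],
                        stim_time=meta["stim_time"],
                        upstroke_times=np.array(meta["upstroke_times"]),
                        apd90=np.array(meta["apd90"]),
                        protocol=proto)
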