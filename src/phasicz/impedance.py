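"""Quasi-active membrane admittance and impedance.

Linearizing the membrane charge balance around a state point gives the
small-signal admittance at angular test frequency ω:

    1/Z(ω) = ∂I/∂V − iωC + Σᵢ (1 − iωτᵢ(V))⁻¹ · (dfᵢ^eq/dV) · (∂I/∂fᵢ)

The first term is the static conductance set by the instantaneous channel
state, the second the capacitive susceptance, and the sum is the dynamic
response of the Hodgkin-Huxley gates: gates fast against the test signal
(ωτ ≪ 1) act as extra conductance (the chain rule of differentiation), while
slow gates (ωτ ≫ 1) lag the voltage and behave as a phenomenological
inductance.  Auxiliary state (concentrations, Markov occupancies) is held
frozen and contributes only through ∂I/∂V.

All partial derivatives are evaluated by dual-number forward-mode automatic
differentiation through the model's own rate laws; no finite differences and
no hand-expanded expressions.

Phasor convention: the formula is used exactly as written above (capacitive
term −iωC, gate factor (1 − iωτ)⁻¹).  This is the complex conjugate of the
e^{+iωt} transfer function of the linearized ODE system; magnitudes are
convention-independent.

Units: V in mV, currents in uA, C in uF, so admittances arise in mS and are
reported in S; impedances are reported in Ω (Z = 1/Y).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import argrelextrema

from .dual import seed, value
from .errors import SingularImpedanceError
from .models.base import IonicModel, MembraneState
from .simulate import APTrajectory

__all__ = [
    "TestSignalSpec", "ComplexAdmittancePoint", "ImpedanceTrace",
    "ConductanceDecomposition", "DeflectionFeatures",
    "membrane_admittance", "impedance_trace", "conductance_decomposition",
    "frequency_sweep", "extract_deflections",
]

MS_TO_S = 1e-3     # admittance: mS -> S
MS_TO_NS = 1e6     # conductance: mS -> nS


@dataclass
class TestSignalSpec:
    """Sinusoidal test-current specification."""

    frequency: float          # Hz
    amplitude: float = 0.02   # I0, mA (used by the recording modules)

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("test frequency must be positive")
        if self.amplitude <= 0:
            raise ValueError("test amplitude must be positive")

    @property
    def omega(self) -> float:
        """Angular frequency in rad/ms (package time unit)."""
        return 2.0 * math.pi * self.frequency / 1000.0


@dataclass
class ComplexAdmittancePoint:
    """Admittance/impedance at one state point, with its Eq.-style breakdown."""

    t: float                  # ms
    Y: complex                # S
    Z: complex                # Ohm
    static: complex           # dI/dV term, S
    capacitive: complex       # -i omega C term, S
    dynamic: dict             # gate name -> complex term, S

    @property
    def terms_sum(self) -> complex:
        return self.static + self.capacitive + sum(self.dynamic.values())


@dataclass
class ImpedanceTrace:
    """Complex impedance along an AP trajectory at one test frequency."""

    times: np.ndarray         # ms
    Z: np.ndarray             # complex, Ohm
    frequency: float          # Hz
    model_name: str
    capacitance_removed: bool = False

    def __len__(self) -> int:
        return len(self.times)

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.Z)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.Z)


@dataclass
class ConductanceDecomposition:
    """Per-current quasi-active conductance (real part) along a trajectory."""

    times: np.ndarray                    # ms
    conductance: dict                    # current name -> nS array
    total: np.ndarray                    # nS
    frequency: float
    model_name: str
    admittance_parts: dict = field(default_factory=dict)  # name -> complex S
    capacitive: np.ndarray | None = None                  # complex S


@dataclass
class DeflectionFeatures:
    """The a/b/a'/b'/c deflections of an impedance trace across one beat.

    Each wave is a (time_ms, magnitude_Ohm) pair or None when the trace has
    no such extremum.  ΔZ is the peak phase-2/3 impedance above the resting
    impedance (the transient phase-0 dip is ignored); dip_ratio is the b-dip
    magnitude relative to rest.
    """

    a: tuple | None
    b: tuple | None
    a_prime: tuple | None
    b_prime: tuple | None
    c: tuple | None
    Z_rest: float
    deltaZ: float
    deltaZ_rel: float
    dip_ratio: float | None


# ----------------------------------------------------------------- core op

def _admittance_terms(model: IonicModel, V: float, gates, P, omega: float):
    """(static mS, capacitive mS, per-gate dynamic mS dict, per-current
    complex admittance mS dict) at one state."""
    n = model.n_gates
    dual_vars = seed([V] + list(gates))
    Vd, gd = dual_vars[0], dual_vars[1:]

    cur = model.per_current(Vd, gd, list(P))          # uA, dual
    f_eq, _tau = model.gate_kinetics(Vd)
    _, tau = model.gate_kinetics(V)

    cap = -1j * omega * model.C                       # mS
    factors = [1.0 / (1.0 - 1j * omega * tau[i]) for i in range(n)]
    dfeq = [g.eps[0] if hasattr(g, "eps") else 0.0 for g in f_eq]

    static = 0.0
    dynamic = {name: 0.0 for name in model.gate_names}
    per_cur = {}
    for cname, I in cur.items():
        grad = I.eps if hasattr(I, "eps") else np.zeros(n + 1)
        y = grad[0]                                   # dI/dV, mS
        static += grad[0]
        for i, gname in enumerate(model.gate_names):
            term = factors[i] * dfeq[i] * grad[1 + i]
            dynamic[gname] += term
            y = y + term
        per_cur[cname] = y
    return static, cap, dynamic, per_cur


def membrane_admittance(model: IonicModel, s: MembraneState,
                        test: TestSignalSpec) -> ComplexAdmittancePoint:
    """Quasi-active admittance of the membrane at one state point.

    Partial derivatives ∂I/∂V and ∂I/∂fᵢ are taken at the state with the
    auxiliary variables P and the other gates held fixed; dfᵢ^eq/dV is taken
    at the state's voltage.
    """
    static, cap, dynamic, _ = _admittance_terms(
        model, s.V, s.gates, s.P, test.omega)
    Y_mS = static + cap + sum(dynamic.values())
    if abs(Y_mS) * MS_TO_S < 1e-15:
        raise SingularImpedanceError(
            f"|Y| = {abs(Y_mS) * MS_TO_S:.3g} S at t={s.t} ms")
    Y = Y_mS * MS_TO_S
    return ComplexAdmittancePoint(
        t=s.t, Y=Y, Z=1.0 / Y,
        static=static * MS_TO_S, capacitive=cap * MS_TO_S,
        dynamic={k: v * MS_TO_S for k, v in dynamic.items()},
    )


def impedance_trace(model: IonicModel, traj: APTrajectory,
                    test: TestSignalSpec, stride: int = 1,
                    remove_capacitance: bool = False) -> ImpedanceTrace:
    """Impedance evaluated at every ``stride``-th trajectory sample."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    idx = np.arange(0, len(traj), stride)
    Z = np.empty(len(idx), dtype=complex)
    omega = test.omega
    for k, i in enumerate(idx):
        static, cap, dynamic, _ = _admittance_terms(
            model, traj.V[i], traj.gates[i], traj.P[i], omega)
        Y_mS = static + sum(dynamic.values())
        if not remove_capacitance:
            Y_mS = Y_mS + cap
        if abs(Y_mS) * MS_TO_S < 1e-15:
            raise SingularImpedanceError(f"|Y| ~ 0 at t={traj.times[i]} ms")
        Z[k] = 1.0 / (Y_mS * MS_TO_S)
    return ImpedanceTrace(times=traj.times[idx], Z=Z, frequency=test.frequency,
                          model_name=model.name,
                          capacitance_removed=remove_capacitance)


def conductance_decomposition(model: IonicModel, traj: APTrajectory,
                              test: TestSignalSpec,
                              stride: int = 1) -> ConductanceDecomposition:
    """Real quasi-active conductance of each membrane current vs time (nS)."""
    idx = np.arange(0, len(traj), stride)
    omega = test.omega
    parts = {name: np.empty(len(idx), dtype=complex)
             for name in model.current_names}
    cap = np.empty(len(idx), dtype=complex)
    for k, i in enumerate(idx):
        _, c, _, per_cur = _admittance_terms(
            model, traj.V[i], traj.gates[i], traj.P[i], omega)
        cap[k] = c * MS_TO_S
        for name in model.current_names:
            parts[name][k] = per_cur[name] * MS_TO_S
    cond = {name: parts[name].real / MS_TO_S * MS_TO_NS for name in parts}
    total = sum(cond.values())
    return ConductanceDecomposition(
        times=traj.times[idx], conductance=cond, total=total,
        frequency=test.frequency, model_name=model.name,
        admittance_parts=parts, capacitive=cap)


def frequency_sweep(model: IonicModel, traj: APTrajectory, frequencies,
                    remove_capacitance: bool = False,
                    stride: int = 1) -> list[ImpedanceTrace]:
    """One impedance trace per test frequency (default grid 20-800 Hz)."""
    frequencies = list(frequencies)
    if not frequencies:
        raise ValueError("frequency list must be non-empty")
    return [impedance_trace(model, traj, TestSignalSpec(f), stride=stride,
                            remove_capacitance=remove_capacitance)
            for f in frequencies]


DEFAULT_SWEEP_HZ = (20.0, 50.0, 100.0, 200.0, 400.0, 800.0)


# ------------------------------------------------------- deflection features

def _nearest_extremum(mag, idx_pool, i_ref, side):
    """Nearest strict local extremum index from idx_pool before/after i_ref."""
    if side == "before":
        cand = idx_pool[idx_pool < i_ref]
        return int(cand[-1]) if len(cand) else None
    cand = idx_pool[idx_pool > i_ref]
    return int(cand[0]) if len(cand) else None


def extract_deflections(zt: ImpedanceTrace,
                        traj: APTrajectory) -> DeflectionFeatures:
    """Locate the a, b, a', b', c waves and the ΔZ statistics of one beat.

    Requires a trace spanning a full beat with at least 50 ms of diastole
    before the stimulus.  Resting impedance is the median magnitude over the
    window 50-10 ms before the stimulus; b is the global minimum within
    ±5 ms of the upstroke; a and a' are the local maxima immediately before
    and after b; c is the magnitude maximum between 30% and 95% of APD90
    after the upstroke; b' is the local minimum between a' and c.  Ties
    resolve to the earliest sample; absent extrema are reported as None.
    """
    t = zt.times
    mag = zt.magnitude
    t_stim = traj.stim_time
    t_up = traj.upstroke_time
    apd = traj.apd90_final

    if t[0] > t_stim - 50.0:
        raise ValueError("trace must start at least 50 ms before the stimulus")

    rest_win = (t >= t_stim - 50.0) & (t <= t_stim - 10.0)
    Z_rest = float(np.median(mag[rest_win]))

    # flat trace: no deflections at all
    if np.ptp(mag) <= 1e-9 * max(Z_rest, 1.0):
        return DeflectionFeatures(a=None, b=None, a_prime=None, b_prime=None,
                                  c=None, Z_rest=Z_rest, deltaZ=0.0,
                                  deltaZ_rel=0.0, dip_ratio=None)

    # Extrema for the slow waves (a, a', b') are located on a ~1 ms smoothed
    # magnitude so that the fast oscillation of |Z| inside the phase-0
    # transient does not masquerade as plateau waves; b and c are read from
    # the raw trace.
    dt_tr = float(np.median(np.diff(t)))
    w = max(3, int(round(1.0 / dt_tr)) | 1)
    pad = np.r_[np.full(w // 2, mag[0]), mag, np.full(w // 2, mag[-1])]
    smooth = np.convolve(pad, np.ones(w) / w, mode="valid")
    maxima = argrelextrema(smooth, np.greater)[0]
    minima = argrelextrema(smooth, np.less)[0]

    # b: global minimum within +-5 ms of the upstroke
    b_win = np.nonzero((t >= t_up - 5.0) & (t <= t_up + 5.0))[0]
    b = None
    if len(b_win):
        i_b = int(b_win[np.argmin(mag[b_win])])
        b = (float(t[i_b]), float(mag[i_b]))

    a = a_p = None
    if b is not None:
        i_a = _nearest_extremum(mag, maxima, i_b, "before")
        if i_a is not None:
            a = (float(t[i_a]), float(mag[i_a]))
        i_ap = _nearest_extremum(mag, maxima, i_b, "after")
        if i_ap is not None:
            a_p = (float(t[i_ap]), float(mag[i_ap]))

    # c: maximum between 30% and 95% of APD90 after the upstroke
    c = None
    c_win = np.nonzero((t >= t_up + 0.30 * apd) & (t <= t_up + 0.95 * apd))[0]
    if len(c_win):
        i_c = int(c_win[np.argmin(-mag[c_win])])
        c = (float(t[i_c]), float(mag[i_c]))

    # b': local minimum between a' and c
    b_p = None
    if a_p is not None and c is not None:
        i_lo, i_hi = i_ap, i_c
        pool = minima[(minima > i_lo) & (minima < i_hi)]
        if len(pool):
            i_bp = int(pool[np.argmin(mag[pool])])
            b_p = (float(t[i_bp]), float(mag[i_bp]))

    deltaZ = (c[1] - Z_rest) if c is not None else 0.0
    return DeflectionFeatures(
        a=a, b=b, a_prime=a_p, b_prime=b_p, c=c,
        Z_rest=Z_rest, deltaZ=deltaZ, deltaZ_rel=deltaZ / Z_rest,
        dip_ratio=(b[1] / Z_rest) if b is not None else None,
    )
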