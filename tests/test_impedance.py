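"""Quasi-active impedance: limits, oracles, decomposition, deflections."""

import numpy as np
import pytest

from helpers import linearized_transfer
from phasicz import MembraneState
from phasicz.dual import seed
from phasicz.impedance import (TestSignalSpec, conductance_decomposition,
                               extract_deflections, frequency_sweep,
                               impedance_trace, membrane_admittance)
from phasicz.models.base import IonicModel
from phasicz.simulate import APTrajectory


class LeakModel(IonicModel):
    """Single ohmic leak current; the decomposition must return exactly g."""

    name = "leak"
    C = 1.0
    gate_names = ()
    aux_names = ()
    current_names = ("I_leak",)
    g_leak = 0.25  # mS

    def gate_kinetics(self, V):
        return [], []

    def per_current(self, V, gates, P):
        return {"I_leak": self.g_leak * (V + 60.0)}

    def resting_state(self):
        return MembraneState(-60.0, np.zeros(0), np.zeros(0))


def _chain_rule_conductance(model, s):
    """Total dI/dV including the gate chain-rule terms (the small-ωτ limit),
    computed with duals only (no Eq.-style factors)."""
    dual_vars = seed([s.V] + list(s.gates))
    Vd, gd = dual_vars[0], dual_vars[1:]
    I = model.total_current(Vd, gd, list(s.P))
    f_eq, _ = model.gate_kinetics(Vd)
    g = I.eps[0]
    for i in range(model.n_gates):
        g += f_eq[i].eps[0] * I.eps[1 + i]
    return g  # mS


def test_capacitive_limit_at_random_states(mahajan, mahajan_traj):
    """|Z|·ωC -> 1 and the phase approaches the purely capacitive +-90 deg
    at very high test frequency."""
    rng = np.random.default_rng(11)
    idx = rng.integers(0, len(mahajan_traj), 10)
    test = TestSignalSpec(1e6)
    w_SI = 2 * np.pi * 1e6
    C_F = mahajan.C * 1e-6
    for i in idx:
        pt = membrane_admittance(mahajan, mahajan_traj.state(i), test)
        assert abs(pt.Z) * w_SI * C_F == pytest.approx(1.0, rel=1e-3)
        assert abs(abs(np.angle(pt.Z, deg=True)) - 90.0) < 1.0


def test_small_omega_tau_limit_reduces_to_chain_rule(mahajan, hh,
                                                     mahajan_traj):
    """When ωτ ≪ 1 for every gate the admittance reduces to the full
    chain-rule conductance minus the capacitive term."""
    s = hh.resting_state()
    test = TestSignalSpec(1e-6)   # Hz; ωτ < 1e-7 for all HH gates
    pt = membrane_admittance(hh, s, test)
    g = _chain_rule_conductance(hh, s) * 1e-3   # S
    expect = g + pt.capacitive
    assert pt.Y == pytest.approx(expect, rel=1e-6)


@pytest.mark.parametrize("f_hz", [2.0, 17.0, 50.0, 240.0, 2000.0])
def test_linearization_matches_ode_transfer_hh(hh, f_hz):
    s = hh.resting_state()
    pt = membrane_admittance(hh, s, TestSignalSpec(f_hz))
    Z_ref = linearized_transfer(hh, s.V, s.gates, s.P, f_hz)
    assert abs(pt.Z - Z_ref) / abs(Z_ref) < 1e-6


def test_linearization_matches_ode_transfer_mahajan(mahajan, mahajan_traj,
                                                    mahajan_states):
    freqs = [2.0, 20.0, 50.0, 400.0, 2000.0]
    assert len(mahajan_states) >= 20
    for i in mahajan_states[:20]:
        s = mahajan_traj.state(i)
        for f_hz in freqs:
            pt = membrane_admittance(mahajan, s, TestSignalSpec(f_hz))
            Z_ref = linearized_transfer(mahajan, s.V, s.gates, s.P, f_hz)
            assert abs(pt.Z - Z_ref) / abs(Z_ref) < 1e-6


def test_quasi_static_gate_approximation_is_small(mahajan, mahajan_traj,
                                                  mahajan_states):
    """Against the literal trajectory-state Jacobian (which keeps the
    off-equilibrium (f_eq - f)·dτ/dV terms the quasi-active formula drops),
    the formula agrees to ~1% along the AP — the quasi-static gate
    approximation is benign."""
    for i in mahajan_states[:10]:
        s = mahajan_traj.state(i)
        for f_hz in (2.0, 50.0, 400.0):
            pt = membrane_admittance(mahajan, s, TestSignalSpec(f_hz))
            Z_ref = linearized_transfer(mahajan, s.V, s.gates, s.P, f_hz,
                                        equilibrium_gates=False)
            assert abs(pt.Z - Z_ref) / abs(Z_ref) < 0.01


def test_dual_partials_match_finite_differences(mahajan, mahajan_traj,
                                                mahajan_states):
    """∂I/∂V, ∂I/∂fᵢ and dfᵢ^eq/dV from duals vs central differences."""
    for i in mahajan_states[:8]:
        s = mahajan_traj.state(i)
        dual_vars = seed([s.V] + list(s.gates))
        I = mahajan.total_current(dual_vars[0], dual_vars[1:], list(s.P))
        f_eq_d, _ = mahajan.gate_kinetics(dual_vars[0])

        # tolerance scaled to the gradient magnitude: finite differences of
        # a small component of a vector with large entries carry absolute
        # error set by the large entries
        # floor covers central-difference truncation (h²/6·∂³I, ~6e-9 for
        # the cubic m-gate dependence at h = 1e-4)
        scale = max(np.max(np.abs(I.eps)), 1e-3)
        tol = max(1e-6 * scale, 1e-8)

        h = 1e-4
        I_p = mahajan.total_current(s.V + h, list(s.gates), list(s.P))
        I_m = mahajan.total_current(s.V - h, list(s.gates), list(s.P))
        assert abs(I.eps[0] - (I_p - I_m) / (2 * h)) < tol

        for k in range(mahajan.n_gates):
            g_p, g_m = list(s.gates), list(s.gates)
            g_p[k] += h
            g_m[k] -= h
            fd = (mahajan.total_current(s.V, g_p, list(s.P))
                  - mahajan.total_current(s.V, g_m, list(s.P))) / (2 * h)
            assert abs(I.eps[1 + k] - fd) < tol

        f_p, _ = mahajan.gate_kinetics(s.V + h)
        f_m, _ = mahajan.gate_kinetics(s.V - h)
        for k in range(mahajan.n_gates):
            fd = (f_p[k] - f_m[k]) / (2 * h)
            assert f_eq_d[k].eps[0] == pytest.approx(fd, rel=1e-6, abs=1e-9)


def test_admittance_terms_sum_and_inverse(mahajan, mahajan_traj):
    s = mahajan_traj.state(1000)
    pt = membrane_admittance(mahajan, s, TestSignalSpec(50.0))
    assert abs(pt.Y * pt.Z - 1.0) < 1e-12
    assert pt.terms_sum == pytest.approx(pt.Y, rel=1e-10)


def test_decomposition_additivity_and_leak(mahajan, mahajan_traj):
    test = TestSignalSpec(50.0)
    dec = conductance_decomposition(mahajan, mahajan_traj, test, stride=500)
    zt = impedance_trace(mahajan, mahajan_traj, test, stride=500)
    Y_rebuilt = sum(dec.admittance_parts.values()) + dec.capacitive
    assert np.allclose(Y_rebuilt, 1.0 / zt.Z, rtol=1e-8)
    assert np.allclose(dec.total, sum(dec.conductance.values()), rtol=1e-8)

    leak = LeakModel()
    traj = APTrajectory(
        times=np.arange(5.0), V=np.full(5, -60.0),
        gates=np.zeros((5, 0)), P=np.zeros((5, 0)), dVdt=np.zeros(5),
        model_name="leak", dt=1.0, stim_time=0.0,
        upstroke_times=np.array([0.0]), apd90=np.array([1.0]))
    dec = conductance_decomposition(leak, traj, test)
    assert np.allclose(dec.conductance["I_leak"], leak.g_leak * 1e6)  # nS


def test_sodium_dominates_the_upstroke_conductance(mahajan, mahajan_traj):
    """The transient conductance surge at the AP onset is carried by the
    fast sodium current."""
    test = TestSignalSpec(50.0)
    dec = conductance_decomposition(mahajan, mahajan_traj, test, stride=10)
    i_na = int(np.argmax(dec.conductance["I_Na"]))
    assert abs(dec.times[i_na] - mahajan_traj.upstroke_time) <= 1.0
    peak_na = dec.conductance["I_Na"][i_na]
    for name, g in dec.conductance.items():
        if name != "I_Na":
            assert g[i_na] < peak_na / 5.0
    # the inward rectifier conductance collapses during depolarization
    k1 = dec.conductance["I_K1"]
    dia = k1[dec.times < mahajan_traj.stim_time - 10.0].mean()
    plateau = (dec.times > mahajan_traj.upstroke_time + 50.0) & \
              (dec.times < mahajan_traj.upstroke_time + 100.0)
    assert k1[plateau].mean() < 0.25 * dia


def test_trace_stride_consistency_and_constant_state(mahajan, mahajan_traj):
    test = TestSignalSpec(50.0)
    z1 = impedance_trace(mahajan, mahajan_traj, test, stride=200)
    z10 = impedance_trace(mahajan, mahajan_traj, test, stride=1000)
    assert np.array_equal(z10.Z, z1.Z[::5])

    s = mahajan_traj.state(0)
    n = 6
    traj_const = APTrajectory(
        times=np.arange(float(n)), V=np.full(n, s.V),
        gates=np.tile(s.gates, (n, 1)), P=np.tile(s.P, (n, 1)),
        dVdt=np.zeros(n), model_name="mahajan", dt=1.0, stim_time=0.0,
        upstroke_times=np.array([0.0]), apd90=np.array([1.0]))
    z = impedance_trace(mahajan, traj_const, test)
    assert np.ptp(np.abs(z.Z)) == 0.0


def test_dip_is_locked_to_the_upstroke(mahajan_traj, mahajan_zt50):
    mag = mahajan_zt50.magnitude
    t = mahajan_zt50.times
    i_min = int(np.argmin(mag))
    assert abs(t[i_min] - mahajan_traj.upstroke_time) <= 2.0


def test_deflection_features_on_steady_beat(mahajan_traj, mahajan_zt50):
    f = extract_deflections(mahajan_zt50, mahajan_traj)
    assert f.b is not None and abs(f.b[0] - mahajan_traj.upstroke_time) <= 5.0
    assert f.dip_ratio is not None and 0.0 < f.dip_ratio < 0.1
    assert f.a is not None and f.a_prime is not None
    assert f.b_prime is not None and f.c is not None
    # ordering a < b < a' < b' < c in time
    times = [f.a[0], f.b[0], f.a_prime[0], f.b_prime[0], f.c[0]]
    assert times == sorted(times)
    assert f.deltaZ > 0 and f.deltaZ_rel == pytest.approx(
        f.deltaZ / f.Z_rest)


def test_flat_trace_has_no_deflections(mahajan_traj, mahajan_zt50):
    from phasicz.impedance import ImpedanceTrace
    flat = ImpedanceTrace(times=mahajan_zt50.times,
                          Z=np.full(len(mahajan_zt50), 5e6 + 0j),
                          frequency=50.0, model_name="mahajan")
    f = extract_deflections(flat, mahajan_traj)
    assert f.a is None and f.b is None and f.b_prime is None and f.c is None
    assert f.deltaZ == 0.0 and f.deltaZ_rel == 0.0


def test_frequency_sweep_flags_and_conductance_trends(mahajan, mahajan_traj,
                                                      mahajan_zt50):
    from phasicz.impedance import _admittance_terms
    traces = frequency_sweep(mahajan, mahajan_traj, [20.0, 100.0],
                             remove_capacitance=True, stride=2000)
    assert all(tr.capacitance_removed for tr in traces)
    assert len(traces) == 2
    with pytest.raises(ValueError):
        frequency_sweep(mahajan, mahajan_traj, [])

    feats = extract_deflections(mahajan_zt50, mahajan_traj)
    grid = [20.0, 50.0, 100.0, 200.0, 400.0, 800.0]

    def g_nocap(i, f_hz):
        st, _, dyn, _ = _admittance_terms(
            mahajan, mahajan_traj.V[i], mahajan_traj.gates[i],
            mahajan_traj.P[i], 2 * np.pi * f_hz / 1000.0)
        return (st + sum(dyn.values())).real

    # diastole: capacitance-removed conductance nearly frequency-independent
    i_dia = int(np.argmin(np.abs(mahajan_traj.times
                                 - (mahajan_traj.stim_time - 30.0))))
    g_dia = [g_nocap(i_dia, f) for f in grid]
    assert (max(g_dia) - min(g_dia)) / abs(np.mean(g_dia)) < 0.05

    # b' wave: conductance increases monotonically as frequency decreases
    i_bp = int(np.argmin(np.abs(mahajan_traj.times - feats.b_prime[0])))
    g_bp = [g_nocap(i_bp, f) for f in grid]
    assert all(g_bp[k] > g_bp[k + 1] for k in range(len(grid) - 1))


def test_slow_gate_acts_as_phenomenological_inductance(mahajan, mahajan_traj):
    """For a gate with ωτ ≫ 1 the dynamic term is rotated ~90° from the
    pure-conductance (chain-rule) value — inductive behavior."""
    s = mahajan_traj.state(0)   # diastole: ytos has a multi-second τ
    test = TestSignalSpec(50.0)
    _, tau = mahajan.gate_kinetics(s.V)
    i_slow = int(np.argmax(tau))
    assert test.omega * tau[i_slow] > 10.0

    dual_vars = seed([s.V] + list(s.gates))
    I = mahajan.total_current(dual_vars[0], dual_vars[1:], list(s.P))
    f_eq_d, _ = mahajan.gate_kinetics(dual_vars[0])
    static_term = f_eq_d[i_slow].eps[0] * I.eps[1 + i_slow]
    dyn_term = static_term / (1.0 - 1j * test.omega * tau[i_slow])
    rot = np.angle(dyn_term / static_term, deg=True)
    assert abs(abs(rot) - 90.0) < 10.0
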