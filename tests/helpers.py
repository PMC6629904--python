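"""Shared independent oracles for the test suite."""

import numpy as np


def linearized_transfer(model, V, gates, P, f_hz, h=1e-6,
                        equilibrium_gates=True):
    """Impedance of the (V, gates) subsystem by dense numerical linearization.

    Builds the Jacobian of the ODE subsystem (auxiliary P frozen) by central
    finite differences and evaluates the input-to-voltage transfer function
    at the test frequency.  Returned in the package's phasor convention
    (conjugate of the e^{+iωt} transfer function), in Ohm.

    ``equilibrium_gates=True`` linearizes each gate equation about its
    equilibrium, i.e. the voltage sensitivity of a gate is
    (df_eq/dV)/tau — the quasi-active convention.  With False, the literal
    trajectory-state Jacobian is built instead, which additionally carries
    an off-equilibrium (f_eq - f)·d(1/τ)/dV term; along an AP the two
    differ by the quality of the quasi-static gate approximation.

    Deliberately independent of the dual-number path: every derivative is
    a central finite difference of whole rate-law evaluations.
    """
    n = model.n_gates
    x0 = np.r_[V, np.asarray(gates, dtype=float)]
    P = list(P)
    f_eq0, tau0 = model.gate_kinetics(float(V))

    def F(x):
        v, g = float(x[0]), list(x[1:])
        f_eq, tau = model.gate_kinetics(v)
        dV = -model.total_current(v, g, P) / model.C
        return np.r_[dV, [(f_eq[i] - g[i]) / tau[i] for i in range(n)]]

    J = np.zeros((n + 1, n + 1))
    for k in range(n + 1):
        hk = h * max(1.0, abs(x0[k]))
        xp, xm = x0.copy(), x0.copy()
        xp[k] += hk
        xm[k] -= hk
        J[:, k] = (F(xp) - F(xm)) / (2.0 * hk)

    if equilibrium_gates:
        hv = h * max(1.0, abs(V))
        f_p, _ = model.gate_kinetics(float(V) + hv)
        f_m, _ = model.gate_kinetics(float(V) - hv)
        for i in range(n):
            J[1 + i, 0] = (f_p[i] - f_m[i]) / (2.0 * hv) / tau0[i]
            J[1 + i, 1 + i] = -1.0 / tau0[i]

    w = 2.0 * np.pi * f_hz / 1000.0          # rad/ms
    b = np.zeros(n + 1)
    b[0] = 1.0 / model.C                     # unit current input, uA
    Z_kOhm = np.linalg.solve(1j * w * np.eye(n + 1) - J, b)[0]
    return np.conj(1000.0 * Z_kOhm)          # Ohm, package convention
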