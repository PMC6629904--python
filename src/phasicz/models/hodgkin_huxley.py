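"""Classic squid-axon Hodgkin-Huxley model (m, h, n gates).

Serves as the analytically tractable benchmark for the quasi-active
impedance machinery: its small (V, m, h, n) subsystem can be linearized by a
dense Jacobian, giving an independent check of the dual-number route.

Standard modern-convention parameters (resting potential near -65 mV),
capacitance 1 uF (i.e. 1 cm^2 of membrane at 1 uF/cm^2).
"""

from __future__ import annotations

import numpy as np

from ..dual import exp
from .base import IonicModel, MembraneState

__all__ = ["HodgkinHuxley"]


def _vtrap(x, y):
    """x / (1 - exp(-x/y)), stable at x -> 0."""
    if abs(x / y) < 1e-6:
        return y * (1.0 + x / (2.0 * y))
    return x / (1.0 - exp(-x / y))


class HodgkinHuxley(IonicModel):
    name = "hh"
    C = 1.0  # uF
    gate_names = ("m", "h", "n")
    aux_names = ()
    current_names = ("I_Na", "I_K", "I_L")

    g_Na = 120.0   # mS
    g_K = 36.0
    g_L = 0.3
    E_Na = 50.0    # mV
    E_K = -77.0
    E_L = -54.387

    def rates(self, V):
        """Forward/backward rate constants (1/ms) for m, h, n."""
        a_m = 0.1 * _vtrap(V + 40.0, 10.0)
        b_m = 4.0 * exp(-(V + 65.0) / 18.0)
        a_h = 0.07 * exp(-(V + 65.0) / 20.0)
        b_h = 1.0 / (1.0 + exp(-(V + 35.0) / 10.0))
        a_n = 0.01 * _vtrap(V + 55.0, 10.0)
        b_n = 0.125 * exp(-(V + 65.0) / 80.0)
        return (a_m, b_m), (a_h, b_h), (a_n, b_n)

    def gate_kinetics(self, V):
        f_eq, tau = [], []
        for a, b in self.rates(V):
            s = a + b
            f_eq.append(a / s)
            tau.append(1.0 / s)
        return f_eq, tau

    def per_current(self, V, gates, P):
        m, h, n = gates[0], gates[1], gates[2]
        return {
            "I_Na": self.C * self.g_Na * m * m * m * h * (V - self.E_Na),
            "I_K": self.C * self.g_K * n * n * n * n * (V - self.E_K),
            "I_L": self.C * self.g_L * (V - self.E_L),
        }

    def resting_state(self) -> MembraneState:
        V0 = -64.99637933119206  # numerically located rest point
        f_eq, _ = self.gate_kinetics(V0)
        return MembraneState(V0, np.array(f_eq), np.zeros(0), 0.0)
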