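"""Ionic-model abstraction.

A model is the membrane charge balance

    C dV/dt = -I(V, f1..fn; P) + Iext

with Hodgkin-Huxley gates relaxing as dfi/dt = -(fi - fi_eq(V)) / tau_i(V)
and a vector P of auxiliary state (concentrations, buffers, Markov-chain
occupancies) with model-defined dynamics.

Units are fixed package-wide: mV, ms, uA, uF (so conductances come out in mS
and impedances in kOhm before conversion to Ohm by the impedance layer).

Rate laws are written generically so they accept either floats or
:class:`phasicz.dual.Dual` values; the impedance module exploits this to pull
exact partial derivatives out of the same code the integrator runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["IonicModel", "MembraneState"]


@dataclass
class MembraneState:
    """Full state of a membrane model at one instant."""

    V: float                 # transmembrane potential, mV
    gates: np.ndarray        # HH gate values, dimensionless, in [0, 1]
    P: np.ndarray            # auxiliary state (model-defined units)
    t: float = 0.0           # ms

    def __post_init__(self) -> None:
        self.gates = np.asarray(self.gates, dtype=float)
        self.P = np.asarray(self.P, dtype=float)

    def copy(self) -> "MembraneState":
        return MembraneState(self.V, self.gates.copy(), self.P.copy(), self.t)

    def validate(self, model: "IonicModel") -> None:
        if len(self.gates) != model.n_gates:
            raise ValueError(
                f"state has {len(self.gates)} gates, model "
                f"{model.name!r} expects {model.n_gates}"
            )
        if len(self.P) != len(model.aux_names):
            raise ValueError(
                f"state has {len(self.P)} auxiliary variables, model "
                f"{model.name!r} expects {len(model.aux_names)}"
            )
        if np.any(self.gates < -1e-12) or np.any(self.gates > 1 + 1e-12):
            bad = model.gate_names[int(np.argmax((self.gates < 0) | (self.gates > 1)))]
            raise ValueError(f"gate {bad!r} outside [0, 1]")

    @property
    def n_state(self) -> int:
        return 1 + len(self.gates) + len(self.P)


class IonicModel:
    """Base class for concrete ionic models.

    Subclasses define:

    ``name``             registry identifier
    ``C``                membrane capacitance (uF)
    ``gate_names``       ordered HH gate labels
    ``aux_names``        ordered auxiliary-state labels
    ``current_names``    ordered membrane-current labels
    ``gate_kinetics(V)`` -> (f_eq list, tau list), generic over float/Dual
    ``per_current(V, gates, P)`` -> dict name -> current (uA), generic
    ``aux_rates(V, gates, P)``   -> list dP/dt
    ``resting_state()``  -> a MembraneState near the model's rest point
    """

    name: str = "base"
    C: float = 1.0
    gate_names: tuple = ()
    aux_names: tuple = ()
    current_names: tuple = ()

    @property
    def n_gates(self) -> int:
        return len(self.gate_names)

    @property
    def n_state(self) -> int:
        return 1 + len(self.gate_names) + len(self.aux_names)

    # -- contracts ----------------------------------------------------------

    def gate_kinetics(self, V):
        raise NotImplementedError

    def per_current(self, V, gates, P):
        raise NotImplementedError

    def total_current(self, V, gates, P):
        """Sum of all membrane currents (uA)."""
        cur = self.per_current(V, gates, P)
        tot = 0.0
        for v in cur.values():
            tot = tot + v
        return tot

    def aux_rates(self, V, gates, P):
        """Time-derivatives of the auxiliary state vector (default: static)."""
        return [0.0] * len(self.aux_names)

    def rhs(self, V, gates, P, I_ext: float = 0.0):
        """(dV/dt, dP/dt) with a single evaluation of the rate laws.

        Subclasses with shared subexpressions between currents and auxiliary
        dynamics override this for speed; the default composes the contracts.
        """
        dV = (-self.total_current(V, gates, P) + I_ext) / self.C
        return dV, self.aux_rates(V, gates, P)

    def resting_state(self) -> MembraneState:
        raise NotImplementedError

    def __repr__(self) -> str:
        return f"<{type(self).__name__} {self.name!r}: {self.n_state} state variables>"
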