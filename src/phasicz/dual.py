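"""First-order dual numbers for forward-mode automatic differentiation.

A dual number ``x = a + b·ε`` (with ``ε² = 0``) carries a value ``a`` and an
infinitesimal part ``b``.  Arithmetic on duals propagates exact first
derivatives through arbitrary compositions of the elementary operations used
by the ionic-model rate laws (rational functions, ``exp``, ``log``, powers).

The infinitesimal part here is a NumPy vector, so a single evaluation of a
rate law seeded with unit directions yields the full gradient with respect to
every seeded variable (V and all gates at once).  This is what the impedance
module uses to obtain ∂I/∂V, ∂I/∂fᵢ and dfᵢ^eq/dV without symbolic expansion
or finite differences.

Comparison operators act on the real part only, so model code containing
voltage-threshold branches evaluates the branch taken at the real point, which
is the correct derivative almost everywhere (the rate laws are piecewise
smooth with matching one-sided limits at the stitch points).
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["Dual", "seed", "value", "exp", "log", "sqrt", "gradient"]


class Dual:
    """A real value together with a vector-valued infinitesimal part."""

    __slots__ = ("val", "eps")

    def __init__(self, val: float, eps) -> None:
        self.val = float(val)
        self.eps = np.asarray(eps, dtype=float)

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        if isinstance(other, Dual):
            return Dual(self.val + other.val, self.eps + other.eps)
        return Dual(self.val + other, self.eps)

    __radd__ = __add__

    def __sub__(self, other):
        if isinstance(other, Dual):
            return Dual(self.val - other.val, self.eps - other.eps)
        return Dual(self.val - other, self.eps)

    def __rsub__(self, other):
        return Dual(other - self.val, -self.eps)

    def __mul__(self, other):
        if isinstance(other, Dual):
            return Dual(self.val * other.val,
                        self.val * other.eps + other.val * self.eps)
        return Dual(self.val * other, self.eps * other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Dual):
            inv = 1.0 / other.val
            return Dual(self.val * inv,
                        (self.eps - self.val * inv * other.eps) * inv)
        inv = 1.0 / other
        return Dual(self.val * inv, self.eps * inv)

    def __rtruediv__(self, other):
        inv = 1.0 / self.val
        return Dual(other * inv, -other * inv * inv * self.eps)

    def __pow__(self, p):
        if isinstance(p, Dual):
            # x**y = exp(y log x); requires x > 0
            return exp(p * log(self))
        if p == 2:
            return Dual(self.val * self.val, 2.0 * self.val * self.eps)
        if p == 3:
            v2 = self.val * self.val
            return Dual(v2 * self.val, 3.0 * v2 * self.eps)
        v = self.val ** p
        return Dual(v, p * self.val ** (p - 1) * self.eps)

    def __rpow__(self, base):
        # base**x = exp(x log base)
        lb = math.log(base)
        v = base ** self.val
        return Dual(v, v * lb * self.eps)

    def __neg__(self):
        return Dual(-self.val, -self.eps)

    def __abs__(self):
        if self.val >= 0.0:
            return Dual(self.val, self.eps.copy())
        return Dual(-self.val, -self.eps)

    # -- comparisons on the real part --------------------------------------

    def _v(self, other):
        return other.val if isinstance(other, Dual) else other

    def __lt__(self, other):
        return self.val < self._v(other)

    def __le__(self, other):
        return self.val <= self._v(other)

    def __gt__(self, other):
        return self.val > self._v(other)

    def __ge__(self, other):
        return self.val >= self._v(other)

    def __eq__(self, other):  # value equality, ignores eps
        return self.val == self._v(other)

    def __hash__(self):
        return hash(self.val)

    def __float__(self):
        return self.val

    def __repr__(self):
        return f"Dual({self.val!r}, eps={self.eps!r})"


def seed(values, n: int | None = None, offset: int = 0):
    """Seed a list of values as duals with unit infinitesimal directions.

    ``seed([v0, v1, ...])`` returns duals whose eps vectors are the rows of an
    identity matrix, so gradients of any downstream scalar come out as its
    eps vector.  ``n``/``offset`` allow embedding into a larger direction
    space (e.g. V in slot 0, gates in slots 1..n).
    """
    values = list(values)
    m = len(values)
    if n is None:
        n = m
    out = []
    for i, v in enumerate(values):
        e = np.zeros(n)
        e[offset + i] = 1.0
        out.append(Dual(v, e))
    return out


def value(x) -> float:
    """Real part of a dual, or the float itself."""
    return x.val if isinstance(x, Dual) else float(x)


def gradient(x, n: int | None = None) -> np.ndarray:
    """Infinitesimal part of a dual, or zeros for a plain float."""
    if isinstance(x, Dual):
        return x.eps
    return np.zeros(0 if n is None else n)


# -- elementary functions (dispatch on type so model code is generic) -------

def exp(x):
    if isinstance(x, Dual):
        v = math.exp(x.val)
        return Dual(v, v * x.eps)
    return math.exp(x)


def log(x):
    if isinstance(x, Dual):
        return Dual(math.log(x.val), x.eps / x.val)
    return math.log(x)


def sqrt(x):
    if isinstance(x, Dual):
        v = math.sqrt(x.val)
        return Dual(v, 0.5 / v * x.eps)
    return math.sqrt(x)
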