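"""Ionic models and the model registry."""

from __future__ import annotations

from .base import IonicModel, MembraneState
from .hodgkin_huxley import HodgkinHuxley
from .mahajan import Mahajan

__all__ = ["IonicModel", "MembraneState", "HodgkinHuxley", "Mahajan",
           "get_model", "MODEL_REGISTRY"]

MODEL_REGISTRY = {
    "hh": HodgkinHuxley,
    "hodgkin-huxley": HodgkinHuxley,
    "mahajan": Mahajan,
}


def get_model(name: str) -> IonicModel:
    """Instantiate a registered ionic model by name."""
    try:
        return MODEL_REGISTRY[name.lower()]()
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; available: {sorted(set(MODEL_REGISTRY))}"
        ) from None
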