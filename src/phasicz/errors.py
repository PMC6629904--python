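"""Package-specific exceptions."""


class PhasiczError(Exception):
    """Base class for all package errors."""


class IntegrationBlowupError(PhasiczError):
    """A state variable became non-finite (or left any plausible range)
    during integration; the message names the offending variable."""


class StimulusFailureError(PhasiczError):
    """The pacing stimulus failed to elicit an action potential
    (max dV/dt below threshold)."""


class SingularImpedanceError(PhasiczError):
    """The admittance magnitude is numerically zero; impedance undefined."""


class AliasingError(PhasiczError):
    """Sampling rate too low for the requested test frequency."""


class ConditioningError(PhasiczError):
    """A least-squares system was too ill-conditioned to solve reliably."""
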