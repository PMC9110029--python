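"""Exception hierarchy for the package."""


class SecTransportError(Exception):
    """Base class for package errors."""


class ParameterError(SecTransportError, ValueError):
    """Invalid model parameters or assay conditions."""


class IntegrationError(SecTransportError, RuntimeError):
    """The ODE integrator failed to converge."""


class FitError(SecTransportError, RuntimeError):
    """A nonlinear fit failed to converge."""


class DataError(SecTransportError, ValueError):
    """Malformed or inconsistent input data."""
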