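"""Exception types shared across the package."""


class MolliEcvError(Exception):
    """Base class for package errors."""


class InvalidParameterError(MolliEcvError, ValueError):
    """A physical parameter is outside its admissible domain."""


class InsufficientDataError(MolliEcvError, ValueError):
    """Too few samples to identify the model."""


class FitError(MolliEcvError, RuntimeError):
    """Nonlinear fit failed to converge; carries diagnostics in ``details``."""

    def __init__(self, message: str, details: dict | None = None):
        super().__init__(message)
        self.details = details or {}
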