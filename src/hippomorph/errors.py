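"""Exception hierarchy.

``ValidationError`` covers bad inputs/parameters (CLI exit code 2),
``NumericalError`` covers runtime numerical failures (CLI exit code 3).
"""


class ValidationError(ValueError):
    """Invalid input data or parameters."""


class ParameterError(ValidationError):
    """A configuration / parameter value is out of its valid range."""


class NumericalError(RuntimeError):
    """A numerical procedure failed (non-convergence, singularity, ...)."""


class RegistrationError(NumericalError):
    """Surface or volume registration failed."""
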