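"""Exception types shared across the package."""


class DomainError(ValueError):
    """A field value is outside the domain of a fractional power.

    Raised when ``phi ** a`` is requested with non-integer ``a`` and
    ``phi <= 0`` (the model presumes real-valued fractional powers).
    """


class IntegrationError(RuntimeError):
    """Numerical integration produced non-finite values.

    Attributes
    ----------
    step : int
        Index of the first integration step at which a non-finite value
        appeared.
    """

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


class UnidentifiableDataError(ValueError):
    """The data carry no information about the model parameters
    (e.g. a constant timeseries)."""


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""
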