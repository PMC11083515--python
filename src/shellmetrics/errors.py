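"""Exception hierarchy shared across the package."""


class ShellmetricsError(Exception):
    """Base class for all package errors."""


class ParameterError(ShellmetricsError, ValueError):
    """A configuration or model parameter violates its constraints."""


class InputError(ShellmetricsError, ValueError):
    """An input array, file or record is malformed or empty."""


class DegenerateInputError(InputError):
    """Input is formally valid but has no usable content (e.g. empty mask)."""


class MissingFieldError(ShellmetricsError, KeyError):
    """A required measurement or predictor is absent; names the fields."""

    def __init__(self, fields):
        self.fields = tuple(fields)
        super().__init__(f"missing required field(s): {', '.join(self.fields)}")


class CollinearityError(ShellmetricsError, ValueError):
    """The regression design matrix is rank deficient; names the columns."""

    def __init__(self, columns):
        self.columns = tuple(columns)
        super().__init__(
            "design matrix is rank deficient; offending column(s): "
            + ", ".join(self.columns)
        )
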