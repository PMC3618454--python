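"""Exception hierarchy shared across the package."""


class ForageError(Exception):
    """Base class for all package-specific errors."""


class PackingError(ForageError, RuntimeError):
    """Patch centers could not be placed within the rejection budget."""


class FormatError(ForageError, ValueError):
    """A tabular input file violates the expected layout."""


class FitError(ForageError, ValueError):
    """A maximum-likelihood fit is undefined or degenerate for the sample."""


class InsufficientDataError(ForageError, ValueError):
    """The sample is too small or too narrow for the requested estimate."""


class EmptyProfileError(ForageError, ValueError):
    """No encounters are available to anchor a turning profile."""


class SchemaError(ForageError, ValueError):
    """An analysis configuration contains unknown or invalid keys."""
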