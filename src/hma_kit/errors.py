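"""Exception hierarchy shared across the toolkit."""


class HmaKitError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(HmaKitError):
    """Invalid generator or pipeline configuration."""


class InputError(HmaKitError):
    """Malformed or insufficient input data."""


class DesignError(InputError):
    """Experimental design missing a required condition or replicates."""


class FormatError(InputError):
    """Malformed file content; carries a line number where possible."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class FitError(HmaKitError):
    """Curve fit failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        self.diagnostics = diagnostics or {}
        super().__init__(message)


class UndefinedCorrelationError(HmaKitError):
    """Correlation requested on a zero-variance vector."""
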