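"""Exception hierarchy for neotls."""


class NeotlsError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(NeotlsError):
    """A simulation or analysis configuration is invalid."""


class FormatError(NeotlsError):
    """An input file or in-memory container violates its format contract."""


class UnimodalityError(NeotlsError):
    """The pseudotime density shows fewer than two modes.

    Carries the KDE diagnostics so the caller can inspect the density or
    fall back to a quantile split.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
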