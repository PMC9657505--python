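"""Exception hierarchy shared across the toolkit.

Errors are split by origin so callers (and the CLI exit-code mapping) can
distinguish bad parameters, malformed files, and analysis failures.
"""


class PTTKitError(Exception):
    """Base class for all toolkit errors."""


class ParameterError(PTTKitError, ValueError):
    """A function argument or configuration value is out of its valid range."""


class TimelineError(PTTKitError, ValueError):
    """A cardiac timeline is incompatible with the requested synthesis
    (e.g. beat spacing shorter than the waveform template support)."""


class FormatError(PTTKitError, IOError):
    """Base class for binary-recording format violations."""


class BadMagicError(FormatError):
    """The byte source does not start with the recording magic number."""


class VersionError(FormatError):
    """The recording was written with an unsupported format version."""

    def __init__(self, found: int, supported: int):
        self.found = found
        self.supported = supported
        super().__init__(
            f"unsupported recording format version {found} (reader supports {supported})"
        )


class TruncatedError(FormatError):
    """The byte source ended before the declared payload was complete."""


class AnalysisError(PTTKitError):
    """An analysis stage could not produce a result from valid inputs."""


class FitError(AnalysisError):
    """Nonlinear model fitting failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        self.diagnostics = diagnostics or {}
        super().__init__(message)
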