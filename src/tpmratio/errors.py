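"""Exception hierarchy for the tpmratio pipeline.

Every error raised by the package derives from :class:`TpmRatioError`, so
callers (and the CLI) can catch pipeline failures without swallowing
programming errors.
"""


class TpmRatioError(Exception):
    """Base class for all tpmratio errors."""


class ValidationError(TpmRatioError):
    """A parameter or input value violates its contract (e.g. negative SD)."""


class ConfigurationError(TpmRatioError):
    """An unknown probe, tissue class, or inconsistent configuration."""


class FormatError(TpmRatioError):
    """A file on disk does not match the expected format or schema."""


class AnalysisError(TpmRatioError):
    """An analysis step cannot proceed (empty mask, empty depth window, ...)."""
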