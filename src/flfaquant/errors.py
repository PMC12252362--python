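"""Exception hierarchy.

All library errors derive from :class:`FLFAError`; the CLI maps the three
branches onto distinct process exit codes (config 2, I/O 3, processing 4).
"""


class FLFAError(Exception):
    """Base class for all flfaquant errors."""


class ConfigError(FLFAError, ValueError):
    """Invalid parameter or configuration value."""


class ImageIOError(FLFAError, OSError):
    """Unreadable/unwritable file or unsupported image format."""


class ProcessingError(FLFAError, RuntimeError):
    """A pipeline stage failed on otherwise valid input."""


class ShortCurveError(ProcessingError):
    """Curve too short for the requested kernel or derivative width."""


class FitError(ProcessingError):
    """Calibration fit failed to converge or data are insufficient."""
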