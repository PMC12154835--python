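"""Exception hierarchy.

Every error raised by this package derives from :class:`RTImputeError` so
callers (and the CLI) can map failures onto a small set of categories:
format problems in input files, validation failures of in-memory objects,
bad configuration, and experimental-design problems.
"""


class RTImputeError(Exception):
    """Base class for all package errors."""


class FormatError(RTImputeError):
    """An input file does not conform to its documented format."""


class ValidationError(RTImputeError):
    """An in-memory object violates one of its invariants."""


class ConfigError(RTImputeError):
    """A configuration value is out of range or inconsistent."""


class DesignError(RTImputeError):
    """Experiment metadata (groups, dilutions) cannot support the analysis."""


class NoSharedFeaturesError(ValidationError):
    """Two vectors share no observed coordinates; no distance is defined."""
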