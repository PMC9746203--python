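"""Exception hierarchy for the homologues package."""


class HomologueError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(HomologueError):
    """Invalid run configuration: bad bounds, missing columns, empty input."""


class SmartsValidationError(HomologueError):
    """The repeating-unit SMARTS is unusable for chain enumeration."""
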