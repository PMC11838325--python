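"""Exception types."""


class StratDDMError(Exception):
    """Base class for package errors."""


class FormatError(StratDDMError):
    """A file does not match the expected tabular format."""


class DataValidationError(StratDDMError):
    """A record violates a dataset invariant."""


class ConfigError(StratDDMError):
    """Run configuration is invalid."""


class DegenerateTrialError(StratDDMError):
    """All strategy component likelihoods vanished for a trial."""
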