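"""Exception hierarchy.

Validation-type errors (bad configuration, malformed/mismatched inputs) are
distinguished from computation-type errors (numerical failure, degenerate
fits) so the CLI can map them to distinct exit codes.
"""


class BrainPadError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BrainPadError):
    """Invalid configuration value; message names the offending field."""


class ValidationError(BrainPadError):
    """Input data failed validation (missing values, bad ranges, ...)."""


class SchemaError(ValidationError):
    """Tables do not line up (feature names, subject ids, ...)."""


class ComputationError(BrainPadError):
    """A fit or statistic could not be computed on otherwise valid input."""


class NotFittedError(ComputationError):
    """A model was queried before being fitted."""
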