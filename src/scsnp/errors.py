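"""Exception hierarchy.

Three failure classes are distinguished so callers (and the CLI) can map
them to exit behaviour: malformed bytes/columns (FormatError), internally
inconsistent but well-formed inputs (IntegrityError), and bad arguments
(ParameterError).
"""


class ScsnpError(Exception):
    """Base class for all package errors."""


class FormatError(ScsnpError):
    """A file does not conform to its declared on-disk layout."""


class IntegrityError(ScsnpError):
    """Well-formed input whose content violates a cross-record constraint."""


class ParameterError(ScsnpError):
    """An argument is outside its documented domain."""


class ModelError(ScsnpError):
    """A model cannot be fitted, loaded, or applied."""
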