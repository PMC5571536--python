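"""Exception hierarchy shared across the pipeline.

All errors derive from :class:`ReversomError` so callers can catch the
package's failures with one clause; each subclass marks a distinct failure
mode (malformed file, inconsistent inputs, bad configuration, ...).
"""


class ReversomError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(ReversomError, ValueError):
    """A file does not follow its declared dialect (TSV matrix, GMT, ...)."""


class ConsistencyError(ReversomError, ValueError):
    """Two inputs that must agree do not (e.g. matrix vs. sample metadata)."""


class ConfigurationError(ReversomError, ValueError):
    """A parameter or label is invalid for the requested operation."""


class InsufficientReplicationError(ReversomError, ValueError):
    """A group has fewer replicate samples than the test requires."""


class EmptyInputError(ReversomError, ValueError):
    """An operation received no usable rows (e.g. every gene filtered out)."""


class DomainError(ReversomError, ValueError):
    """A numeric argument lies outside its mathematical domain."""
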