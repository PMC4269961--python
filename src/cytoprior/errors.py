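"""Exception hierarchy.

All toolkit errors derive from :class:`CytopriorError` so callers can catch
one base class; the three subclasses mirror the failure modes a pipeline run
can hit (bad data, bad file syntax, bad configuration).
"""


class CytopriorError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(CytopriorError, ValueError):
    """Input data violates a declared invariant (duplicate symbol, negative
    expression value, start >= end, ...)."""


class ParseError(CytopriorError, ValueError):
    """A file could not be parsed; the message carries the 1-based line number."""


class ConfigurationError(CytopriorError, ValueError):
    """Inconsistent or incomplete run configuration (e.g. all fusion weights
    zero, or network evidence required but no network supplied)."""
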