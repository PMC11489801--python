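"""Exception hierarchy.

All errors raised by the package derive from :class:`GeocontextError` so
callers (and the CLI exit-code mapping) can distinguish user-input problems
from bugs.
"""


class GeocontextError(Exception):
    """Base class for all package errors."""


class ValidationError(GeocontextError):
    """A value violates a domain precondition (coordinates out of range,
    non-positive radius, empty address, ...)."""


class ConfigurationError(GeocontextError):
    """A configuration key is unknown or inconsistent (unknown projection
    identifier, unknown measure name, ...)."""


class SchemaError(GeocontextError):
    """An external file violates its declared schema (missing columns,
    duplicate unit ids, out-of-range rows).  Carries a list of row/feature
    level messages so every problem is reported in one pass."""

    def __init__(self, message, details=None):
        super().__init__(message)
        self.details = list(details or [])

    def __str__(self):
        base = super().__str__()
        if self.details:
            return base + "\n  - " + "\n  - ".join(str(d) for d in self.details)
        return base
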