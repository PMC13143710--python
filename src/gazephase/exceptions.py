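"""Exception hierarchy.

Configuration problems (bad column maps, infeasible constraint bands) are
distinguished from data problems (malformed input rows) and from numerical
failures inside model fitting, so callers can react differently.
"""


class GazephaseError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GazephaseError):
    """A user-supplied configuration is invalid or infeasible."""


class DataError(GazephaseError):
    """Input data violate a structural requirement (bad rows, bad ranges)."""


class NumericalError(GazephaseError):
    """A numerical failure inside model fitting or decoding."""
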