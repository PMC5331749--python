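"""Exception hierarchy.

``ConfigError`` marks invalid user input (bad parameter values, malformed
tables); ``AnalysisError`` marks a dataset the method cannot analyse (rank
deficiency, zero GRM denominator, missing upstream artifact).  The CLI maps
the former to exit code 1 and unexpected failures to exit code 2.
"""


class PoolsireError(Exception):
    """Base class for all package errors."""


class ConfigError(PoolsireError, ValueError):
    """Invalid configuration value."""


class ParseError(PoolsireError, ValueError):
    """Malformed input table; message names the offending row/column."""


class AnalysisError(PoolsireError, RuntimeError):
    """Data violate a precondition of an analysis step."""
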