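"""Exception hierarchy.

``GcasError`` is the base for everything raised deliberately by this
package; the CLI maps :class:`UsageError` to exit code 1 and
:class:`DataError` (and subclasses) to exit code 2.
"""


class GcasError(Exception):
    """Base class for all errors raised by gcas."""


class UsageError(GcasError):
    """Bad command-line usage or inconsistent in-code arguments."""


class DataError(GcasError):
    """Invalid or inconsistent input data."""


class ParseError(DataError):
    """A source file could not be parsed.

    Carries optional ``path`` and ``line`` so callers can point at the
    offending location.
    """

    def __init__(self, message, path=None, line=None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)


class NetworkError(DataError):
    """Violation of a network invariant (duplicate id, missing endpoint...)."""


class ConfigError(GcasError):
    """An unsatisfiable configuration."""
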