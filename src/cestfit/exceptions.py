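"""Exception hierarchy used across the package."""


class CestError(Exception):
    """Base class for all cestfit errors."""


class ValidationError(CestError, ValueError):
    """A parameter or data structure violates its documented bounds."""


class ParseError(CestError, ValueError):
    """A profile or configuration file could not be parsed.

    Carries the offending path and, where known, the 1-based line number.
    """

    def __init__(self, message, path=None, line=None):
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f":{line}"
            loc = f" [{loc}]"
        super().__init__(f"{message}{loc}")
        self.path = path
        self.line = line


class DegeneracyError(CestError, ValueError):
    """Raised when a fit is requested with data at a single RF field strength.

    The exchange rate, minor population and minor-state R2 cannot be
    determined uniquely from one field; profiles at two or more distinct
    B1 strengths are required.
    """


class ConvergenceError(CestError, RuntimeError):
    """The optimizer failed to converge and no usable result exists."""
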