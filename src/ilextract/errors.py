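"""Exception hierarchy shared by all ilextract modules."""


class IlextractError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(IlextractError, ValueError):
    """Input violates a documented precondition or type invariant."""


class ParseError(IlextractError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class RangeError(IlextractError, ValueError):
    """A query lies outside the supported range; the message names the bound."""


class DegenerateModelError(IlextractError, ValueError):
    """Model parameters make the requested quantity undefined."""


class ConvergenceError(IlextractError, RuntimeError):
    """An iterative solver failed to converge."""


class OverlapError(IlextractError, RuntimeError):
    """Forward and reverse work distributions do not overlap."""
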